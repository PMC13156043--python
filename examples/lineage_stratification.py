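"""Curate a synthetic cancer registry and stratify by developmental lineage.

Generates 20,000 registry records with 2% duplicate and 5% short-residency
contamination, curates them (every drop carries a reason), and counts the
six germ-layer lineage groups plus the explicit exclusion rows.
"""

from pestmap import synth
from pestmap.lineage import curate, load_crosswalk, stratify

grid = synth.make_landscape(16, 16, 1, seed=9)
districts, pops = synth.make_districts(grid, 4, 4, seed=9)

mix = {"endo_ecto_surface": 0.366, "endo_ecto_parenchymal": 0.207,
       "non_mesenchymal_mesoderm": 0.202, "mesenchyme": 0.136,
       "neuroectoderm": 0.050, "primitive": 0.014,
       "EXCLUDED_undetermined": 0.023, "EXCLUDED_trophoblastic": 0.002}
registry = synth.make_registry(districts, pops, mix, n_cases=20000, seed=9,
                               duplicate_rate=0.02, short_residency_frac=0.05)

kept, dropped = curate(registry)
print(f"curated: kept {len(kept)}, dropped {len(dropped)} "
      f"({dropped['reason'].value_counts().to_dict()})")

table = stratify(kept, load_crosswalk())
print(table.to_string(index=False))
print("-> percentages are shares of ALL curated cases (excluded groups "
      "included), so the n column always sums to the curated total.")
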