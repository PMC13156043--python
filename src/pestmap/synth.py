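"""Synthetic study inputs with known ground truth.

Every generator is a pure function of (config, seed): landscapes (smoothed
Gaussian random-field elevation with a regional gradient so drainage exists,
slope by central differences, soil organic carbon, seasonal monthly
precipitation with run-off bounded by precipitation), active-ingredient
parameter tables, district tessellations with sex × age stratified
populations, district case counts drawn from the generative BYM Poisson
model (so the inference module can be scored against known β0, β1, τ_u,
τ_v), registry records with controllable duplicate and short-residency
contamination, and hair-biomonitoring concentrations proportional to local
risk plus noise. Generated data satisfies the type invariants of its
consumers by construction (Q ≤ P, populations > 0, E > 0), asserted at
generation time.

The default desk-scale scenario is a 64×64 grid, 12 months, 5 AIs and a
10×10 district tessellation — the full pipeline runs in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from pestmap.bayes import AdjacencyGraph
from pestmap.fate import AiParams, AI_CLASSES
from pestmap.grids import DistrictGeometry, EnvGrid
from pestmap.sir import STRATA, AGE_BANDS, SEXES

__all__ = [
    "SyntheticTruth",
    "make_landscape",
    "make_ai_table",
    "make_districts",
    "simulate_counts",
    "make_registry",
    "simulate_biomonitoring",
    "icar_sample",
]

#: fixed age-pyramid proportions (young population): 0–39, 40–59, ≥60
AGE_PYRAMID = (0.65, 0.25, 0.10)

#: class split of the 31-AI inventory (insecticides, fungicides, herbicides)
CLASS_SPLIT_31 = (19, 7, 5)


@dataclass
class SyntheticTruth:
    """Ground truth persisted alongside every generated count dataset."""

    seed: int
    beta0: float
    beta1: float
    tau_u: float
    tau_v: float
    u: list = field(default_factory=list)
    v: list = field(default_factory=list)
    exposure: list = field(default_factory=list)
    theta: list = field(default_factory=list)
    biomonitoring_noise_sd: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _smooth_field(rng, shape, sigma):
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_landscape(n_rows: int = 64, n_cols: int = 64, n_months: int = 12,
                   seed: int = 0, cell_size_m: float = 100.0,
                   relief_m: float = 400.0, gradient_m: float = 300.0,
                   mean_precip_mm: float = 120.0) -> EnvGrid:
    """Generate an aligned environmental raster stack.

    Elevation = regional west→east gradient (guarantees drainage) plus a
    smoothed Gaussian random field of amplitude ``relief_m``; slope by
    central differences; SOC in [0.1, 8] %; monthly precipitation follows a
    seasonal sinusoid with spatial noise; run-off Q = c(slope)·P with
    c ∈ (0, 0.9), so Q ≤ P holds cell-wise by construction.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("landscape must be at least 8×8")
    if n_months < 1:
        raise ValueError("need at least one month")
    rng = np.random.default_rng(seed)
    grid = EnvGrid(n_rows, n_cols, cell_size_m=cell_size_m)

    xg = np.linspace(1.0, 0.0, n_cols)[None, :] * gradient_m
    elev = xg + relief_m * 0.25 * _smooth_field(rng, (n_rows, n_cols),
                                                sigma=max(n_rows, 8) / 8)
    elev = elev - elev.min() + 100.0
    grid.add_layer("elevation_m", elev)

    dy, dx = np.gradient(elev, cell_size_m)
    slope = np.degrees(np.arctan(np.hypot(dx, dy)))
    grid.add_layer("slope_deg", np.clip(slope, 0.0, 90.0))

    soc = 2.0 * np.exp(0.6 * _smooth_field(rng, (n_rows, n_cols), sigma=6))
    grid.add_layer("soc_percent", np.clip(soc, 0.1, 8.0))

    runoff_coef = 0.1 + 0.8 * slope / (slope + 10.0)  # in (0.1, 0.9)
    for m in range(n_months):
        season = 1.0 + 0.8 * np.sin(2 * np.pi * m / 12.0)
        p = mean_precip_mm * season * np.exp(
            0.3 * _smooth_field(rng, (n_rows, n_cols), sigma=8))
        p = np.clip(p, 0.0, None)
        q = runoff_coef * p
        grid.add_layer(f"precip_mm[{m}]", p)
        grid.add_layer(f"runoff_mm[{m}]", q)
    grid.validate()
    return grid


def make_ai_table(n_ais: int = 5, seed: int = 0) -> list[AiParams]:
    """Active-ingredient table: log-uniform Koc ∈ [10, 1e5] L/kg, DT50 ∈
    [1, 365] d. For n_ais = 31 the class labels follow the 19/7/5
    insecticide/fungicide/herbicide split of the modelled inventory;
    otherwise classes are assigned proportionally."""
    if n_ais < 1:
        raise ValueError("n_ais must be >= 1")
    rng = np.random.default_rng(seed)
    if n_ais == 31:
        counts = CLASS_SPLIT_31
    else:
        raw = [round(n_ais * c / 31) for c in CLASS_SPLIT_31]
        raw[0] += n_ais - sum(raw)
        counts = raw
    classes = [c for c, k in zip(AI_CLASSES, counts) for _ in range(k)]
    koc = 10 ** rng.uniform(1.0, 5.0, size=n_ais)
    dt50 = rng.uniform(1.0, 365.0, size=n_ais)
    return [
        AiParams(name=f"ai_{i:02d}", cas=f"9999-{i:02d}-{seed % 10}",
                 ai_class=classes[i], koc=float(koc[i]),
                 dt50_soil_days=float(dt50[i]))
        for i in range(n_ais)
    ]


def make_districts(grid: EnvGrid, n_x: int = 10, n_y: int = 10, seed: int = 0,
                   mean_population: float = 10000.0
                   ) -> tuple[list[DistrictGeometry], pd.DataFrame]:
    """Rectangular district tessellation of the grid extent with stratified
    populations (log-normal totals ≥ 100, split by sex and the fixed age
    pyramid). Returns (districts, populations by district × stratum)."""
    if n_x * n_y < 4:
        raise ValueError("need at least 4 districts")
    if n_x > grid.n_cols or n_y > grid.n_rows:
        raise ValueError("tessellation finer than the grid")
    rng = np.random.default_rng(seed)
    ox, oy = grid.origin
    w = grid.n_cols * grid.cell_size_m
    h = grid.n_rows * grid.cell_size_m
    districts = []
    for iy in range(n_y):
        for ix in range(n_x):
            x0 = ox + ix * w / n_x
            x1 = ox + (ix + 1) * w / n_x
            y0 = oy - (iy + 1) * h / n_y
            y1 = oy - iy * h / n_y
            districts.append(DistrictGeometry(
                district_id=f"D{iy:02d}{ix:02d}", polygon=box(x0, y0, x1, y1)))
    totals = np.maximum(
        100.0, rng.lognormal(np.log(mean_population), 0.6, size=len(districts)))
    rows = {}
    for d, tot in zip(districts, totals):
        sex_split = rng.beta(50, 50)  # near-even, jittered
        shares = rng.dirichlet(np.array(AGE_PYRAMID) * 200)
        pops = {}
        for s, sex_frac in zip(SEXES, (sex_split, 1 - sex_split)):
            for (lo, hi), share in zip(AGE_BANDS, shares):
                lab = f"{s}_{lo}-{hi if hi is not None else 'plus'}"
                pops[lab] = tot * sex_frac * share
        rows[d.district_id] = pops
    pop = pd.DataFrame.from_dict(rows, orient="index")[list(STRATA)]
    assert (pop.sum(axis=1) >= 100 - 1e-6).all()
    return districts, pop


def icar_sample(graph: AdjacencyGraph, tau_u: float,
                rng: np.random.Generator) -> np.ndarray:
    """Draw u from the sum-to-zero-constrained ICAR prior via the spectral
    decomposition of the graph Laplacian (pseudo-inverse covariance);
    isolated districts get u = 0. Intended for desk-scale n (≤ ~500)."""
    if tau_u <= 0:
        raise ValueError("tau_u must be > 0")
    q = np.diag(graph.degree.astype(float)) - graph.adjacency.astype(float)
    vals, vecs = np.linalg.eigh(q)
    pos = vals > 1e-9
    z = rng.standard_normal(pos.sum())
    u = vecs[:, pos] @ (z / np.sqrt(tau_u * vals[pos]))
    for comp in graph.components:  # exact sum-to-zero per component
        if len(comp) > 1:
            u[comp] -= u[comp].mean()
        else:
            u[comp] = 0.0
    return u


def simulate_counts(e: np.ndarray, exposure: np.ndarray, beta0: float,
                    beta1: float, tau_u: float, tau_v: float,
                    graph: AdjacencyGraph, seed: int = 0
                    ) -> tuple[np.ndarray, SyntheticTruth]:
    """Draw district counts from y_i ~ Poisson(E_i θ_i), log θ_i = β0 +
    β1·P_i + u_i + v_i, with u ICAR(τ_u) and v iid Normal(0, 1/τ_v).

    Pass tau = np.inf to switch an effect off exactly. Returns (Y, truth).
    """
    e = np.asarray(e, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if np.any(e <= 0):
        raise ValueError("E must be > 0")
    if tau_u <= 0 or tau_v <= 0:
        raise ValueError("precisions must be > 0")
    rng = np.random.default_rng(seed)
    n = len(e)
    u = (np.zeros(n) if np.isinf(tau_u) else icar_sample(graph, tau_u, rng))
    v = (np.zeros(n) if np.isinf(tau_v)
         else rng.standard_normal(n) / np.sqrt(tau_v))
    theta = np.exp(beta0 + beta1 * exposure + u + v)
    y = rng.poisson(e * theta)
    truth = SyntheticTruth(seed=seed, beta0=beta0, beta1=beta1,
                           tau_u=float(tau_u), tau_v=float(tau_v),
                           u=u.tolist(), v=v.tolist(),
                           exposure=exposure.tolist(), theta=theta.tolist())
    return y.astype(float), truth


def _codes_by_group(assignment) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for code, g in assignment.mapping.items():
        if len(code) == 3:  # block-level codes only
            groups.setdefault(g, []).append(code)
    return {g: sorted(v) for g, v in groups.items()}


def make_registry(districts: list[DistrictGeometry], populations: pd.DataFrame,
                  lineage_mix: dict, n_cases: int, seed: int = 0,
                  assignment=None, theta: np.ndarray | None = None,
                  duplicate_rate: float = 0.0,
                  short_residency_frac: float = 0.0) -> pd.DataFrame:
    """Generate registry records (as a DataFrame with RegistryRecord fields).

    Cases are allocated to districts proportional to θ_i·population (uniform
    risk if ``theta`` is None); ICD-10 codes are drawn within each lineage
    group's code blocks from ``assignment`` (default packaged crosswalk), so
    stratification recovers ``lineage_mix`` up to sampling noise. A fraction
    ``short_residency_frac`` of rows gets residency < 5 years and
    ``duplicate_rate`` of rows are exact copies of earlier rows, to exercise
    curation.
    """
    if not districts:
        raise ValueError("empty district list")
    if abs(sum(lineage_mix.values()) - 1.0) > 1e-9:
        raise ValueError("lineage_mix must sum to 1")
    if assignment is None:
        from pestmap.lineage import load_crosswalk
        assignment = load_crosswalk()
    rng = np.random.default_rng(seed)
    codes_by_group = _codes_by_group(assignment)
    pop_tot = populations.sum(axis=1).to_numpy(dtype=float)
    wt = pop_tot * (np.ones(len(districts)) if theta is None
                    else np.asarray(theta, dtype=float))
    wt = wt / wt.sum()
    groups = list(lineage_mix)
    gprobs = np.array([lineage_mix[g] for g in groups])
    age_edges = [(0, 39), (40, 59), (60, 90)]
    rows = []
    for i in range(n_cases):
        if rows and rng.random() < duplicate_rate:
            rows.append(dict(rows[rng.integers(len(rows))]))
            continue
        d_idx = rng.choice(len(districts), p=wt)
        g = groups[rng.choice(len(groups), p=gprobs)]
        code = codes_by_group[g][rng.integers(len(codes_by_group[g]))]
        band = age_edges[rng.choice(3, p=np.array(AGE_PYRAMID))]
        age = int(rng.integers(band[0], band[1] + 1))
        if rng.random() < short_residency_frac:
            residency = float(rng.uniform(0.0, 4.99))
        else:
            residency = float(rng.uniform(5.0, 40.0))
        year = int(rng.integers(2007, 2021))
        month = int(rng.integers(1, 13))
        rows.append({
            "record_id": f"R{i:06d}",
            "icd10": code,
            "sex": SEXES[int(rng.integers(2))],
            "age_years": age,
            "district_id": districts[d_idx].district_id,
            "diagnosis_date": f"{year:04d}-{month:02d}-15",
            "residency_years_at_diagnosis": residency,
        })
    return pd.DataFrame(rows)


def simulate_biomonitoring(n_subjects: int, risk_at_locations: np.ndarray,
                           noise_sd: float, seed: int = 0,
                           intercept: float = 5.0, slope: float = 1.0
                           ) -> np.ndarray:
    """Hair concentrations (pg/mg): a + b·risk + Normal(0, noise_sd),
    truncated at 0, at the given subject locations (risk values)."""
    if n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    risk = np.asarray(risk_at_locations, dtype=float)
    if len(risk) != n_subjects:
        raise ValueError("risk_at_locations length must equal n_subjects")
    rng = np.random.default_rng(seed)
    conc = intercept + slope * risk + rng.normal(0.0, noise_sd, size=n_subjects)
    return np.clip(conc, 0.0, None)
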