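"""Indirect standardization: expected counts and standardized incidence ratios.

Six strata: sex {female, male} × age bands {0–39, 40–59, ≥60} (left-closed,
so age 40 is in 40–59). Stratum rates come from a standard population —
by default the pooled study population itself (internal standardization),
which makes the population-weighted SIR equal 1 by construction, a property
the tests assert. Expected counts are E_i = Σ_j r_j η_ij over strata j and
SIR_i = Y_i/E_i; districts with SIR > 1 are flagged as raw cancer clusters
(strict inequality). Smoothing is left to the Bayesian spatial model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["STRATA", "stratum_of", "reference_rates", "expected_counts",
           "standardized_incidence_ratio", "sir_table"]

AGE_BANDS = ((0, 39), (40, 59), (60, None))
SEXES = ("female", "male")
#: the six sex × age strata, in canonical order
STRATA = tuple(f"{s}_{lo}-{hi if hi is not None else 'plus'}"
               for s in SEXES for lo, hi in AGE_BANDS)


def stratum_of(sex: str, age_years: float) -> str:
    """Map (sex, age at diagnosis) to its stratum label."""
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if age_years < 0:
        raise ValueError("negative age")
    for lo, hi in AGE_BANDS:
        if age_years >= lo and (hi is None or age_years <= hi):
            return f"{sex}_{lo}-{hi if hi is not None else 'plus'}"
    raise AssertionError("unreachable")


def reference_rates(case_counts: dict, standard_population: dict) -> dict:
    """Stratum rates r_j = cases_j / standard-population_j (cases per person).

    ``case_counts`` and ``standard_population`` map stratum label → number.
    A stratum with cases but zero population is a contract violation.
    """
    rates = {}
    for j in STRATA:
        cases = float(case_counts.get(j, 0))
        pop = float(standard_population.get(j, 0))
        if pop <= 0:
            if cases > 0:
                raise ValueError(f"stratum {j}: cases with zero population")
            rates[j] = 0.0
        else:
            rates[j] = cases / pop
    return rates


def expected_counts(rates: dict, populations: dict) -> float:
    """E = Σ_j r_j η_j for one district. All six strata must be present in
    ``rates``; missing population strata count as zero people."""
    missing = set(STRATA) - set(rates)
    if missing:
        raise ValueError(f"missing strata in rates: {sorted(missing)}")
    return float(sum(rates[j] * float(populations.get(j, 0.0)) for j in STRATA))


def standardized_incidence_ratio(y: float, e: float):
    """(SIR, cluster_flag) with cluster ⇔ SIR > 1 strictly.

    E == 0 with Y > 0 is undefined and raises; E == 0 with Y == 0 returns
    (nan, False) — the district is omitted from cluster mapping.
    """
    if e < 0 or y < 0:
        raise ValueError("negative count")
    if e == 0:
        if y > 0:
            raise ValueError("SIR undefined: expected 0 with observed > 0")
        return float("nan"), False
    sir = y / e
    return float(sir), bool(sir > 1)


def sir_table(observed: pd.DataFrame, populations: pd.DataFrame,
              standard_population: dict | None = None) -> pd.DataFrame:
    """District-level SIR table from observed stratum counts and populations.

    ``observed``: rows = districts, columns = STRATA (case counts), indexed
    by district_id. ``populations``: same layout with person counts.
    ``standard_population``: stratum → persons; default is the pooled study
    population (column sums of ``populations``), i.e. internal
    standardization.

    Returns a DataFrame with columns Y, E, SIR, cluster_flag.
    """
    observed = observed.reindex(columns=list(STRATA)).fillna(0.0)
    populations = populations.reindex(columns=list(STRATA)).fillna(0.0)
    observed, populations = observed.align(populations, join="inner", axis=0)
    if standard_population is None:
        standard_population = populations.sum(axis=0).to_dict()
    std_cases = observed.sum(axis=0).to_dict()
    rates = reference_rates(std_cases, standard_population)
    r = np.array([rates[j] for j in STRATA])
    e = populations.to_numpy(dtype=float) @ r
    y = observed.to_numpy(dtype=float).sum(axis=1)
    sir = np.full_like(e, np.nan)
    ok = e > 0
    if np.any(~ok & (y > 0)):
        bad = observed.index[~ok & (y > 0)].tolist()
        raise ValueError(f"districts with observed cases but E=0: {bad}")
    sir[ok] = y[ok] / e[ok]
    # strict SIR > 1, with a guard against float summation noise at SIR == 1
    flag = np.where(np.isnan(sir), False, sir > 1.0 + 1e-12)
    return pd.DataFrame({"Y": y, "E": e, "SIR": sir, "cluster_flag": flag},
                        index=observed.index)
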