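"""Cumulative risk surface: aggregation, 0–100 normalization, land-cover
calibration, district zonal statistics and climate-phase comparison.

The cumulative surface is the cellwise mean over all (AI, month) deposition
layers, then min–max normalized to 0–100 over the whole domain. An optional
per-AI pre-normalization (scale each AI's stack to 0–100 before averaging)
is available for sensitivity analysis of intercompound comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pestmap.grids import LABEL_NODATA

__all__ = [
    "RiskSurface",
    "aggregate_layers",
    "normalize_0_100",
    "calibrate_with_landcover",
    "zonal_statistics",
    "compare_phases",
    "coverage_percent",
]


def coverage_percent(n_mapped: int, n_total: int) -> float:
    """Share of districts with a mapped risk value, as a percentage rounded
    to one decimal (e.g. 1793 of 1874 -> 95.7)."""
    if n_total <= 0 or n_mapped < 0 or n_mapped > n_total:
        raise ValueError("need 0 <= n_mapped <= n_total, n_total > 0")
    return round(100.0 * n_mapped / n_total, 1)


@dataclass
class RiskSurface:
    """Normalized cumulative risk score grid with provenance."""

    score: np.ndarray  # values in [0, 100]; NaN = nodata
    n_layers_aggregated: int
    provenance: list = field(default_factory=list)  # (ai_name, month) ids


def aggregate_layers(layers: list[np.ndarray]) -> np.ndarray:
    """Cellwise arithmetic mean ignoring NaN; NaN only where all layers NaN."""
    if len(layers) == 0:
        raise ValueError("no layers to aggregate")
    shape = np.asarray(layers[0]).shape
    for lay in layers[1:]:
        if np.asarray(lay).shape != shape:
            raise ValueError("misaligned layers")
    stack = np.stack([np.asarray(l, dtype=float) for l in layers])
    with np.errstate(invalid="ignore"):
        out = np.nanmean(stack, axis=0)
    return out


def normalize_0_100(grid: np.ndarray) -> np.ndarray:
    """Min–max map to [0, 100] over non-NaN cells; a constant grid maps to
    all-0 (a flat field carries no relative risk signal)."""
    grid = np.asarray(grid, dtype=float)
    valid = ~np.isnan(grid)
    if not valid.any():
        raise ValueError("all-nodata grid")
    lo = grid[valid].min()
    hi = grid[valid].max()
    if hi == lo:
        out = np.where(valid, 0.0, np.nan)
        return out
    return (grid - lo) / (hi - lo) * 100.0


def calibrate_with_landcover(score: np.ndarray, labels: np.ndarray,
                             cultivated_fraction: dict) -> np.ndarray:
    """Scale each cell by its district's cultivated land fraction, then
    renormalize to 0–100.

    ``cultivated_fraction`` maps district label (int) → fraction in [0, 1];
    every label present in ``labels`` (except nodata) must have an entry.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    present = np.unique(labels[labels != LABEL_NODATA])
    missing = [int(k) for k in present if int(k) not in cultivated_fraction]
    if missing:
        raise ValueError(f"districts missing cultivated_fraction: {missing}")
    frac = np.full(score.shape, np.nan)
    for k in present:
        frac[labels == k] = cultivated_fraction[int(k)]
    out = np.where(labels == LABEL_NODATA, np.nan, score * frac)
    return normalize_0_100(out)


def zonal_statistics(score: np.ndarray, labels: np.ndarray,
                     district_ids: list[str] | None = None,
                     cultivated_fraction: dict | None = None
                     ) -> tuple[pd.DataFrame, list]:
    """Per-district mean/median/min/max of the score over non-NaN cells.

    Returns (table, omitted): districts whose cells are all nodata are left
    out of the table and listed in ``omitted``. Labels index districts;
    ``district_ids`` (optional) supplies the id strings.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != score.shape:
        raise ValueError("labels misaligned with score")
    rows, omitted = [], []
    for k in np.unique(labels[labels != LABEL_NODATA]):
        k = int(k)
        did = district_ids[k] if district_ids is not None else str(k)
        vals = score[labels == k]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            omitted.append(did)
            continue
        row = {
            "district_id": did,
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n_cells": int(vals.size),
        }
        if cultivated_fraction is not None:
            row["cultivated_fraction"] = cultivated_fraction.get(k, np.nan)
        rows.append(row)
    return pd.DataFrame(rows), omitted


def compare_phases(grid_a: np.ndarray, grid_b: np.ndarray):
    """Paired two-sided t test on cellwise differences between two phases.

    Returns (t, p, n_pairs). Cells that are NaN in either grid are dropped.
    Zero-variance differences are a degenerate input and raise ValueError
    (the grids differ by an exact constant — the test is undefined).
    """
    a = np.asarray(grid_a, dtype=float).ravel()
    b = np.asarray(grid_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("grids misaligned")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("fewer than 2 paired cells")
    d = b - a
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, 1.0, int(a.size)
        raise ValueError(
            "zero-variance differences (constant offset); t test undefined")
    res = stats.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue), int(a.size)
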