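"""Replicated simulation experiments that score the inference machinery
against known ground truth.

These are the package's own calibration studies: frequentist coverage of
the Bayesian exposure coefficient, hotspot false-positive behaviour under a
null generative model, and type-I error of the Moran permutation test. Each
experiment is a pure function of its seed. Study conditions (100 districts,
β1 = 0.5, τ_u = 4, τ_v = 16, district expected counts averaging ≈ 30) are
fixed defaults; the null hotspot run uses θ ≡ 1 (no covariate effect, no
random effects) so every flagged district is a genuine false positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pestmap import synth
from pestmap.bayes import MCMCSettings, SpatialModelSpec, build_adjacency, fit, summarize
from pestmap.moran import morans_i_global, permutation_test, rook_grid_weights

__all__ = [
    "district_study_scene",
    "beta1_recovery_experiment",
    "null_hotspot_experiment",
    "moran_type1_experiment",
]


def district_study_scene(seed: int = 101, n_x: int = 10, n_y: int = 10):
    """Fixed desk-scale study scene: 10×10 districts on a 32×32 landscape,
    expected counts scaled to an average of ≈ 30 cases per district."""
    grid = synth.make_landscape(32, 32, 1, seed=seed)
    districts, pops = synth.make_districts(grid, n_x, n_y, seed=seed)
    graph = build_adjacency(districts)
    e = np.clip(pops.sum(axis=1).to_numpy() / 400.0, 5.0, None)
    return graph, e


def _one_fit(graph, e, expo, y, seed):
    data = pd.DataFrame({"Y": y, "E": e, "x": expo})
    return fit(SpatialModelSpec(), data, graph, MCMCSettings(seed=seed),
               covariates=["x"])


def beta1_recovery_experiment(n_replicates: int = 20, beta1: float = 0.5,
                              tau_u: float = 4.0, tau_v: float = 16.0,
                              seed: int = 0) -> dict:
    """Simulate counts with known β1 and refit; report 95%-CI coverage of
    the truth and the bias of the posterior mean across replicates."""
    graph, e = district_study_scene()
    base = (seed % 100000) * 10
    covered = 0
    means = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(base + 1000 + rep)
        expo = rng.standard_normal(graph.n)
        y, _ = synth.simulate_counts(e, expo, beta0=0.0, beta1=beta1,
                                     tau_u=tau_u, tau_v=tau_v, graph=graph,
                                     seed=base + 2000 + rep)
        draws = _one_fit(graph, e, expo, y, seed=base + 3000 + rep)
        lo, hi = np.percentile(draws.beta[:, 1], [2.5, 97.5])
        covered += int(lo <= beta1 <= hi)
        means.append(draws.beta[:, 1].mean())
    return {
        "n_replicates": n_replicates,
        "n_districts": graph.n,
        "coverage_count": covered,
        "coverage_rate": covered / n_replicates,
        "mean_bias": float(np.mean(means) - beta1),
    }


def null_hotspot_experiment(n_replicates: int = 20, seed: int = 0) -> dict:
    """Fit the model to counts simulated with θ ≡ 1 (β1 = 0, no random
    effects); report the mean fraction of districts falsely flagged as
    hotspots (CI lower bound > 1)."""
    graph, e = district_study_scene()
    base = (seed % 100000) * 10
    fps = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(base + 5000 + rep)
        expo = rng.standard_normal(graph.n)
        y, _ = synth.simulate_counts(e, expo, beta0=0.0, beta1=0.0,
                                     tau_u=np.inf, tau_v=np.inf, graph=graph,
                                     seed=base + 6000 + rep)
        draws = _one_fit(graph, e, expo, y, seed=base + 7000 + rep)
        summ = summarize(draws)
        fps.append(float(summ.table["hotspot"].mean()))
    return {
        "n_replicates": n_replicates,
        "n_districts": graph.n,
        "mean_false_positive_fraction": float(np.mean(fps)),
        "max_false_positive_fraction": float(np.max(fps)),
    }


def moran_type1_experiment(n_replicates: int = 200, n_perm: int = 999,
                           alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error of the Moran permutation test on iid data: 7×7 rook
    grid (n = 49), rejection rate at the given α across replicates."""
    w = rook_grid_weights(7, 7, style="row")
    base = (seed % 100000) * 10
    rejections = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(base + 9000 + rep)
        x = rng.standard_normal(49)
        _, _, p = permutation_test(morans_i_global, x, w, n_perm=n_perm,
                                   seed=base + 11000 + rep)
        rejections += int(p <= alpha)
    return {
        "n_replicates": n_replicates,
        "n_units": 49,
        "n_perm": n_perm,
        "rejection_rate": rejections / n_replicates,
    }
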