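"""Global, local and bivariate Moran's I with Monte Carlo permutation tests.

With deviations z = x − x̄ and weights w_ij (zero diagonal),

    I      = (n/S0) · Σ_ij w_ij z_i z_j / Σ_i z_i²
    I_xy   = (n/S0) · Σ_ij w_ij zx_i zy_j / √(Σ zx² · Σ zy²)
    I_i    = n · z_i · (Wz)_i / Σ z²          (so Σ_i I_i = S0 · I)

S0 = Σ_ij w_ij. Default weights are queen/rook contiguity, row-standardized
(matching the Bayesian module's adjacency); k-nearest-neighbour weights are
provided for point data. Significance comes from value permutation over
locations: the bivariate test holds x fixed and permutes y (conditional
null). Two-sided p doubles the smaller tail with the +1 correction, so p
is never 0. Under permutation E[I] = −1/(n−1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpatialWeights",
    "rook_grid_weights",
    "knn_weights",
    "weights_from_adjacency",
    "morans_i_global",
    "morans_i_bivariate",
    "local_morans",
    "permutation_test",
]


@dataclass
class SpatialWeights:
    """Spatial weight matrix with zero diagonal; style 'binary' or 'row'."""

    w: np.ndarray
    style: str = "binary"

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("weight matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        return float(self.w.sum())

    def row_standardized(self) -> "SpatialWeights":
        rs = self.w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0  # isolates keep an all-zero row
        return SpatialWeights(self.w / rs, style="row")


def weights_from_adjacency(adj: np.ndarray, style: str = "row") -> SpatialWeights:
    """Binary weights from a symmetric 0/1 adjacency matrix."""
    adj = np.asarray(adj, dtype=float)
    if not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be symmetric before standardization")
    w = SpatialWeights(adj, style="binary")
    return w.row_standardized() if style == "row" else w


def rook_grid_weights(n_rows: int, n_cols: int, style: str = "row") -> SpatialWeights:
    """Rook contiguity on a regular grid, row-major unit ordering."""
    n = n_rows * n_cols
    a = np.zeros((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                a[i, i + 1] = a[i + 1, i] = 1
            if r + 1 < n_rows:
                a[i, i + n_cols] = a[i + n_cols, i] = 1
    return weights_from_adjacency(a, style)


def knn_weights(points: np.ndarray, k: int = 5, style: str = "row") -> SpatialWeights:
    """Symmetrized k-nearest-neighbour weights for point data (union rule)."""
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if k >= n:
        raise ValueError("k must be < number of points")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    a = np.zeros((n, n))
    for i in range(n):
        for j in idx[i, 1:]:
            a[i, j] = a[j, i] = 1
    return weights_from_adjacency(a, style)


def _deviations(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    z = x - x.mean()
    if np.allclose(z, 0):
        raise ValueError("zero-variance input; Moran's I undefined")
    return z


def morans_i_global(x, w: SpatialWeights) -> float:
    z = _deviations(x)
    if len(z) < 3:
        raise ValueError("need n >= 3")
    if len(z) != w.n:
        raise ValueError("x and weights size mismatch")
    return float(len(z) / w.s0 * z @ w.w @ z / (z @ z))


def morans_i_bivariate(x, y, w: SpatialWeights) -> float:
    zx = _deviations(x)
    zy = _deviations(y)
    if len(zx) != len(zy) or len(zx) != w.n:
        raise ValueError("size mismatch")
    denom = np.sqrt((zx @ zx) * (zy @ zy))
    return float(len(zx) / w.s0 * zx @ w.w @ zy / denom)


def local_morans(x, w: SpatialWeights) -> np.ndarray:
    """Per-unit I_i; Σ_i I_i = S0 · I (global) holds algebraically."""
    z = _deviations(x)
    if len(z) != w.n:
        raise ValueError("size mismatch")
    return len(z) * z * (w.w @ z) / (z @ z)


def permutation_test(statistic_fn, data, w: SpatialWeights,
                     n_perm: int = 10000, seed: int | None = None):
    """Monte Carlo permutation test for a spatial statistic.

    ``data`` is x for a univariate statistic or (x, y) for a bivariate one
    (x held fixed, y permuted). Returns (observed, z_score, p_value) with
    z = (obs − mean_perm)/sd_perm and two-sided p by doubling the smaller
    tail, +1-corrected: p = min(1, 2·min tail), tail = (1 + #{≥ or ≤})/(n_perm+1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    bivariate = isinstance(data, tuple)
    if bivariate:
        x, y = data
        observed = statistic_fn(x, y, w)
        base = np.asarray(y, dtype=float).ravel()
    else:
        x = data
        observed = statistic_fn(x, w)
        base = np.asarray(x, dtype=float).ravel()

    # vectorized path for the package's own statistics
    if statistic_fn in (morans_i_global, morans_i_bivariate):
        perms = np.array([rng.permutation(base) for _ in range(n_perm)])
        zp = perms - perms.mean(axis=1, keepdims=True)
        lagT = w.w @ zp.T  # (n, n_perm)
        if bivariate:
            zx = _deviations(x)
            num = zx @ lagT
            denom = np.sqrt((zx @ zx) * np.sum(zp * zp, axis=1))
        else:
            num = np.sum(zp.T * lagT, axis=0)
            denom = np.sum(zp * zp, axis=1)
        stats_perm = w.n / w.s0 * num / denom
    else:
        stats_perm = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(base)
            stats_perm[b] = (statistic_fn(x, perm, w) if bivariate
                             else statistic_fn(perm, w))

    sd = stats_perm.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate permutation distribution (sd = 0)")
    z_score = (observed - stats_perm.mean()) / sd
    p_hi = (1 + np.sum(stats_perm >= observed)) / (n_perm + 1)
    p_lo = (1 + np.sum(stats_perm <= observed)) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return float(observed), float(z_score), float(p)
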