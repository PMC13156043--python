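"""Besag–York–Mollié Poisson spatial model: MCMC fit, hotspots, DIC/WAIC.

Model, per district i with expected count E_i and covariate row x_i:

    y_i | θ_i ~ Poisson(E_i · θ_i),   log θ_i = x_iᵀβ + u_i + v_i

u is a spatially structured intrinsic CAR (ICAR) effect on the district
adjacency graph with precision τ_u, constrained to sum to zero; v is an
exchangeable Normal(0, 1/τ_v) effect. Priors: β ~ Normal(0, 10²),
τ_u, τ_v ~ Gamma(1, 0.01) — common disease-mapping defaults, all exposed.
A zero-inflated Poisson variant adds a structural-zero mixture weight π
with a Beta(1, 1) prior, for sensitivity analysis.

Inference is Metropolis-within-Gibbs: random-walk Metropolis for β, for u
(updated one graph-colour class at a time, so non-adjacent districts move
as a single vectorized block) and for v (conditionally independent sites);
Gibbs for τ_u, τ_v (conjugate Gamma) and for the ZIP indicators and π.
Proposal scales adapt toward optimal acceptance during burn-in only and are
frozen afterwards, preserving detailed balance for the retained draws. The
sum-to-zero constraint on u is enforced every iteration by recentring, with
the subtracted mean absorbed into the intercept so the likelihood is
untouched. A district isolated in the adjacency graph has no ICAR prior and
keeps u_i = 0. Everything is reproducible from the seed.

Hotspots are districts whose 95% credible interval for the relative risk
θ_i lies entirely above 1 (lower bound > 1, strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln
from shapely.strtree import STRtree

from pestmap.grids import DistrictGeometry

__all__ = [
    "AdjacencyGraph",
    "SpatialModelSpec",
    "MCMCSettings",
    "Draws",
    "PosteriorSummary",
    "build_adjacency",
    "fit",
    "fit_zero_inflated",
    "summarize",
    "detect_hotspots",
    "information_criteria",
]


@dataclass
class AdjacencyGraph:
    """Symmetric binary district adjacency with component bookkeeping."""

    n: int
    adjacency: np.ndarray  # (n, n) 0/1, zero diagonal
    components: list = field(default_factory=list)  # lists of node indices
    isolated: np.ndarray = None  # bool per node

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if self.isolated is None:
            self.isolated = a.sum(axis=1) == 0
        if not self.components:
            g = nx.from_numpy_array(a)
            self.components = [sorted(c) for c in nx.connected_components(g)]

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def colour_classes(self) -> list[np.ndarray]:
        """Greedy graph colouring; same-colour districts are non-adjacent."""
        g = nx.from_numpy_array(self.adjacency)
        colours = nx.greedy_color(g, strategy="largest_first")
        k = max(colours.values()) + 1 if colours else 0
        return [np.array([v for v, c in colours.items() if c == ci], dtype=int)
                for ci in range(k)]


def build_adjacency(districts: list[DistrictGeometry]) -> AdjacencyGraph:
    """Queen contiguity: any shared boundary point makes two districts
    neighbours. Isolated districts and disconnected components are flagged."""
    if not districts:
        raise ValueError("empty district list")
    geoms = [d.polygon for d in districts]
    n = len(geoms)
    a = np.zeros((n, n), dtype=int)
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            if g.intersects(geoms[j]):  # touch (point or edge) suffices
                a[i, j] = a[j, i] = 1
    return AdjacencyGraph(n=n, adjacency=a)


@dataclass
class SpatialModelSpec:
    """Model structure and priors for one fit."""

    likelihood: str = "poisson"  # poisson | zero_inflated_poisson
    beta_prior_sd: float = 10.0
    tau_prior_shape: float = 1.0
    tau_prior_rate: float = 0.01
    pi_prior: tuple = (1.0, 1.0)  # Beta(a, b) for the ZIP weight
    include_structured: bool = True
    include_unstructured: bool = True

    def __post_init__(self):
        if self.likelihood not in ("poisson", "zero_inflated_poisson"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")


@dataclass
class MCMCSettings:
    iterations: int = 5000
    burn_in: int = 2000
    chains: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")


@dataclass
class Draws:
    """Post-burn-in posterior draws, concatenated over chains."""

    beta: np.ndarray  # (S, p)
    u: np.ndarray  # (S, n)
    v: np.ndarray  # (S, n)
    tau_u: np.ndarray  # (S,)
    tau_v: np.ndarray  # (S,)
    loglik: np.ndarray  # (S, n) pointwise log p(y_i | draw)
    chain: np.ndarray  # (S,) chain index
    theta: np.ndarray  # (S, n) = exp(linear predictor)
    y: np.ndarray
    e: np.ndarray
    x: np.ndarray
    rhat: dict = field(default_factory=dict)
    pi: np.ndarray | None = None  # ZIP mixture weight draws

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


@dataclass
class PosteriorSummary:
    """Per-district RR summaries plus global parameters and fit criteria."""

    table: pd.DataFrame  # district rows: rr_mean, rr_lo, rr_hi, hotspot
    beta_mean: np.ndarray
    beta_lo: np.ndarray
    beta_hi: np.ndarray
    dic: float
    waic: float
    ess: np.ndarray
    rhat: dict
    seed: int | None = None
    warnings: list = field(default_factory=list)


def _poisson_loglik(y, mu):
    return y * np.log(mu) - mu - gammaln(y + 1)


def _split_rhat(x: np.ndarray, chain: np.ndarray) -> float:
    """Split-R̂ of a scalar parameter from concatenated chain draws."""
    halves = []
    for c in np.unique(chain):
        xs = x[chain == c]
        h = len(xs) // 2
        if h >= 2:
            halves.extend([xs[:h], xs[h:2 * h]])
    if len(halves) < 2:
        return np.nan
    m = len(halves)
    nlen = min(len(h) for h in halves)
    arr = np.array([h[:nlen] for h in halves])
    means = arr.mean(axis=1)
    b = nlen * means.var(ddof=1)
    wvar = arr.var(axis=1, ddof=1).mean()
    if wvar == 0:
        return 1.0
    var_plus = (nlen - 1) / nlen * wvar + b / nlen
    return float(np.sqrt(var_plus / wvar))


def _ess(x: np.ndarray) -> float:
    """Crude effective sample size from the initial positive autocorrelations."""
    x = x - x.mean()
    s = len(x)
    if np.allclose(x, 0):
        return float(s)
    acf = np.correlate(x, x, mode="full")[s - 1:] / (np.arange(s, 0, -1) * x.var())
    rho_sum = 0.0
    for k in range(1, min(s, 200)):
        if acf[k] < 0.05:
            break
        rho_sum += acf[k]
    return float(s / (1 + 2 * rho_sum))


def _run_chain(y, e, x, graph, spec, n_iter, burn_in, rng, zip_model):
    n, p = x.shape
    deg = graph.degree.astype(float)
    isolated = graph.isolated
    colour_classes = [c[~isolated[c]] for c in graph.colour_classes()]
    colour_classes = [c for c in colour_classes if len(c)]
    adj = graph.adjacency.astype(float)
    n_free = int((~isolated).sum())
    # rank of the ICAR precision = n_free − (number of components with ≥2 nodes)
    big_comps = sum(1 for comp in graph.components if len(comp) > 1)
    icar_rank = max(n_free - big_comps, 0)

    beta = np.zeros(p)
    # initialize intercept near log(sum Y / sum E) for faster settling
    tot = y.sum() / max(e.sum(), 1e-12)
    beta[0] = np.log(tot) if tot > 0 else 0.0
    u = np.zeros(n)
    v = np.zeros(n)
    tau_u = 1.0
    tau_v = 1.0
    pi = 0.1
    z = np.zeros(n, dtype=bool)  # ZIP structural-zero indicators

    eta = x @ beta + u + v
    mu = e * np.exp(eta)

    ls_beta = np.full(p, np.log(0.1))
    ls_u = np.full(n, np.log(0.5))
    ls_v = np.full(n, np.log(0.5))
    target = 0.44

    a_tau, b_tau = spec.tau_prior_shape, spec.tau_prior_rate
    beta_prec = 1.0 / spec.beta_prior_sd**2
    keep = n_iter - burn_in
    out_beta = np.empty((keep, p))
    out_u = np.empty((keep, n))
    out_v = np.empty((keep, n))
    out_tu = np.empty(keep)
    out_tv = np.empty(keep)
    out_pi = np.empty(keep) if zip_model else None

    def active():
        # districts whose Poisson term enters the likelihood
        return ~z if zip_model else np.ones(n, dtype=bool)

    for t in range(n_iter):
        adapt = t < burn_in
        act = active()

        # --- beta: per-coordinate random-walk Metropolis
        for j in range(p):
            step = np.exp(ls_beta[j]) * rng.standard_normal()
            eta_new = eta + x[:, j] * step
            mu_new = e * np.exp(eta_new)
            dll = np.sum((y * (eta_new - eta) - (mu_new - mu))[act])
            bj_new = beta[j] + step
            dlp = -0.5 * beta_prec * (bj_new**2 - beta[j]**2)
            if np.log(rng.random()) < dll + dlp:
                beta[j] = bj_new
                eta, mu = eta_new, mu_new
                acc = 1.0
            else:
                acc = 0.0
            if adapt:
                ls_beta[j] += (acc - target) / np.sqrt(t + 1.0)

        # --- u: ICAR effect, colour class at a time
        if spec.include_structured:
            for cls in colour_classes:
                ubar = (adj[cls] @ u) / deg[cls]
                step = np.exp(ls_u[cls]) * rng.standard_normal(len(cls))
                u_new = u[cls] + step
                eta_new = eta[cls] + step
                mu_new = e[cls] * np.exp(eta_new)
                w = act[cls].astype(float)
                dll = w * (y[cls] * (eta_new - eta[cls]) - (mu_new - mu[cls]))
                dlp = -0.5 * tau_u * deg[cls] * ((u_new - ubar)**2
                                                 - (u[cls] - ubar)**2)
                accept = np.log(rng.random(len(cls))) < dll + dlp
                idx = cls[accept]
                u[idx] += step[accept]
                eta[idx] = eta_new[accept]
                mu[idx] = mu_new[accept]
                if adapt:
                    ls_u[cls] += (accept - target) / np.sqrt(t + 1.0)
            # sum-to-zero: recentre u, absorb the mean into the intercept
            if n_free:
                shift = u[~isolated].mean()
                u[~isolated] -= shift
                beta[0] += shift  # eta unchanged
            # tau_u | u: Gibbs with the ICAR quadratic form Σ_edges (u_i−u_j)²
            quad = 0.5 * float(u @ (np.diag(deg) - adj) @ u)
            tau_u = rng.gamma(a_tau + 0.5 * icar_rank, 1.0 / (b_tau + quad))

        # --- v: exchangeable effect, all sites at once (cond. independent)
        if spec.include_unstructured:
            step = np.exp(ls_v) * rng.standard_normal(n)
            v_new = v + step
            eta_new = eta + step
            mu_new = e * np.exp(eta_new)
            w = act.astype(float)
            dll = w * (y * (eta_new - eta) - (mu_new - mu))
            dlp = -0.5 * tau_v * (v_new**2 - v**2)
            accept = np.log(rng.random(n)) < dll + dlp
            v[accept] = v_new[accept]
            eta[accept] = eta_new[accept]
            mu[accept] = mu_new[accept]
            if adapt:
                ls_v += (accept - target) / np.sqrt(t + 1.0)
            tau_v = rng.gamma(a_tau + 0.5 * n,
                              1.0 / (b_tau + 0.5 * float(v @ v)))

        # --- ZIP indicators and mixture weight
        if zip_model:
            zero = y == 0
            p1 = pi
            p0 = (1 - pi) * np.exp(-mu[zero])
            prob = p1 / (p1 + p0)
            z[:] = False
            z[zero] = rng.random(zero.sum()) < prob
            a_pi, b_pi = spec.pi_prior
            pi = rng.beta(a_pi + z.sum(), b_pi + n - z.sum())

        if t >= burn_in:
            k = t - burn_in
            out_beta[k] = beta
            out_u[k] = u
            out_v[k] = v
            out_tu[k] = tau_u
            out_tv[k] = tau_v
            if zip_model:
                out_pi[k] = pi

    return out_beta, out_u, out_v, out_tu, out_tv, out_pi


def fit(spec: SpatialModelSpec, data: pd.DataFrame, graph: AdjacencyGraph,
        mcmc: MCMCSettings | None = None,
        covariates: list[str] | None = None) -> Draws:
    """Fit the BYM model by MCMC; returns concatenated post-burn-in draws.

    ``data`` needs columns Y and E (E > 0 everywhere) plus any covariate
    columns named in ``covariates`` (an intercept is always included; the
    exposure covariate should already be standardized by the caller).
    Identical data + settings + seed give bit-identical draws.
    """
    mcmc = mcmc or MCMCSettings()
    y = data["Y"].to_numpy(dtype=float)
    e = data["E"].to_numpy(dtype=float)
    if np.any(e <= 0):
        raise ValueError("E must be > 0 for all modelled districts")
    if np.any(~np.isfinite(y)) or np.any(y < 0):
        raise ValueError("invalid observed counts")
    cols = [np.ones(len(y))]
    for c in covariates or []:
        cols.append(data[c].to_numpy(dtype=float))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix not full column rank")
    if graph.n != len(y):
        raise ValueError("graph size does not match data")

    zip_model = spec.likelihood == "zero_inflated_poisson"
    ss = np.random.SeedSequence(mcmc.seed)
    child_seeds = ss.spawn(mcmc.chains)
    pieces = []
    for ci in range(mcmc.chains):
        rng = np.random.default_rng(child_seeds[ci])
        pieces.append(_run_chain(y, e, x, graph, spec, mcmc.iterations,
                                 mcmc.burn_in, rng, zip_model))

    beta = np.concatenate([p[0] for p in pieces])
    u = np.concatenate([p[1] for p in pieces])
    v = np.concatenate([p[2] for p in pieces])
    tau_u = np.concatenate([p[3] for p in pieces])
    tau_v = np.concatenate([p[4] for p in pieces])
    pi = (np.concatenate([p[5] for p in pieces]) if zip_model else None)
    keep = mcmc.iterations - mcmc.burn_in
    chain = np.repeat(np.arange(mcmc.chains), keep)

    eta = beta @ x.T + u + v  # (S, n)
    theta = np.exp(eta)
    mu = e * theta
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = _poisson_loglik(y, mu)
    if zip_model:
        zero = y == 0
        pois = np.exp(loglik[:, zero])
        loglik[:, zero] = np.log(pi[:, None] + (1 - pi[:, None]) * pois)
        loglik[:, ~zero] = np.log1p(-pi)[:, None] + loglik[:, ~zero]

    rhat = {f"beta[{j}]": _split_rhat(beta[:, j], chain)
            for j in range(x.shape[1])}
    rhat["tau_v"] = _split_rhat(tau_v, chain)
    if spec.include_structured:
        rhat["tau_u"] = _split_rhat(tau_u, chain)
    bad = {k: r for k, r in rhat.items() if np.isfinite(r) and r > 1.1}
    if bad:
        warnings.warn(f"possible non-convergence, split-R-hat > 1.1: {bad}",
                      RuntimeWarning, stacklevel=2)

    return Draws(beta=beta, u=u, v=v, tau_u=tau_u, tau_v=tau_v,
                 loglik=loglik, chain=chain, theta=theta, y=y, e=e, x=x,
                 rhat=rhat, pi=pi)


def fit_zero_inflated(spec: SpatialModelSpec, data, graph,
                      mcmc: MCMCSettings | None = None,
                      covariates: list[str] | None = None) -> Draws:
    """Zero-inflated Poisson sensitivity fit (π ~ Beta prior)."""
    zspec = SpatialModelSpec(
        likelihood="zero_inflated_poisson",
        beta_prior_sd=spec.beta_prior_sd,
        tau_prior_shape=spec.tau_prior_shape,
        tau_prior_rate=spec.tau_prior_rate,
        pi_prior=spec.pi_prior,
        include_structured=spec.include_structured,
        include_unstructured=spec.include_unstructured,
    )
    return fit(zspec, data, graph, mcmc, covariates)


def information_criteria(draws: Draws) -> tuple[float, float]:
    """DIC and WAIC from stored pointwise log-likelihoods.

    DIC = D̄ + p_D with p_D = D̄ − D(θ̄), the plug-in deviance evaluated at
    the posterior mean RR θ̄_i. WAIC = −2(lppd − p_WAIC) with
    p_WAIC = Σ_i Var_draws(log p(y_i | draw)).
    """
    ll = draws.loglik
    if ll is None or ll.size == 0:
        raise ValueError("pointwise log-likelihoods missing")
    dbar = float(-2.0 * ll.sum(axis=1).mean())
    theta_bar = draws.theta.mean(axis=0)
    mu_bar = draws.e * theta_bar
    ll_at_mean = _poisson_loglik(draws.y, mu_bar)
    if draws.pi is not None:
        pi_bar = draws.pi.mean()
        zero = draws.y == 0
        ll_at_mean[zero] = np.log(pi_bar + (1 - pi_bar) * np.exp(ll_at_mean[zero]))
        ll_at_mean[~zero] = np.log1p(-pi_bar) + ll_at_mean[~zero]
    d_hat = float(-2.0 * ll_at_mean.sum())
    p_d = dbar - d_hat
    dic = dbar + p_d

    # WAIC: log-mean-exp per district, numerically stabilized
    m = ll.max(axis=0)
    lppd = float(np.sum(m + np.log(np.mean(np.exp(ll - m), axis=0))))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    waic = -2.0 * (lppd - p_waic)
    return dic, waic


def summarize(draws: Draws, seed: int | None = None) -> PosteriorSummary:
    """Posterior means, percentile 95% CIs and hotspot flags per district."""
    if draws.n_draws < 100:
        raise ValueError("need at least 100 post-burn-in draws")
    theta = draws.theta
    rr_mean = theta.mean(axis=0)
    rr_lo = np.percentile(theta, 2.5, axis=0)
    rr_hi = np.percentile(theta, 97.5, axis=0)
    table = pd.DataFrame({
        "rr_mean": rr_mean,
        "rr_lo": rr_lo,
        "rr_hi": rr_hi,
        "hotspot": rr_lo > 1.0,
    })
    dic, waic = information_criteria(draws)
    ess = np.array([_ess(draws.beta[:, j]) for j in range(draws.beta.shape[1])])
    warns = [f"{k}: split-R-hat={r:.3f}" for k, r in draws.rhat.items()
             if np.isfinite(r) and r > 1.1]
    return PosteriorSummary(table=table,
                            beta_mean=draws.beta.mean(axis=0),
                            beta_lo=np.percentile(draws.beta, 2.5, axis=0),
                            beta_hi=np.percentile(draws.beta, 97.5, axis=0),
                            dic=dic, waic=waic, ess=ess, rhat=draws.rhat,
                            seed=seed, warnings=warns)


def detect_hotspots(summary: PosteriorSummary) -> pd.DataFrame:
    """Districts with rr_lo > 1 (strict), sorted by RR descending."""
    t = summary.table
    if t.empty:
        return t.reindex(columns=["rr_mean", "rr_lo", "rr_hi"])
    hot = t[t["hotspot"].astype(bool)].sort_values("rr_mean", ascending=False)
    return hot[["rr_mean", "rr_lo", "rr_hi"]]
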