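"""EM estimation of univariate Gaussian mixtures and component selection.

The model is the G-component normal mixture with weights π_g, means μ_g
and variances σ²_g.  The E-step computes responsibilities

    ẑ_ig = π_g φ(x_i|μ_g, σ²_g) / Σ_h π_h φ(x_i|μ_h, σ²_h)

(in log-space), and the M-step updates

    π̂_g = n_g / n,   μ̂_g = Σ_i ẑ_ig x_i / n_g,
    σ̂²_g = Σ_i ẑ_ig (x_i − μ̂_g)² / (n_g − 1),    n_g = Σ_i ẑ_ig.

The (n_g − 1) variance denominator mirrors the unbiased sample-variance
convention; it is a slight deviation from the maximizer of the expected complete-data
log-likelihood (which divides by n_g), so the observed log-likelihood is
not strictly guaranteed monotone under it.  Both denominators are
available (``variance_mode="ng-1"`` default, ``"ng"`` standard); with
``"ng"`` monotonicity is asserted up to round-off.

Component count selection fits G = 1..G_max and ranks by BIC (default)
or AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GMMParams",
    "complete_log_likelihood",
    "e_step",
    "m_step",
    "observed_log_likelihood",
    "fit_em",
    "select_components",
]

_LOG2PI = np.log(2 * np.pi)


class ComponentCollapseError(RuntimeError):
    """A component's effective sample size fell to <= 1; restart advised."""


@dataclass
class GMMParams:
    """Weights, means and variances of a G-component normal mixture."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        G = len(self.weights)
        if not (len(self.means) == len(self.variances) == G) or G < 1:
            raise ValueError("weights, means, variances must share length G >= 1")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in (0, 1]")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def G(self) -> int:
        return len(self.weights)

    def sorted_by_mean(self) -> "GMMParams":
        order = np.argsort(self.means)
        return GMMParams(self.weights[order], self.means[order],
                         self.variances[order])

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "means": self.means.tolist(),
                "variances": self.variances.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GMMParams":
        return cls(d["weights"], d["means"], d["variances"])


def _log_component_densities(x: np.ndarray, v: GMMParams) -> np.ndarray:
    """(n, G) matrix of log φ(x_i | μ_g, σ²_g)."""
    x = np.asarray(x, dtype=float)[:, None]
    return (-0.5 * (_LOG2PI + np.log(v.variances)[None, :])
            - 0.5 * (x - v.means[None, :]) ** 2 / v.variances[None, :])


def complete_log_likelihood(x, z, v: GMMParams) -> float:
    """Σ_i Σ_g z_ig [log π_g + log φ(x_i|μ_g, σ²_g)] for hard one-hot z."""
    z = np.asarray(z, dtype=float)
    if not np.allclose(z.sum(axis=1), 1.0) or not np.all(np.isin(z, (0.0, 1.0))):
        raise ValueError("z rows must be one-hot")
    assigned = z.sum(axis=0) > 0
    if np.any(assigned & (v.weights <= 0)):
        return -np.inf
    logphi = _log_component_densities(x, v)
    return float(np.sum(z * (np.log(v.weights)[None, :] + logphi)))


def observed_log_likelihood(x, v: GMMParams) -> float:
    """Σ_i log Σ_g π_g φ(x_i|μ_g, σ²_g)."""
    logphi = _log_component_densities(x, v)
    return float(logsumexp(logphi + np.log(v.weights)[None, :], axis=1).sum())


def e_step(x, v: GMMParams) -> np.ndarray:
    """Responsibilities ẑ (n×G, row-stochastic), computed in log-space."""
    logphi = _log_component_densities(x, v)
    logw = logphi + np.log(v.weights)[None, :]
    lse = logsumexp(logw, axis=1, keepdims=True)
    z = np.exp(logw - lse)
    bad = ~np.isfinite(lse[:, 0])
    if np.any(bad):
        import warnings

        warnings.warn("density underflow for some points; using uniform "
                      "responsibilities there", RuntimeWarning, stacklevel=2)
        z[bad] = 1.0 / v.G
    return z


def m_step(x, z, variance_mode: str = "ng-1",
           var_floor_frac: float = 1e-10) -> GMMParams:
    """Weighted parameter updates from responsibilities.

    ``variance_mode="ng-1"`` divides the weighted squared deviations by
    n_g − 1 (the default); ``"ng"`` divides by n_g (the EM maximizer).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    n, G = z.shape
    ng = z.sum(axis=0)
    if np.any(ng <= 1.0):
        raise ComponentCollapseError(
            f"component effective sizes {ng} include values <= 1")
    weights = ng / n
    means = (z * x[:, None]).sum(axis=0) / ng
    sq = (z * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
    if variance_mode == "ng-1":
        variances = sq / (ng - 1.0)
    elif variance_mode == "ng":
        variances = sq / ng
    else:
        raise ValueError("variance_mode must be 'ng-1' or 'ng'")
    floor = var_floor_frac * float(np.var(x))
    variances = np.maximum(variances, max(floor, 1e-300))
    return GMMParams(weights / weights.sum(), means, variances)


@dataclass
class EMResult:
    params: GMMParams
    log_likelihood: float
    trajectory: np.ndarray  # observed log-likelihood per iteration
    n_iter: int
    converged: bool


def _init_params(x: np.ndarray, G: int, rng: np.random.Generator,
                 perturb: bool) -> GMMParams:
    # k-quantile means, pooled variance, uniform weights
    qs = (np.arange(1, G + 1) - 0.5) / G
    means = np.quantile(x, qs)
    if perturb:
        means = means + rng.normal(0, np.std(x) / max(G, 2), size=G)
    var = np.full(G, np.var(x) / max(G, 1) + 1e-12)
    weights = np.full(G, 1.0 / G)
    return GMMParams(weights, means, np.maximum(var, 1e-12))


def fit_em(x, G: int, seed=None, max_iter: int = 500, tol: float = 1e-8,
           restarts: int = 10, variance_mode: str = "ng-1") -> EMResult:
    """Fit a G-component normal mixture by EM with random restarts.

    The first restart starts from k-quantile means with pooled variance
    and uniform weights; subsequent restarts perturb the means.  The best
    restart by observed log-likelihood wins.  Components are reported
    sorted by mean ascending.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * G:
        raise ValueError(f"need n >= 10*G = {10 * G}, got {len(x)}")
    if G == 1:
        # closed form: weight 1, sample mean/variance (matching the M-step)
        z = np.ones((len(x), 1))
        params = m_step(x, z, variance_mode=variance_mode)
        ll = observed_log_likelihood(x, params)
        return EMResult(params, ll, np.array([ll]), 1, True)

    rng = np.random.default_rng(seed)
    best: EMResult | None = None
    for r in range(restarts):
        params = _init_params(x, G, rng, perturb=(r > 0))
        traj = []
        converged = False
        prev = -np.inf
        try:
            for _ in range(max_iter):
                # fused E-step: densities evaluated once per iteration
                logw = (_log_component_densities(x, params)
                        + np.log(params.weights)[None, :])
                m = logw.max(axis=1, keepdims=True)
                lse = m + np.log(np.exp(logw - m).sum(axis=1, keepdims=True))
                ll = float(lse.sum())
                traj.append(ll)
                if ll - prev < tol and np.isfinite(prev):
                    converged = True
                    break
                prev = ll
                z = np.exp(logw - lse)
                bad = ~np.isfinite(lse[:, 0])
                if np.any(bad):
                    z[bad] = 1.0 / G
                params = m_step(x, z, variance_mode=variance_mode)
        except ComponentCollapseError:
            if not traj:
                continue
        result = EMResult(params.sorted_by_mean(), traj[-1],
                          np.asarray(traj), len(traj), converged)
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    if best is None:
        raise ComponentCollapseError("every restart collapsed")
    return best


def select_components(x, G_max: int, seed=None, criterion: str = "bic",
                      restarts: int = 5, **kwargs):
    """Fit G = 1..G_max and pick the argmin of BIC (default) or AIC.

    Returns (G*, scores) where scores is the list of criterion values.
    """
    if G_max < 1:
        raise ValueError("G_max must be >= 1")
    x = np.asarray(x, dtype=float)
    n = len(x)
    scores = []
    for G in range(1, G_max + 1):
        res = fit_em(x, G, seed=seed, restarts=restarts, **kwargs)
        p = 3 * G - 1
        if criterion == "bic":
            score = -2 * res.log_likelihood + p * np.log(n)
        elif criterion == "aic":
            score = -2 * res.log_likelihood + 2 * p
        else:
            raise ValueError("criterion must be 'bic' or 'aic'")
        scores.append(float(score))
    return int(np.argmin(scores)) + 1, scores
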