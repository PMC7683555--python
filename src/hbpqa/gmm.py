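"""Two-component Gaussian mixture for in-mask intensity separation.

On an adequate hepatobiliary-phase image the standardized in-mask histogram
is bimodal: a lower component of dark blood vessels and an upper component
of bright parenchyma.  The mixture density is

    p(x) = (1 - pi) g1(x; mu1, sigma1) + pi g2(x; mu2, sigma2),

with pi the weight of component 2 (the brighter parenchyma) and the labeling
convention mu1 <= mu2.  Fitting is plain EM on the voxel sample; because the
sample was standardized to mean 0 / sd 1, the five parameters satisfy two
moment identities,

    (1 - pi) mu1 + pi mu2 = 0
    (1 - pi) (sigma1^2 + mu1^2) + pi (sigma2^2 + mu2^2) = 1,

so (mu1, sigma1, pi) already determine the mixture; those three scalars are
the intensity features.  The identities are checked, never enforced during
EM — they are consequences of standardization, and hold exactly only in the
large-N / moment-matched limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "GMMParams",
    "EMTrace",
    "e_step",
    "m_step",
    "em_fit",
    "gmm_features",
    "constraint_residuals",
    "reconstruct_from_features",
]


@dataclass(frozen=True)
class GMMParams:
    """Mixture parameters; ``pi`` is the weight of component 2."""

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    pi: float

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigmas must be positive")
        if not 0 < self.pi < 1:
            raise ValueError("pi must lie strictly in (0, 1)")

    @property
    def is_labeled(self) -> bool:
        """True when components follow the mu1 <= mu2 convention."""
        return self.mu1 <= self.mu2

    def relabel(self) -> "GMMParams":
        """Return parameters with components ordered so mu1 <= mu2."""
        if self.is_labeled:
            return self
        return GMMParams(mu1=self.mu2, sigma1=self.sigma2,
                         mu2=self.mu1, sigma2=self.sigma1, pi=1 - self.pi)


@dataclass
class EMTrace:
    log_likelihood: list[float]
    iterations: int
    converged: bool
    restarts: int = 0

    def to_json(self, path: str) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({"log_likelihood": self.log_likelihood,
                       "iterations": self.iterations,
                       "converged": self.converged,
                       "restarts": self.restarts}, fh)


def _log_densities(x: np.ndarray, p: GMMParams) -> tuple[np.ndarray, np.ndarray]:
    l1 = norm.logpdf(x, p.mu1, p.sigma1) + np.log1p(-p.pi)
    l2 = norm.logpdf(x, p.mu2, p.sigma2) + np.log(p.pi)
    return l1, l2


def log_likelihood(x: np.ndarray, p: GMMParams) -> float:
    """Mixture log-likelihood of the sample."""
    l1, l2 = _log_densities(np.asarray(x, float), p)
    return float(logsumexp(np.stack([l1, l2]), axis=0).sum())


def e_step(x: np.ndarray, p: GMMParams) -> np.ndarray:
    """Posterior probability of component 2 per voxel, in log space.

    The max-log shift inside :func:`scipy.special.logsumexp` guarantees a
    finite posterior even where both component densities underflow.
    """
    x = np.asarray(x, float)
    l1, l2 = _log_densities(x, p)
    denom = logsumexp(np.stack([l1, l2]), axis=0)
    return np.exp(l2 - denom)


def m_step(x: np.ndarray, p2: np.ndarray) -> GMMParams:
    """Weighted means, variances and class probability from posteriors."""
    x = np.asarray(x, float)
    p2 = np.asarray(p2, float)
    w2 = p2.sum()
    w1 = (1.0 - p2).sum()
    if w1 < 1e-10 or w2 < 1e-10:
        raise ValueError("degenerate component: total posterior weight ~ 0")
    mu1 = float(((1 - p2) * x).sum() / w1)
    mu2 = float((p2 * x).sum() / w2)
    var1 = float(((1 - p2) * (x - mu1) ** 2).sum() / w1)
    var2 = float((p2 * (x - mu2) ** 2).sum() / w2)
    # scale-relative variance floor: a component sitting on an atom of a
    # discrete sample (e.g. a noiseless two-intensity image) would otherwise
    # collapse to sigma = 0 and an unbounded likelihood
    var_floor = (1e-4 * float(x.std())) ** 2
    var1 = max(var1, var_floor)
    var2 = max(var2, var_floor)
    pi = float(w2 / len(x))
    return GMMParams(mu1=mu1, sigma1=float(np.sqrt(var1)),
                     mu2=mu2, sigma2=float(np.sqrt(var2)), pi=pi)


def _default_init(x: np.ndarray) -> GMMParams:
    """Deterministic quantile-split init: means at the 25th/75th
    percentiles, equal sigmas, pi = 0.5."""
    q25, q75 = np.percentile(x, [25, 75])
    sd = float(x.std())
    if q75 <= q25:
        q25, q75 = q25 - 0.5 * sd, q25 + 0.5 * sd
    return GMMParams(mu1=float(q25), sigma1=max(sd, 1e-3),
                     mu2=float(q75), sigma2=max(sd, 1e-3), pi=0.5)


def em_fit(
    x: np.ndarray,
    init: GMMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    max_restarts: int = 5,
) -> tuple[GMMParams, EMTrace]:
    """Fit the 2-component mixture by EM.

    Alternates E and M steps until the relative log-likelihood change drops
    below *tol*; components are relabeled afterwards so mu1 <= mu2.  On
    variance collapse (sigma < 1e-6) the fit restarts from a deterministic
    perturbation of the init, at most *max_restarts* times.
    """
    x = np.asarray(x, float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if x.std() == 0:
        raise ValueError("sample variance is zero")

    base_init = init or _default_init(x)
    restarts = 0
    while True:
        params = base_init
        if restarts > 0:
            # deterministic perturbation; grows with the restart count
            shift = 0.5 * x.std() * restarts
            params = GMMParams(
                mu1=base_init.mu1 - shift, sigma1=base_init.sigma1,
                mu2=base_init.mu2 + shift, sigma2=base_init.sigma2,
                pi=base_init.pi,
            )
        try:
            params, trace = _em_loop(x, params, tol, max_iter)
            trace.restarts = restarts
            return params.relabel(), trace
        except _VarianceCollapse:
            restarts += 1
            if restarts > max_restarts:
                raise ValueError(
                    f"variance collapse persisted over {max_restarts} restarts")


class _VarianceCollapse(Exception):
    pass


def _em_loop(x, params, tol, max_iter) -> tuple[GMMParams, EMTrace]:
    ll_hist = [log_likelihood(x, params)]
    converged = False
    for _ in range(max_iter):
        p2 = e_step(x, params)
        params = m_step(x, p2)
        if params.sigma1 < 1e-6 or params.sigma2 < 1e-6:
            raise _VarianceCollapse
        ll = log_likelihood(x, params)
        ll_hist.append(ll)
        if abs(ll - ll_hist[-2]) <= tol * (abs(ll_hist[-2]) + 1e-12):
            # the symmetric fixed point mu1 == mu2 is stationary but never a
            # useful two-component fit; escape it via a perturbed restart
            if abs(params.mu1 - params.mu2) < 1e-8 * (x.std() + 1e-12):
                raise _VarianceCollapse
            converged = True
            break
    return params, EMTrace(log_likelihood=ll_hist,
                           iterations=len(ll_hist) - 1, converged=converged)


def gmm_features(p: GMMParams) -> tuple[float, float, float]:
    """The three intensity features (mu1, sigma1, pi).

    Requires labeled parameters (mu1 <= mu2): component 1 is the darker
    vessel class, and the remaining two parameters are recoverable from the
    standardization moment identities.
    """
    if not p.is_labeled:
        raise ValueError("parameters must be labeled with mu1 <= mu2")
    return (p.mu1, p.sigma1, p.pi)


def constraint_residuals(p: GMMParams) -> tuple[float, float]:
    """Residuals of the two standardization moment identities
    (first moment - 0, second moment - 1)."""
    m1 = (1 - p.pi) * p.mu1 + p.pi * p.mu2
    m2 = (1 - p.pi) * (p.sigma1 ** 2 + p.mu1 ** 2) + \
        p.pi * (p.sigma2 ** 2 + p.mu2 ** 2)
    return (float(m1), float(m2 - 1.0))


def reconstruct_from_features(mu1: float, sigma1: float, pi: float) -> GMMParams:
    """Solve the two moment identities for (mu2, sigma2) given the feature
    triple; valid for samples that are exactly standardized."""
    mu2 = -(1 - pi) * mu1 / pi
    var2 = (1.0 - (1 - pi) * (sigma1 ** 2 + mu1 ** 2)) / pi - mu2 ** 2
    if var2 <= 0:
        raise ValueError("identities admit no positive sigma2 for this triple")
    return GMMParams(mu1=mu1, sigma1=sigma1, mu2=float(mu2),
                     sigma2=float(np.sqrt(var2)), pi=pi)
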