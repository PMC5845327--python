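"""One- and two-tissue mixture sub-models fit by EM on the pseudo-likelihood.

The K-tissue hierarchical model says a gene-SNP pair's z-statistic vector
is a 2^K-component Gaussian mixture, one component per eQTL configuration
gamma, with covariance Delta + Sigma o (gamma gamma') (o = elementwise).
The scalable strategy never fits that model directly: it fits every
two-tissue restriction (a 4-component bivariate mixture over the
configurations 00, 01, 10, 11) and every one-tissue restriction (a
2-component scalar mixture), and later stitches the pieces together.

The pseudo-likelihood treats the N gene-SNP pairs as independent; EM
maximizes it locally. The EM here uses posterior-weighted moment matching
for the structured covariances:

* E-step: w[l, g] ∝ p(g) * phi2(z_l; 0, cov_g).
* M-step: p(g) = mean_l w[l, g]; the null correlation delta comes from the
  w00-weighted second moment of z rescaled to unit diagonal; the effect
  variances sigma_kk come from the weighted second moments of components
  where tissue k is active, minus the unit null variance; the effect
  covariance sigma_12 comes from the w11-weighted cross moment minus delta.

These updates are consistent (each weighted moment estimates the
corresponding conditional moment by the tower property) but are not a
provable ascent step, so each covariance proposal is accepted only when
it does not lower the pseudo-likelihood (generalized EM); the trace is
therefore non-decreasing by construction, and a sentinel raises if it
ever drops beyond slack, which would indicate a numerical defect.

Two refinements keep the fit away from a well-known ridge of the
likelihood. First, the effect variances are floored at ``min_sigma``
(default 0.5): an "eQTL" component whose effect variance tends to zero is
an exact clone of the null component, along which direction the mixture
weights are unidentifiable. Second, after each covariance update the
mixture weights are refined by weight-only EM iterations, which reuse the
already-computed component densities (so they are cheap) and are exactly
ascent steps for fixed components; without them the weights drain off a
clone-like component geometrically slowly and the fit can stop near its
starting weights on data with little or no signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .data import ZMatrix

__all__ = [
    "PairwiseFit", "SingleFit", "PairwiseMixtureEM", "SingleTissueEM",
    "em_fit_pair", "em_fit_single", "pair_loglik", "fit_all_pairs",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_PROB_FLOOR = 1e-12
_VAR_FLOOR = 1e-8
# slack (relative to |loglik|) allowed before a decrease is deemed a bug
_ASCENT_SLACK = 1e-6

# configuration order: first digit = lower-indexed tissue
_CONFIGS2 = ("00", "01", "10", "11")


@dataclass
class PairwiseFit:
    """Estimated two-tissue sub-model for one tissue pair (i < j)."""

    tissues: tuple            # (i, j), 0-based indices
    p: np.ndarray             # probabilities over (00, 01, 10, 11)
    delta: float              # null cross-correlation
    sigma: np.ndarray         # 2x2 effect covariance
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iter: int = 0
    converged: bool = False

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        validate_pair_params(self.p, self.delta, self.sigma)

    def to_dict(self) -> dict:
        return {
            "tissues": list(self.tissues),
            "p": self.p.tolist(),
            "delta": float(self.delta),
            "sigma": self.sigma.tolist(),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairwiseFit":
        return cls(tuple(d["tissues"]), np.asarray(d["p"]),
                   float(d["delta"]), np.asarray(d["sigma"]),
                   n_iter=int(d.get("n_iter", 0)),
                   converged=bool(d.get("converged", False)))


@dataclass
class SingleFit:
    """Estimated one-tissue sub-model: z ~ (1-p1) N(0,1) + p1 N(0, 1+sigma)."""

    tissue: int
    p1: float
    sigma: float
    n_iter: int = 0
    converged: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p1 <= 1.0):
            raise ValueError("p1 must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def to_dict(self) -> dict:
        return {"tissue": int(self.tissue), "p1": float(self.p1),
                "sigma": float(self.sigma), "n_iter": int(self.n_iter),
                "converged": bool(self.converged)}

    @classmethod
    def from_dict(cls, d: dict) -> "SingleFit":
        return cls(int(d["tissue"]), float(d["p1"]), float(d["sigma"]),
                   int(d.get("n_iter", 0)), bool(d.get("converged", False)))


def validate_pair_params(p, delta, sigma) -> None:
    p = np.asarray(p, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if p.shape != (4,):
        raise ValueError("p must have 4 entries (00, 01, 10, 11)")
    if np.any(p < -1e-15) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p entries must be >= 0 and sum to 1")
    if not -1.0 < delta < 1.0:
        raise ValueError("delta must lie in (-1, 1)")
    if sigma.shape != (2, 2):
        raise ValueError("sigma must be 2x2")
    if abs(sigma[0, 1] - sigma[1, 0]) > 1e-12:
        raise ValueError("sigma must be symmetric")
    if sigma[0, 0] < 0 or sigma[1, 1] < 0:
        raise ValueError("sigma diagonal must be >= 0")
    if sigma[0, 1] ** 2 > sigma[0, 0] * sigma[1, 1] * (1 + 1e-9) + 1e-15:
        raise ValueError("sigma must be positive semi-definite")


def _component_covs(delta: float, sigma: np.ndarray) -> np.ndarray:
    """(4, 3) array of (a, b, c) = (var1, var2, cov) per configuration."""
    s11, s12, s22 = sigma[0, 0], sigma[0, 1], sigma[1, 1]
    return np.array([
        [1.0, 1.0, delta],                       # 00
        [1.0, 1.0 + s22, delta],                 # 01
        [1.0 + s11, 1.0, delta],                 # 10
        [1.0 + s11, 1.0 + s22, delta + s12],     # 11
    ])


def _weight_em_pass(dens: np.ndarray, p: np.ndarray) -> np.ndarray:
    mix = dens @ p
    p_new = np.maximum((dens * p / mix[:, None]).mean(axis=0), _PROB_FLOOR)
    return p_new / p_new.sum()


def _optimize_weights(dens: np.ndarray, p: np.ndarray,
                      max_cycles: int = 50) -> np.ndarray:
    """Maximize sum(log(dens @ p)) over the probability simplex.

    Weight-only EM is globally convergent here but geometrically slow
    when a component's density nearly coincides with another's; each
    cycle therefore applies a squared-extrapolation (SQUAREM-style)
    acceleration of the EM map, falling back to the plain double EM step
    whenever the extrapolated point does not improve the objective.
    """
    def ll(q):
        return float(np.log(dens @ q).sum())

    cur = ll(p)
    for _ in range(max_cycles):
        p1 = _weight_em_pass(dens, p)
        p2 = _weight_em_pass(dens, p1)
        r = p1 - p
        v = p2 - p1 - r
        nr, nv = np.linalg.norm(r), np.linalg.norm(v)
        if nr < 1e-13:
            p = p2
            break
        cand = p2
        if nv > 1e-300:
            alpha = -nr / nv
            pa = p - 2.0 * alpha * r + alpha * alpha * v
            if np.all(pa > 0):
                pa = np.maximum(pa, _PROB_FLOOR)
                pa = pa / pa.sum()
                pa = _weight_em_pass(dens, pa)   # stabilizing EM pass
                if ll(pa) >= ll(p2):
                    cand = pa
        nxt = ll(cand)
        p = cand
        if nxt - cur < 1e-10 * max(1.0, abs(cur)):
            cur = nxt
            break
        cur = nxt
    return p


def _bvn_logpdf(z: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    det = a * b - c * c
    if det <= 0 or a <= 0 or b <= 0:
        raise ValueError(f"invalid 2x2 covariance (det={det:.3g})")
    z1, z2 = z[:, 0], z[:, 1]
    quad = (b * z1 * z1 - 2.0 * c * z1 * z2 + a * z2 * z2) / det
    return -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad


def _log_component_densities(z: np.ndarray, delta: float,
                             sigma: np.ndarray) -> np.ndarray:
    covs = _component_covs(delta, sigma)
    return np.column_stack([_bvn_logpdf(z, *covs[g]) for g in range(4)])


def pair_loglik(params, z2: np.ndarray) -> float:
    """Pseudo-log-likelihood of a two-tissue sub-model on an (N, 2) array.

    ``params`` is a :class:`PairwiseFit` or any object with attributes
    ``p``, ``delta``, ``sigma``. Stable for |z| up to ~40 (log-sum-exp).
    """
    z2 = np.asarray(z2, dtype=float)
    if z2.ndim != 2 or z2.shape[1] != 2:
        raise ValueError("z2 must be (N, 2)")
    p = np.asarray(params.p, dtype=float)
    validate_pair_params(p, params.delta, np.asarray(params.sigma))
    logd = _log_component_densities(z2, float(params.delta),
                                    np.asarray(params.sigma, dtype=float))
    with np.errstate(divide="ignore"):
        lw = logd + np.log(np.maximum(p, 0.0))[None, :]
    return float(logsumexp(lw, axis=1).sum())


class PairwiseMixtureEM(BaseEstimator):
    """EM for the two-tissue 4-component eQTL mixture.

    Parameters
    ----------
    tol : float
        Relative pseudo-log-likelihood change declaring convergence.
    max_iter : int
    init : dict or None
        Optional overrides for the starting point: keys among
        ``p`` (4-vector), ``delta`` (float), ``sigma`` (2x2).
    min_sigma : float
        Lower bound on the effect variances sigma_kk; keeps the
        alternative components distinguishable from the null.
    n_inner : int
        Maximum accelerated weight-refinement cycles per outer iteration.

    Attributes
    ----------
    p_ : (4,) ndarray over configurations (00, 01, 10, 11)
    delta_ : float
    sigma_ : (2, 2) ndarray
    loglik_trace_ : ndarray of per-iteration pseudo-log-likelihoods
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500,
                 init: dict | None = None, min_sigma: float = 0.5,
                 n_inner: int = 50):
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.min_sigma = min_sigma
        self.n_inner = n_inner

    def _initial_params(self, z):
        p = np.array([0.90, 0.02, 0.02, 0.06])
        calm = (np.abs(z[:, 0]) < 2) & (np.abs(z[:, 1]) < 2)
        zc = z[calm] if calm.sum() >= 10 else z
        delta = float(np.corrcoef(zc[:, 0], zc[:, 1])[0, 1])
        if not np.isfinite(delta):
            delta = 0.0
        delta = float(np.clip(delta, -0.99, 0.99))
        v = np.maximum(z.var(axis=0) - 1.0, 0.5)
        s12 = 0.7 * np.sqrt(v[0] * v[1])
        sigma = np.array([[v[0], s12], [s12, v[1]]])
        if self.init:
            p = np.asarray(self.init.get("p", p), dtype=float)
            delta = float(self.init.get("delta", delta))
            sigma = np.asarray(self.init.get("sigma", sigma), dtype=float)
        return p, delta, sigma

    def fit(self, X, y=None):
        z = np.asarray(X, dtype=float)
        if z.ndim != 2 or z.shape[1] != 2:
            raise ValueError("X must be (N, 2)")
        if not np.all(np.isfinite(z)):
            raise ValueError("X contains non-finite values")
        if z.shape[0] < 1000:
            warnings.warn(
                f"only {z.shape[0]} rows; mixture estimates may be "
                "unstable below ~1000", RuntimeWarning)
        p, delta, sigma = self._initial_params(z)
        validate_pair_params(p, delta, sigma)

        trace = []
        converged = False
        logd = _log_component_densities(z, delta, sigma)
        shift = logd.max(axis=1)
        dens = np.exp(logd - shift[:, None])            # safe: max is 0
        mix = dens @ p
        for it in range(self.max_iter):
            ll = float((np.log(mix) + shift).sum())
            if trace:
                slack = _ASCENT_SLACK * max(1.0, abs(trace[-1]))
                if ll < trace[-1] - slack:
                    raise RuntimeError(
                        f"EM pseudo-log-likelihood decreased at iteration "
                        f"{it}: {trace[-1]:.6f} -> {ll:.6f}")
            trace.append(ll)
            if len(trace) > 1:
                rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
                if rel < self.tol:
                    converged = True
                    break

            # M-step for the weights: solve the weight subproblem (a
            # concave program over the simplex) on the fixed component
            # densities with accelerated EM
            p = _optimize_weights(dens, p, max_cycles=self.n_inner)
            mix = dens @ p
            w = dens * p / mix[:, None]
            ll_weights = float((np.log(mix) + shift).sum())

            # proposed covariance update from posterior-weighted moments
            z1, z2c = z[:, 0], z[:, 1]
            w0 = w[:, 0]
            s0 = w0.sum()
            m11 = (w0 * z1 * z1).sum() / s0
            m22 = (w0 * z2c * z2c).sum() / s0
            m12 = (w0 * z1 * z2c).sum() / s0
            delta_p = float(np.clip(m12 / np.sqrt(m11 * m22),
                                    -1 + 1e-9, 1 - 1e-9))
            wa1 = w[:, 2] + w[:, 3]          # tissue 1 active: 10, 11
            wa2 = w[:, 1] + w[:, 3]          # tissue 2 active: 01, 11
            s11 = max((wa1 * z1 * z1).sum() / wa1.sum() - 1.0,
                      self.min_sigma)
            s22 = max((wa2 * z2c * z2c).sum() / wa2.sum() - 1.0,
                      self.min_sigma)
            w3 = w[:, 3]
            cross = (w3 * z1 * z2c).sum() / w3.sum()
            s12 = cross - delta_p
            bound = (1 - _VAR_FLOOR) * np.sqrt(s11 * s22)
            s12 = float(np.clip(s12, -bound, bound))
            sigma_p = np.array([[s11, s12], [s12, s22]])

            # moment matching is not a provable ascent step: accept the
            # proposal only if it does not lower the objective, else keep
            # the current covariances for this round (generalized EM)
            logd_p = _log_component_densities(z, delta_p, sigma_p)
            shift_p = logd_p.max(axis=1)
            dens_p = np.exp(logd_p - shift_p[:, None])
            mix_p = dens_p @ p
            ll_prop = float((np.log(mix_p) + shift_p).sum())
            if ll_prop >= ll_weights:
                delta, sigma = delta_p, sigma_p
                shift, dens, mix = shift_p, dens_p, mix_p

        self.p_ = p
        self.delta_ = delta
        self.sigma_ = sigma
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        self.converged_ = converged
        return self

    def score(self, X, y=None) -> float:
        """Mean pseudo-log-likelihood per row under the fitted parameters."""
        fit = PairwiseFit((0, 1), self.p_, self.delta_, self.sigma_)
        return pair_loglik(fit, X) / np.asarray(X).shape[0]


class SingleTissueEM(BaseEstimator):
    """EM for the scalar mixture (1 - p1) N(0, 1) + p1 N(0, 1 + sigma).

    The null variance is fixed at 1 by the Fisher-transform scaling; only
    the eQTL proportion ``p1_`` and excess variance ``sigma_`` are free.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500,
                 init: dict | None = None, min_sigma: float = 0.5,
                 n_inner: int = 50):
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.min_sigma = min_sigma
        self.n_inner = n_inner

    def fit(self, X, y=None):
        z = np.asarray(X, dtype=float).ravel()
        if not np.all(np.isfinite(z)):
            raise ValueError("X contains non-finite values")
        p1 = 0.1
        sigma = max(float(z.var()) - 1.0, self.min_sigma)
        if self.init:
            p1 = float(self.init.get("p1", p1))
            sigma = max(float(self.init.get("sigma", sigma)), _VAR_FLOOR)

        trace = []
        converged = False
        zz = z * z
        log_null = -0.5 * (_LOG2PI + zz)
        for it in range(self.max_iter):
            v = 1.0 + sigma
            log_alt = -0.5 * (_LOG2PI + np.log(v) + zz / v)
            logd = np.column_stack([log_null, log_alt])
            shift = logd.max(axis=1)
            dens = np.exp(logd - shift[:, None])
            p = np.array([1 - p1, p1])
            mix = dens @ p
            ll = float((np.log(mix) + shift).sum())
            if trace:
                slack = _ASCENT_SLACK * max(1.0, abs(trace[-1]))
                if ll < trace[-1] - slack:
                    raise RuntimeError(
                        f"EM pseudo-log-likelihood decreased at iteration "
                        f"{it}: {trace[-1]:.6f} -> {ll:.6f}")
            trace.append(ll)
            if len(trace) > 1:
                rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
                if rel < self.tol:
                    converged = True
                    break
            p = _optimize_weights(dens, p, max_cycles=self.n_inner)
            mix = dens @ p
            w = dens * p / mix[:, None]
            p1 = float(p[1])
            w1 = w[:, 1]
            sigma = max((w1 * zz).sum() / w1.sum() - 1.0, self.min_sigma)

        self.p1_ = p1
        self.sigma_ = sigma
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        self.converged_ = converged
        return self


def em_fit_pair(z2: np.ndarray, init: dict | None = None, tol: float = 1e-6,
                max_iter: int = 500, tissues: tuple = (0, 1),
                **kwargs) -> PairwiseFit:
    """Fit the two-tissue mixture sub-model; thin wrapper over
    :class:`PairwiseMixtureEM`."""
    est = PairwiseMixtureEM(tol=tol, max_iter=max_iter, init=init,
                            **kwargs).fit(z2)
    return PairwiseFit(tuple(tissues), est.p_, est.delta_, est.sigma_,
                       loglik_trace=est.loglik_trace_, n_iter=est.n_iter_,
                       converged=est.converged_)


def em_fit_single(z1: np.ndarray, tol: float = 1e-6, max_iter: int = 500,
                  tissue: int = 0, init: dict | None = None,
                  **kwargs) -> SingleFit:
    """Fit the one-tissue sub-model; thin wrapper over
    :class:`SingleTissueEM`."""
    est = SingleTissueEM(tol=tol, max_iter=max_iter, init=init,
                         **kwargs).fit(z1)
    return SingleFit(tissue, est.p1_, est.sigma_, est.n_iter_, est.converged_)


def _fit_one_pair(Z, mask, i, j, names, tol, max_iter):
    if mask.sum() < 100:
        raise ValueError(
            f"tissue pair ({names[i]}, {names[j]}) has only "
            f"{int(mask.sum())} complete rows (< 100)")
    return em_fit_pair(Z[mask][:, [i, j]], tol=tol, max_iter=max_iter,
                       tissues=(i, j))


def fit_all_pairs(zmat: ZMatrix, tol: float = 1e-6, max_iter: int = 500,
                  n_jobs: int = 1) -> tuple:
    """Fit every unordered tissue pair (and every single tissue) by EM.

    Pairs are ordered (0,1), (0,2), ..., (K-2, K-1); each uses the rows
    complete in both of its tissues. Fits are mutually independent, so the
    result is identical for any worker count.

    Returns
    -------
    (pair_fits, single_fits) : lists of :class:`PairwiseFit`,
    :class:`SingleFit`
    """
    K = zmat.K
    if K < 2:
        raise ValueError("need at least two tissues")
    Z = zmat.Z
    names = zmat.panel.tissue_names
    jobs = []
    for i in range(K):
        for j in range(i + 1, K):
            mask = zmat.complete_mask([i, j])
            jobs.append((mask, i, j))
    pair_fits = Parallel(n_jobs=n_jobs)(
        delayed(_fit_one_pair)(Z, mask, i, j, names, tol, max_iter)
        for mask, i, j in jobs)
    single_fits = []
    for k in range(K):
        mask = zmat.complete_mask([k])
        single_fits.append(em_fit_single(Z[mask, k], tol=tol,
                                         max_iter=max_iter, tissue=k))
    return list(pair_fits), single_fits
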