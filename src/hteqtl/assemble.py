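"""Stitch pairwise sub-model fits into one K-tissue model.

Three ingredients, each estimated from the K(K-1)/2 two-tissue fits:

* Delta — off-diagonal (i, j) is the pairwise null correlation delta^ij;
  projected to the nearest correlation matrix if indefinite.
* Sigma — each diagonal sigma_kk is the *minimum* of its K-1 pairwise
  estimates (the heavy-tailed z distribution inflates pairwise variance
  estimates, and the minimum compensates); the correlation part is
  assembled like Delta from the pairwise effect correlations.
* p(.) — a multi-Probit construction: each pairwise 2x2 configuration
  table is matched exactly by thresholds (tau1, tau2) and a latent
  correlation omega for a bivariate normal; the per-tissue thresholds
  are aggregated by minimum, the omegas form a correlation matrix Omega,
  and the K-tissue prior is the orthant mass of N(0, Omega) over the
  thresholds. Probabilities below `trunc` (default 1e-5) are dropped and
  the survivors renormalized.

The exact orthant computation evaluates the 2^K marginal-subset normal
CDFs once and obtains every configuration mass by a signed
(Moebius-type) difference transform. Because all masses derive from the
same shared CDF values, they form an exact partition of unity up to
floating-point rounding — the pre-truncation masses sum to 1 by
construction, not by renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm, qmc

from .data import TissuePanel
from .model import HTModel, check_psd
from .pairwise import PairwiseFit, SingleFit

__all__ = [
    "ProbitPair", "nearest_correlation", "bvn_upper_orthant",
    "probit_invert_pair", "assemble_delta", "assemble_sigma",
    "assemble_prior", "assemble_model",
]


@dataclass(frozen=True)
class ProbitPair:
    """Bivariate-Probit match of one pairwise configuration table."""

    tissues: tuple
    tau1: float
    tau2: float
    omega: float

    def __post_init__(self):
        if not (0.0 <= self.omega < 1.0):
            raise ValueError("omega must lie in [0, 1)")
        if not (np.isfinite(self.tau1) and np.isfinite(self.tau2)):
            raise ValueError("thresholds must be finite")


def nearest_correlation(M: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a correlation matrix.

    Eigendecompose, clip negative eigenvalues to zero, reconstruct, then
    rescale to unit diagonal. A valid correlation matrix is a fixed
    point (up to rounding).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if not np.all(np.isfinite(M)):
        raise ValueError("M must be finite")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("M must be symmetric")
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    w = np.clip(w, 0.0, None)
    R = (V * w) @ V.T
    d = np.diag(R).copy()
    if np.any(d <= 0):
        raise ValueError(
            "zero diagonal after eigenvalue clipping; cannot rescale")
    s = 1.0 / np.sqrt(d)
    R = R * np.outer(s, s)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def _corr_or_project(M: np.ndarray) -> np.ndarray:
    """Return M if already a valid correlation matrix, else project."""
    w = np.linalg.eigvalsh((M + M.T) / 2.0)
    if w.min() >= -1e-12:
        return (M + M.T) / 2.0
    return nearest_correlation(M)


def bvn_upper_orthant(tau1: float, tau2: float, omega: float) -> float:
    """P(W1 > tau1, W2 > tau2) for standard bivariate normal, corr omega.

    Evaluated as the 1-d integral of phi(x) * Phi-bar((tau2 - omega x) /
    sqrt(1 - omega^2)) over (tau1, inf); deterministic and accurate to
    ~1e-12.
    """
    if abs(omega) >= 1.0 - 1e-12:
        if omega > 0:
            return float(norm.sf(max(tau1, tau2)))
        return float(max(0.0, norm.cdf(-tau2) - norm.cdf(tau1)))
    s = np.sqrt(1.0 - omega * omega)

    def integrand(x):
        return norm.pdf(x) * norm.sf((tau2 - omega * x) / s)

    val, _ = integrate.quad(integrand, tau1, np.inf,
                            epsabs=1e-13, epsrel=1e-11, limit=200)
    return float(min(max(val, 0.0), 1.0))


def probit_invert_pair(p2: np.ndarray, tissues: tuple = (0, 1)
                       ) -> ProbitPair:
    """Invert a 2x2 configuration table to Probit parameters.

    ``p2`` is ordered (p00, p01, p10, p11) with the first digit the
    lower-indexed tissue. Thresholds match the marginals exactly:
    tau1 = Phi^-1(p00 + p01), tau2 = Phi^-1(p00 + p10); omega is solved
    so the upper orthant above (tau1, tau2) equals p11 (residual < 1e-8).
    If p11 falls outside the range attainable for omega in [0, 1), omega
    is clamped to the nearest endpoint with a warning.
    """
    p2 = np.asarray(p2, dtype=float)
    if p2.shape != (4,):
        raise ValueError("p2 must have 4 entries (p00, p01, p10, p11)")
    if np.any(p2 <= 0) or abs(p2.sum() - 1.0) > 1e-9:
        raise ValueError("p2 entries must be positive and sum to 1")
    tau1 = float(norm.ppf(p2[0] + p2[1]))
    tau2 = float(norm.ppf(p2[0] + p2[2]))
    p11 = float(p2[3])
    hi = 1.0 - 1e-6

    def f(om):
        return bvn_upper_orthant(tau1, tau2, om) - p11

    f0, fhi = f(0.0), f(hi)
    if abs(f0) < 1e-12:
        omega = 0.0
    elif f0 > 0:
        warnings.warn(
            f"pair {tissues}: p11={p11:.3g} below the independence orthant; "
            "omega clamped to 0", RuntimeWarning)
        omega = 0.0
    elif fhi < 0:
        warnings.warn(
            f"pair {tissues}: p11={p11:.3g} above the comonotone bound; "
            "omega clamped to 1 - 1e-6", RuntimeWarning)
        omega = hi
    else:
        omega = float(brentq(f, 0.0, hi, xtol=1e-13, rtol=8.9e-16))
        if abs(f(omega)) > 1e-8:
            raise RuntimeError(
                f"pair {tissues}: orthant residual {f(omega):.3g} "
                "exceeds 1e-8")
    return ProbitPair(tuple(tissues), tau1, tau2, omega)


def _pair_index(fits) -> dict:
    idx = {}
    for f in fits:
        i, j = f.tissues
        if i >= j:
            raise ValueError(f"pair fit with non-increasing tissues {f.tissues}")
        idx[(i, j)] = f
    return idx


def _infer_K(fits) -> int:
    return max(j for f in fits for j in f.tissues) + 1


def _require_all_pairs(idx: dict, K: int) -> None:
    for i in range(K):
        for j in range(i + 1, K):
            if (i, j) not in idx:
                raise ValueError(f"missing pairwise fit for tissue pair "
                                 f"({i}, {j})")


def assemble_delta(fits) -> np.ndarray:
    """K x K null correlation matrix from the pairwise delta estimates."""
    K = _infer_K(fits)
    idx = _pair_index(fits)
    _require_all_pairs(idx, K)
    D = np.eye(K)
    for (i, j), f in idx.items():
        D[i, j] = D[j, i] = f.delta
    return _corr_or_project(D)


def assemble_sigma(fits) -> np.ndarray:
    """K x K effect covariance from the pairwise Sigma estimates.

    Diagonal: minimum of the K-1 pairwise variance estimates per tissue.
    Off-diagonal: pairwise effect correlations, projected to a valid
    correlation matrix, then rescaled by the diagonal.
    """
    K = _infer_K(fits)
    idx = _pair_index(fits)
    _require_all_pairs(idx, K)
    var_estimates = [[] for _ in range(K)]
    R = np.eye(K)
    for (i, j), f in idx.items():
        s = f.sigma
        var_estimates[i].append(s[0, 0])
        var_estimates[j].append(s[1, 1])
        R[i, j] = R[j, i] = s[0, 1] / np.sqrt(s[0, 0] * s[1, 1])
    diag = np.array([min(v) for v in var_estimates])
    if np.any(diag <= 0):
        bad = np.nonzero(diag <= 0)[0].tolist()
        raise ValueError(f"non-positive effect variance for tissue(s) {bad}")
    R = _corr_or_project(R)
    sd = np.sqrt(diag)
    S = R * np.outer(sd, sd)
    return (S + S.T) / 2.0


def _orthant_masses_exact(Omega: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """All 2^K configuration masses of N(0, Omega) split at tau.

    Computes the marginal-subset CDFs F[T] = P(X_k <= tau_k, k in T) for
    every subset T, then applies, coordinate by coordinate, the signed
    difference transform (a1, a0 - a1) that turns subset CDFs into
    rectangle masses. Sharing the CDF values makes the masses telescope
    to exactly 1.
    """
    K = len(tau)
    F = np.empty(2 ** K)
    F[0] = 1.0
    for T in range(1, 2 ** K):
        idx = [k for k in range(K) if T >> (K - 1 - k) & 1]
        if len(idx) == 1:
            F[T] = norm.cdf(tau[idx[0]])
        else:
            sub = Omega[np.ix_(idx, idx)]
            # fixed rng: the randomized-QMC quadrature becomes a
            # deterministic rule, so reruns are bit-identical
            F[T] = multivariate_normal.cdf(
                tau[idx], mean=np.zeros(len(idx)), cov=sub,
                allow_singular=True, maxpts=200_000,
                abseps=1e-9, releps=0, rng=np.random.default_rng(0))
    # difference transform: bit k set in the index now means gamma_k = 1
    # (coordinate above tau) instead of "coordinate constrained <= tau"
    a = F.reshape((2,) * K)
    for axis in range(K):
        a0 = np.take(a, 0, axis=axis)   # subsets without coordinate
        a1 = np.take(a, 1, axis=axis)   # subsets with coordinate <= tau
        a = np.stack([a1, a0 - a1], axis=axis)
    return a.reshape(-1)


def _orthant_masses_mc(Omega: np.ndarray, tau: np.ndarray, n_samples: int,
                       seed: int) -> np.ndarray:
    """One quasi-Monte-Carlo sweep tallying all configuration masses."""
    K = len(tau)
    w, V = np.linalg.eigh(Omega)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    sob = qmc.Sobol(d=K, scramble=True, rng=np.random.default_rng(seed))
    powers = 1 << np.arange(K - 1, -1, -1).astype(np.int64)
    counts = np.zeros(2 ** K, dtype=np.int64)
    remaining = int(n_samples)
    chunk = 1 << 18
    while remaining > 0:
        m = min(chunk, remaining)
        u = sob.random(m)
        x = norm.ppf(np.clip(u, 1e-16, 1 - 1e-16)) @ L.T
        codes = ((x > tau[None, :]).astype(np.int64) @ powers)
        counts += np.bincount(codes, minlength=2 ** K)
        remaining -= m
    return counts / counts.sum()


def assemble_prior(probit_pairs, K: int, trunc: float = 1e-5,
                   method: str = "exact", n_samples: int = 10_000_000,
                   seed: int | None = None):
    """Build (Omega, tau, sparse prior) from the per-pair Probit matches.

    Returns
    -------
    Omega : (K, K) correlation matrix of the latent Probit normal
    tau : (K,) aggregate thresholds (per-tissue minimum)
    (configs, probs) : support configurations (M, K) and probabilities,
        truncated at ``trunc`` and renormalized, in bitstring order.
    """
    idx = {tuple(pp.tissues): pp for pp in probit_pairs}
    _require_all_pairs(idx, K)
    W = np.eye(K)
    taus = [[] for _ in range(K)]
    for (i, j), pp in idx.items():
        W[i, j] = W[j, i] = pp.omega
        taus[i].append(pp.tau1)
        taus[j].append(pp.tau2)
    for k, ts in enumerate(taus):
        if max(ts) - min(ts) > 0.5:
            warnings.warn(
                f"tissue {k}: pairwise thresholds span "
                f"[{min(ts):.3f}, {max(ts):.3f}] (range > 0.5); pairwise "
                "sub-models disagree noticeably", RuntimeWarning)
    tau = np.array([min(ts) for ts in taus])
    Omega = _corr_or_project(W)

    if method == "exact":
        if K > 15:
            raise ValueError(
                "exact orthant enumeration limited to K <= 15; use "
                "method='montecarlo'")
        masses = _orthant_masses_exact(Omega, tau)
    elif method in ("montecarlo", "mc"):
        if seed is None:
            raise ValueError("montecarlo orthant method requires a seed")
        masses = _orthant_masses_mc(Omega, tau, n_samples, seed)
    else:
        raise ValueError(f"unknown orthant method {method!r}")

    keep = np.nonzero(masses >= trunc)[0]
    if keep.size == 0:
        raise ValueError("no configuration mass survives truncation")
    probs = masses[keep] / masses[keep].sum()
    configs = ((keep[:, None] >> np.arange(K - 1, -1, -1)[None, :]) & 1
               ).astype(np.int8)
    return Omega, tau, (configs, probs)


def assemble_model(fits, singles=None, panel: TissuePanel | None = None,
                   trunc: float = 1e-5, method: str = "exact",
                   seed: int | None = None,
                   n_samples: int = 10_000_000) -> HTModel:
    """Assemble the K-tissue model from pairwise (and single) fits."""
    K = _infer_K(fits)
    Delta = assemble_delta(fits)
    Sigma = assemble_sigma(fits)
    check_psd(Sigma, "assembled Sigma")
    probit_pairs = [probit_invert_pair(f.p, f.tissues) for f in fits]
    Omega, tau, (configs, probs) = assemble_prior(
        probit_pairs, K, trunc=trunc, method=method, n_samples=n_samples,
        seed=seed)
    provenance = {
        "trunc": float(trunc),
        "orthant_method": method,
        "seed": seed,
        "n_samples": int(n_samples) if method != "exact" else None,
        "support_size": int(len(probs)),
        "n_pair_fits": len(fits),
        "single_fits": None if singles is None else
            [s.to_dict() for s in singles],
    }
    return HTModel(K, configs, probs, Delta, Sigma, Omega, tau, panel,
                   trunc, provenance)
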