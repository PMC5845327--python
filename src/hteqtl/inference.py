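"""Configuration-set lfdr, adaptive FDR thresholding, model summaries.

Multiple testing over gene-SNP pairs is phrased per configuration set S:
H0 "the pair's configuration lies outside S" vs H1 "it lies in S". The
local false discovery rate of a pair is the posterior probability of H0
given its z-vector,

    eta_S(z) = sum_{g in S^c} p(g) f_g(z) / sum_g p(g) f_g(z),

with f_g the N(0, Delta + Sigma o gg') density and sums over the
truncated prior support. The adaptive procedure sorts the lfdrs and
rejects the largest prefix whose running mean stays strictly below the
nominal level alpha, which controls the FDR at alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.linalg import solve_triangular
from scipy.spatial.distance import squareform

from .data import ZMatrix
from .model import HTModel

__all__ = [
    "ConfigSet", "InferenceResult", "lfdr", "adaptive_fdr",
    "marginalize_model", "hamming_class_summary", "tissue_clustering",
    "linkage_to_newick",
]

_KINDS = ("any", "common", "tissue_specific", "in_tissue", "explicit")


@dataclass(frozen=True)
class ConfigSet:
    """A set S of eQTL configurations to test for.

    kind:
      * ``any`` — an eQTL in at least one tissue (gamma != 0)
      * ``common`` — an eQTL in every tissue (gamma == 1)
      * ``tissue_specific`` — in some but not all tissues
      * ``in_tissue`` — an eQTL in tissue ``k`` (gamma_k == 1)
      * ``explicit`` — membership of an explicit list of configurations
    """

    kind: str
    K: int
    k: int | None = None
    configs: tuple = ()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown config-set kind {self.kind!r}")
        if self.kind == "in_tissue":
            if self.k is None or not 0 <= self.k < self.K:
                raise ValueError("in_tissue requires 0 <= k < K")
        if self.kind == "explicit":
            cfgs = tuple(tuple(int(b) for b in c) for c in self.configs)
            for c in cfgs:
                if len(c) != self.K or any(b not in (0, 1) for b in c):
                    raise ValueError(f"invalid configuration {c}")
            object.__setattr__(self, "configs", cfgs)

    @classmethod
    def parse(cls, spec: str, K: int) -> "ConfigSet":
        """Parse 'any', 'common', 'tissue-specific' or 'tissue:<k>'."""
        s = spec.strip().lower().replace("-", "_")
        if s in ("any", "common", "tissue_specific"):
            return cls(s, K)
        if s.startswith("tissue:"):
            return cls("in_tissue", K, k=int(s.split(":", 1)[1]))
        raise ValueError(f"cannot parse config set {spec!r}")

    def contains(self, configs: np.ndarray) -> np.ndarray:
        """Boolean membership for an (M, K) array of configurations."""
        c = np.asarray(configs)
        ones = c.sum(axis=1)
        if self.kind == "any":
            return ones > 0
        if self.kind == "common":
            return ones == self.K
        if self.kind == "tissue_specific":
            return (ones > 0) & (ones < self.K)
        if self.kind == "in_tissue":
            return c[:, self.k] == 1
        explicit = set(self.configs)
        return np.array([tuple(int(b) for b in row) in explicit
                         for row in c])

    def describe(self) -> str:
        if self.kind == "in_tissue":
            return f"in_tissue:{self.k}"
        if self.kind == "explicit":
            return f"explicit[{len(self.configs)}]"
        return self.kind


@dataclass
class InferenceResult:
    """Adaptive-FDR decision for each gene-SNP pair."""

    pair_ids: list
    lfdr: np.ndarray
    alpha: float
    reject: np.ndarray
    n_reject: int = 0
    mean_lfdr_rejected: float = 0.0
    config_set: str = ""

    def __post_init__(self):
        self.lfdr = np.asarray(self.lfdr, dtype=float)
        self.reject = np.asarray(self.reject, dtype=bool)
        self.n_reject = int(self.reject.sum())
        if self.n_reject:
            self.mean_lfdr_rejected = float(self.lfdr[self.reject].mean())
            if not self.mean_lfdr_rejected < self.alpha:
                raise ValueError(
                    "rejected-set mean lfdr must be below alpha")


def _log_densities(Z: np.ndarray, model: HTModel) -> np.ndarray:
    """(N, M) log N(0, Delta + Sigma o gg') densities over the support.

    One Cholesky factorization per supported configuration, reused for
    all rows; stable in log space for |z| up to ~40.
    """
    N, K = Z.shape
    M = model.support_size
    out = np.empty((N, M))
    log2pi = np.log(2.0 * np.pi)
    for m in range(M):
        C = model.config_cov(model.configs[m])
        L = np.linalg.cholesky(C)
        y = solve_triangular(L, Z.T, lower=True)
        quad = (y * y).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, m] = -0.5 * (K * log2pi + logdet + quad)
    return out


def lfdr(zmat, model: HTModel, S: ConfigSet) -> np.ndarray:
    """Local false discovery rate eta_S for every (complete) z row.

    ``zmat`` may be a :class:`ZMatrix` or a plain (N, K) array. Rows must
    be complete; use :func:`marginalize_model` to score rows observed on
    a tissue subset.
    """
    Z = zmat.Z if isinstance(zmat, ZMatrix) else np.asarray(zmat, float)
    if Z.ndim != 2 or Z.shape[1] != model.K:
        raise ValueError(f"z matrix must be (N, {model.K})")
    if np.isnan(Z).any():
        raise ValueError("z rows must be complete (no NaN); drop or "
                         "marginalize first")
    in_S = S.contains(model.configs)
    if not (~in_S).any():
        warnings.warn("null set S^c carries no prior mass; lfdr is 0 "
                      "everywhere", RuntimeWarning)
        return np.zeros(Z.shape[0])
    logd = _log_densities(Z, model)
    logp = np.log(model.probs)
    lw = logd + logp[None, :]
    shift = lw.max(axis=1, keepdims=True)
    w = np.exp(lw - shift)
    num = w[:, ~in_S].sum(axis=1)
    den = w.sum(axis=1)
    return np.clip(num / den, 0.0, 1.0)


def adaptive_fdr(lfdrs: np.ndarray, alpha: float,
                 pair_ids: list | None = None,
                 config_set: str = "") -> InferenceResult:
    """Adaptive lfdr thresholding controlling the FDR at ``alpha``.

    Sort the lfdrs ascending (stable, so ties break by pair index) and
    reject the largest prefix whose running mean is strictly below
    ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    eta = np.asarray(lfdrs, dtype=float)
    if eta.ndim != 1:
        raise ValueError("lfdrs must be 1-dimensional")
    if np.any((eta < 0) | (eta > 1)):
        raise ValueError("lfdrs must lie in [0, 1]")
    if pair_ids is None:
        pair_ids = [("pair", str(i)) for i in range(eta.size)]
    order = np.argsort(eta, kind="stable")
    prefix_means = np.cumsum(eta[order]) / np.arange(1, eta.size + 1)
    below = np.nonzero(prefix_means < alpha)[0]
    n_rej = int(below[-1] + 1) if below.size else 0
    reject = np.zeros(eta.size, dtype=bool)
    reject[order[:n_rej]] = True
    return InferenceResult(list(pair_ids), eta, float(alpha), reject,
                           config_set=config_set)


def marginalize_model(model: HTModel, subset: Iterable[int]) -> HTModel:
    """Restrict a K-tissue model to a tissue subset.

    Delta, Sigma, Omega, tau restrict to the subset's rows/columns; the
    prior sums over the removed coordinates. Marginal compatibility of
    the mixture makes this the exact sub-model.
    """
    sub = list(subset)
    if len(sub) == 0:
        raise ValueError("subset must be non-empty")
    if len(set(sub)) != len(sub) or not all(0 <= k < model.K for k in sub):
        raise ValueError("subset must be distinct valid tissue indices")
    ix = np.asarray(sub, dtype=int)
    grouped: dict = {}
    for cfg, pr in zip(model.configs, model.probs):
        key = tuple(int(b) for b in cfg[ix])
        grouped[key] = grouped.get(key, 0.0) + float(pr)
    keys = sorted(grouped)
    configs = np.array(keys, dtype=np.int8)
    probs = np.array([grouped[k] for k in keys])
    panel = model.panel.subset(sub) if model.panel is not None else None
    return HTModel(
        len(sub), configs, probs,
        model.Delta[np.ix_(ix, ix)], model.Sigma[np.ix_(ix, ix)],
        None if model.Omega is None else model.Omega[np.ix_(ix, ix)],
        None if model.tau is None else model.tau[ix],
        panel, model.trunc,
        {**model.provenance, "marginalized_from": int(model.K),
         "subset": sub})


def hamming_class_summary(model_or_prior) -> np.ndarray:
    """Total prior mass per Hamming class m = 0..K (configs with m ones)."""
    if isinstance(model_or_prior, HTModel):
        configs, probs = model_or_prior.configs, model_or_prior.probs
        K = model_or_prior.K
    else:
        configs, probs = model_or_prior
        configs = np.asarray(configs)
        probs = np.asarray(probs, dtype=float)
        K = configs.shape[1]
    ones = np.asarray(configs).sum(axis=1).astype(int)
    out = np.zeros(K + 1)
    np.add.at(out, ones, probs)
    return out


def tissue_clustering(Sigma: np.ndarray) -> np.ndarray:
    """Single-linkage merge tree of tissues from effect-size similarity.

    The distance between tissues is 1 - corr(Sigma)_ij (the correlation
    induced by the effect covariance is a similarity, so its complement
    is the dissimilarity). Returns a scipy linkage matrix.
    """
    S = np.asarray(Sigma, dtype=float)
    d = np.diag(S)
    if np.any(d <= 0):
        raise ValueError("Sigma diagonal must be positive")
    corr = S / np.sqrt(np.outer(d, d))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return linkage(squareform(dist, checks=False), method="single")


def linkage_to_newick(Zlink: np.ndarray, labels: list) -> str:
    """Render a scipy linkage matrix as a Newick string with branch
    lengths (parent height minus child height)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(labels[i]) for i in range(n)}
    for step, (a, b, h, _) in enumerate(Zlink):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        node = n + step
        nodes[node] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[node] = h
    return nodes[n + len(Zlink) - 1] + ";"
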