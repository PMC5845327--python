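"""The assembled K-tissue hierarchical mixture model.

A fitted model says: a gene-SNP pair's z-statistic vector is drawn from

    Z ~ sum_gamma p(gamma) N(0, Delta + Sigma o (gamma gamma'))

where gamma ranges over a (truncated) support of eQTL configurations,
Delta is the null correlation across tissues (subject overlap), Sigma the
effect-size covariance, and `o` is the elementwise product. The prior
p(.) is represented sparsely: configurations and their probabilities,
usually the survivors of a multi-Probit orthant construction truncated at
`trunc` and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TissuePanel

__all__ = ["HTModel", "check_correlation", "check_psd"]


def check_psd(M: np.ndarray, name: str = "matrix", tol: float = 1e-8) -> None:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError(f"{name} is not positive semi-definite "
                         f"(min eigenvalue {w.min():.3g})")


def check_correlation(M: np.ndarray, name: str = "matrix") -> None:
    check_psd(M, name)
    if not np.allclose(np.diag(M), 1.0, atol=1e-8):
        raise ValueError(f"{name} must have unit diagonal")


def _config_key(cfg: np.ndarray) -> int:
    """Integer code of a configuration; tissue 0 is the most significant
    bit, so codes sort like bitstrings."""
    code = 0
    for b in cfg:
        code = (code << 1) | int(b)
    return code


@dataclass
class HTModel:
    """Sparse-prior Gaussian mixture model over eQTL configurations.

    Parameters
    ----------
    K : number of tissues
    configs : (M, K) 0/1 array — the supported configurations
    probs : (M,) prior probabilities (positive, summing to 1)
    Delta : (K, K) null correlation matrix
    Sigma : (K, K) effect covariance matrix
    Omega : (K, K) Probit latent correlation matrix, or None for models
        specified directly (e.g. the built-in synthetic model)
    tau : (K,) Probit thresholds, or None
    panel : optional TissuePanel
    trunc : truncation level used for the prior support
    provenance : free-form dict recorded at assembly time
    """

    K: int
    configs: np.ndarray
    probs: np.ndarray
    Delta: np.ndarray
    Sigma: np.ndarray
    Omega: np.ndarray | None = None
    tau: np.ndarray | None = None
    panel: TissuePanel | None = None
    trunc: float = 1e-5
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.configs = np.asarray(self.configs, dtype=np.int8)
        self.probs = np.asarray(self.probs, dtype=float)
        self.Delta = np.asarray(self.Delta, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Omega is not None:
            self.Omega = np.asarray(self.Omega, dtype=float)
        if self.tau is not None:
            self.tau = np.asarray(self.tau, dtype=float)
        self.validate()

    def validate(self) -> None:
        K = self.K
        if self.configs.ndim != 2 or self.configs.shape[1] != K:
            raise ValueError("configs must be (M, K)")
        if not np.isin(self.configs, (0, 1)).all():
            raise ValueError("configs must be 0/1")
        if self.probs.shape != (self.configs.shape[0],):
            raise ValueError("probs must align with configs")
        if np.any(self.probs <= 0):
            raise ValueError("prior probabilities must be > 0")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"prior probabilities sum to {self.probs.sum():.12g}, not 1")
        keys = [_config_key(c) for c in self.configs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate configurations in support")
        check_correlation(self.Delta, "Delta")
        check_psd(self.Sigma, "Sigma")
        if self.Delta.shape != (K, K) or self.Sigma.shape != (K, K):
            raise ValueError("Delta/Sigma must be K x K")
        if self.Omega is not None:
            check_correlation(self.Omega, "Omega")
        if self.tau is not None and self.tau.shape != (K,):
            raise ValueError("tau must have length K")

    @property
    def support_size(self) -> int:
        return self.configs.shape[0]

    def support_bitstrings(self) -> list:
        return ["".join(str(int(b)) for b in c) for c in self.configs]

    def config_cov(self, gamma: np.ndarray) -> np.ndarray:
        """Delta + Sigma o (gamma gamma') for one configuration."""
        g = np.asarray(gamma, dtype=float)
        return self.Delta + self.Sigma * np.outer(g, g)

    def prob_of(self, gamma) -> float:
        """Prior probability of a configuration (0 if outside support)."""
        g = np.asarray(gamma, dtype=np.int8)
        hit = np.nonzero((self.configs == g).all(axis=1))[0]
        return float(self.probs[hit[0]]) if hit.size else 0.0

    def sorted_by_config(self) -> "HTModel":
        """Support reordered by configuration bitstring (canonical order)."""
        order = np.argsort([_config_key(c) for c in self.configs],
                           kind="stable")
        return HTModel(self.K, self.configs[order], self.probs[order],
                       self.Delta, self.Sigma, self.Omega, self.tau,
                       self.panel, self.trunc, dict(self.provenance))

    def to_dict(self) -> dict:
        d = {
            "format": "hteqtl-model",
            "version": 1,
            "K": int(self.K),
            "p": [[bs, float(pr)] for bs, pr in
                  zip(self.support_bitstrings(), self.probs)],
            "Delta": self.Delta.tolist(),
            "Sigma": self.Sigma.tolist(),
            "Omega": None if self.Omega is None else self.Omega.tolist(),
            "tau": None if self.tau is None else self.tau.tolist(),
            "trunc": float(self.trunc),
            "provenance": self.provenance,
        }
        if self.panel is not None:
            d["panel"] = {
                "tissue_names": list(self.panel.tissue_names),
                "n": self.panel.n.tolist(),
                "n_cov": self.panel.n_cov.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HTModel":
        if d.get("format") != "hteqtl-model":
            raise ValueError("not an hteqtl model file")
        if int(d.get("version", -1)) != 1:
            raise ValueError(
                f"unsupported model file version {d.get('version')!r}")
        configs = np.array([[int(ch) for ch in bs] for bs, _ in d["p"]],
                           dtype=np.int8)
        probs = np.array([pr for _, pr in d["p"]], dtype=float)
        panel = None
        if "panel" in d:
            panel = TissuePanel(d["panel"]["tissue_names"], d["panel"]["n"],
                                d["panel"]["n_cov"])
        return cls(int(d["K"]), configs, probs,
                   np.asarray(d["Delta"], dtype=float),
                   np.asarray(d["Sigma"], dtype=float),
                   None if d.get("Omega") is None else np.asarray(d["Omega"]),
                   None if d.get("tau") is None else np.asarray(d["tau"]),
                   panel, float(d.get("trunc", 1e-5)),
                   dict(d.get("provenance", {})))
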