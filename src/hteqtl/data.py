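"""Core data containers: the tissue panel and the z-statistic matrix.

A multi-tissue cis-eQTL analysis starts from per-tissue expression /
genotype correlations that are variance-stabilized into z-statistics.
These containers carry the two pieces of metadata every downstream stage
needs: which tissues are present (with their effective degrees of
freedom) and the N x K matrix of z-statistics for N gene-SNP pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["TissuePanel", "ZMatrix"]


@dataclass(frozen=True)
class TissuePanel:
    """Tissues under study with per-tissue sample sizes.

    Parameters
    ----------
    tissue_names : sequence of str
        Unique tissue identifiers, length K.
    n : sequence of int
        Number of genotyped subjects contributing expression in each tissue.
    n_cov : sequence of int, optional
        Number of covariates regressed out of expression per tissue
        (defaults to zero for all tissues).

    Notes
    -----
    The degrees of freedom ``d_k = n_k - n_cov_k - 3`` scale the Fisher-
    transformed correlations so that, for a null gene-SNP pair, the
    resulting z-statistic is approximately standard normal.
    """

    tissue_names: tuple
    n: np.ndarray
    n_cov: np.ndarray = None

    def __init__(self, tissue_names: Sequence[str], n: Sequence[int],
                 n_cov: Sequence[int] | None = None):
        names = tuple(str(t) for t in tissue_names)
        if len(names) < 1:
            raise ValueError("panel needs at least one tissue")
        if len(set(names)) != len(names):
            raise ValueError("tissue names must be unique")
        n_arr = np.asarray(n, dtype=int)
        if n_arr.shape != (len(names),):
            raise ValueError("n must have one entry per tissue")
        if np.any(n_arr < 1):
            raise ValueError("sample sizes must be >= 1")
        if n_cov is None:
            nc = np.zeros(len(names), dtype=int)
        else:
            nc = np.asarray(n_cov, dtype=int)
        if nc.shape != (len(names),):
            raise ValueError("n_cov must have one entry per tissue")
        if np.any(nc < 0):
            raise ValueError("covariate counts must be >= 0")
        d = n_arr - nc - 3
        if np.any(d <= 0):
            bad = [names[i] for i in np.nonzero(d <= 0)[0]]
            raise ValueError(
                f"non-positive degrees of freedom for tissue(s) {bad}: "
                "need n - n_cov - 3 > 0")
        object.__setattr__(self, "tissue_names", names)
        object.__setattr__(self, "n", n_arr)
        object.__setattr__(self, "n_cov", nc)

    @property
    def K(self) -> int:
        return len(self.tissue_names)

    @property
    def d(self) -> np.ndarray:
        """Per-tissue degrees of freedom ``n - n_cov - 3``."""
        return self.n - self.n_cov - 3

    def index_of(self, name: str) -> int:
        return self.tissue_names.index(name)

    def subset(self, idx: Sequence[int]) -> "TissuePanel":
        idx = list(idx)
        return TissuePanel([self.tissue_names[i] for i in idx],
                           self.n[idx], self.n_cov[idx])


@dataclass
class ZMatrix:
    """N gene-SNP pairs x K tissues of Fisher-transformed z-statistics.

    Entries may be NaN where a gene is not measured in a tissue; such
    rows are excluded from full-panel inference (or scored on their
    observed subset, see :func:`hteqtl.inference.lfdr`).
    """

    pair_ids: list
    Z: np.ndarray
    panel: TissuePanel

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise ValueError("Z must be 2-dimensional")
        if self.Z.shape[1] != self.panel.K:
            raise ValueError(
                f"Z has {self.Z.shape[1]} columns but panel has "
                f"{self.panel.K} tissues")
        if len(self.pair_ids) != self.Z.shape[0]:
            raise ValueError("pair_ids length must match Z rows")
        self.pair_ids = [tuple(p) for p in self.pair_ids]
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise ValueError("pair_ids must be unique")
        if np.any(np.isinf(self.Z)):
            raise ValueError("Z contains non-finite (infinite) entries")

    @property
    def N(self) -> int:
        return self.Z.shape[0]

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    def complete_mask(self, cols: Sequence[int] | None = None) -> np.ndarray:
        """Boolean mask of rows with no missing value in ``cols``."""
        Z = self.Z if cols is None else self.Z[:, list(cols)]
        return ~np.isnan(Z).any(axis=1)

    def complete_rows(self) -> "ZMatrix":
        m = self.complete_mask()
        return ZMatrix([p for p, keep in zip(self.pair_ids, m) if keep],
                       self.Z[m], self.panel)
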