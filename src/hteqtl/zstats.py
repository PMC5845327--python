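"""From expression/genotype matrices to variance-stabilized z-statistics.

For each cis gene-SNP pair and tissue, the (covariate-corrected) Pearson
correlation r between expression and minor-allele dosage is mapped to

    z = atanh(r) * sqrt(d),    d = n - n_cov - 3,

so that under the null (population correlation zero) z is approximately
standard normal. Covariate correction is ordinary least-squares
residualization of expression per tissue; genotype enters raw.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .data import TissuePanel, ZMatrix

__all__ = ["residualize", "pair_correlations", "fisher_z"]

# correlations at or beyond this magnitude are clamped before atanh
_R_CLAMP = 1.0 - 1e-12


def residualize(matrix: np.ndarray, covariates: np.ndarray | None = None
                ) -> np.ndarray:
    """OLS-residualize each column (feature) of ``matrix`` on ``covariates``.

    Parameters
    ----------
    matrix : (n_subjects, n_features) array
    covariates : (n_subjects, c) array or None
        An intercept column is appended if none is present. ``None``
        means intercept-only (column centering).

    Returns
    -------
    (n_subjects, n_features) array of residuals, orthogonal to the
    covariate columns.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    n = X.shape[0]
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError(
                f"subject-count mismatch: matrix has {n} rows, "
                f"covariates have {C.shape[0]}")
        # append an intercept unless some column is already constant
        col_rng = C.max(axis=0) - C.min(axis=0)
        has_const = np.any((col_rng == 0) & (np.abs(C).max(axis=0) > 0))
        if not has_const:
            C = np.hstack([C, np.ones((n, 1))])
    # rank check with column pivoting to name the collinear columns
    _, R, piv = scipy.linalg.qr(C, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(C.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < C.shape[1]:
        bad = sorted(int(j) for j in piv[rank:])
        raise ValueError(
            f"rank-deficient covariates: columns {bad} are collinear "
            "with the others (after intercept augmentation)")
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ beta


def pair_correlations(expr_by_tissue: Sequence[pd.DataFrame],
                      geno: pd.DataFrame,
                      pairs: Sequence[tuple]) -> np.ndarray:
    """Per-tissue Pearson correlations for a list of gene-SNP pairs.

    Parameters
    ----------
    expr_by_tissue : list of K DataFrames, genes x subjects
        Subject columns of each tissue must be a subset of the genotype
        subject columns. Expression is assumed already covariate-corrected
        (see :func:`residualize`).
    geno : DataFrame, SNPs x subjects
        Minor-allele dosages.
    pairs : list of (gene_id, snp_id)

    Returns
    -------
    (N, K) array of correlations; NaN marks pairs whose gene is not
    measured in a tissue or whose gene/SNP has zero variance there.
    """
    pairs = [tuple(p) for p in pairs]
    genes = [g for g, _ in pairs]
    snps = [s for _, s in pairs]
    missing_snps = sorted(set(snps) - set(geno.index))
    if missing_snps:
        raise KeyError(f"SNPs absent from genotype matrix: {missing_snps[:5]}")
    out = np.full((len(pairs), len(expr_by_tissue)), np.nan)
    for k, expr in enumerate(expr_by_tissue):
        subj = expr.columns
        if not set(subj).issubset(geno.columns):
            extra = sorted(set(subj) - set(geno.columns))
            raise KeyError(
                f"tissue {k}: subjects without genotypes: {extra[:5]}")
        G = geno.loc[snps, subj].to_numpy(dtype=float)
        present = np.array([g in expr.index for g in genes])
        if not present.any():
            continue
        E = expr.reindex([g for g, p in zip(genes, present) if p]
                         ).to_numpy(dtype=float)
        Gp = G[present]
        Ec = E - E.mean(axis=1, keepdims=True)
        Gc = Gp - Gp.mean(axis=1, keepdims=True)
        se = np.sqrt((Ec ** 2).sum(axis=1))
        sg = np.sqrt((Gc ** 2).sum(axis=1))
        ok = (se > 0) & (sg > 0)
        r = np.full(len(se), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            r[ok] = (Ec[ok] * Gc[ok]).sum(axis=1) / (se[ok] * sg[ok])
        n_degen = int((~ok).sum())
        if n_degen:
            warnings.warn(
                f"tissue {k}: {n_degen} pair(s) with zero-variance gene or "
                "SNP marked missing", RuntimeWarning)
        out[present, k] = np.clip(r, -1.0, 1.0)
    return out


def fisher_z(r: np.ndarray, panel: TissuePanel,
             pair_ids: Sequence[tuple] | None = None) -> ZMatrix:
    """Fisher-transform correlations into a :class:`ZMatrix`.

    ``Z[l, k] = atanh(r[l, k]) * sqrt(d_k)``; NaN (missing) entries
    propagate. Correlations with ``|r| >= 1 - 1e-12`` are clamped to
    that bound (with a warning) so that duplicated expression/dosage
    columns yield extreme but finite evidence rather than infinities.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim == 1:
        r = r[:, None]
    if r.shape[1] != panel.K:
        raise ValueError(f"r has {r.shape[1]} columns, panel K={panel.K}")
    with np.errstate(invalid="ignore"):
        over = np.abs(r) >= _R_CLAMP
    n_over = int(np.nansum(over))
    if n_over:
        warnings.warn(
            f"{n_over} correlation(s) with |r| >= 1 - 1e-12 clamped before "
            "atanh", RuntimeWarning)
        r = np.where(over, np.sign(r) * _R_CLAMP, r)
    Z = np.arctanh(r) * np.sqrt(panel.d)[None, :]
    if pair_ids is None:
        pair_ids = [("pair", str(i)) for i in range(r.shape[0])]
    return ZMatrix(list(pair_ids), Z, panel)
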