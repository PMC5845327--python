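"""The top-level scikit-learn-style estimator for multi-tissue eQTL
analysis.

``HTEQTL.fit`` takes the (N, K) z-statistic matrix, fits every two-tissue
mixture sub-model by EM, and assembles them into the K-tissue model
(covariance stitching plus a multi-Probit configuration prior).
``predict_proba`` returns posterior null/alternative probabilities for a
configuration set, ``predict`` the adaptive-FDR rejection flags.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .assemble import assemble_model
from .data import TissuePanel, ZMatrix
from .inference import ConfigSet, InferenceResult, adaptive_fdr, lfdr
from .model import HTModel
from .pairwise import fit_all_pairs

__all__ = ["HTEQTL"]


class HTEQTL(BaseEstimator):
    """Scalable empirical-Bayes model for eQTL analysis across tissues.

    Parameters
    ----------
    tol, max_iter, min_sigma : EM controls for the pairwise fits.
    trunc : prior truncation level (configurations below it are dropped).
    orthant_method : 'exact' (K <= 15) or 'montecarlo'.
    n_samples : Monte-Carlo draws when orthant_method='montecarlo'.
    random_state : seed for the Monte-Carlo orthant sweep.
    alpha : nominal FDR level used by :meth:`predict`.
    config_set : 'any', 'common', 'tissue_specific' or 'tissue:<k>'.
    n_jobs : parallel workers for the pairwise fits.

    Attributes
    ----------
    model_ : :class:`~hteqtl.model.HTModel`
    pair_fits_, single_fits_ : the underlying sub-model fits
    delta_, sigma_, omega_, tau_ : assembled parameters
    prior_ : (configs, probs) sparse configuration prior
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500,
                 min_sigma: float = 0.5, trunc: float = 1e-5,
                 orthant_method: str = "exact",
                 n_samples: int = 10_000_000,
                 random_state: int | None = None, alpha: float = 0.05,
                 config_set: str = "any", n_jobs: int = 1):
        self.tol = tol
        self.max_iter = max_iter
        self.min_sigma = min_sigma
        self.trunc = trunc
        self.orthant_method = orthant_method
        self.n_samples = n_samples
        self.random_state = random_state
        self.alpha = alpha
        self.config_set = config_set
        self.n_jobs = n_jobs

    def _as_zmatrix(self, X) -> ZMatrix:
        if isinstance(X, ZMatrix):
            return X
        Z = np.asarray(X, dtype=float)
        if Z.ndim != 2:
            raise ValueError("X must be a 2-d z-statistic matrix")
        panel = TissuePanel([f"T{k + 1}" for k in range(Z.shape[1])],
                            [150] * Z.shape[1])
        return ZMatrix([(f"g{i}", f"s{i}") for i in range(Z.shape[0])],
                       Z, panel)

    def fit(self, X, y=None):
        zmat = self._as_zmatrix(X)
        self.pair_fits_, self.single_fits_ = fit_all_pairs(
            zmat, tol=self.tol, max_iter=self.max_iter, n_jobs=self.n_jobs)
        self.model_ = assemble_model(
            self.pair_fits_, self.single_fits_, zmat.panel,
            trunc=self.trunc, method=self.orthant_method,
            seed=self.random_state, n_samples=self.n_samples)
        self.delta_ = self.model_.Delta
        self.sigma_ = self.model_.Sigma
        self.omega_ = self.model_.Omega
        self.tau_ = self.model_.tau
        self.prior_ = (self.model_.configs, self.model_.probs)
        self.n_features_in_ = zmat.K
        return self

    def _config_set(self) -> ConfigSet:
        return ConfigSet.parse(self.config_set, self.model_.K)

    def lfdr(self, X, S: ConfigSet | None = None) -> np.ndarray:
        """Per-pair local false discovery rate for the configuration set."""
        check_is_fitted(self, "model_")
        zmat = self._as_zmatrix(X)
        return lfdr(zmat, self.model_, S or self._config_set())

    def predict_proba(self, X) -> np.ndarray:
        """(N, 2) columns [P(H0 | z), P(H1 | z)] for the configuration
        set."""
        eta = self.lfdr(X)
        return np.column_stack([eta, 1.0 - eta])

    def infer(self, X, S: ConfigSet | None = None,
              alpha: float | None = None) -> InferenceResult:
        """Full adaptive-FDR inference (lfdrs plus rejection flags)."""
        check_is_fitted(self, "model_")
        zmat = self._as_zmatrix(X)
        S = S or self._config_set()
        eta = lfdr(zmat, self.model_, S)
        return adaptive_fdr(eta, alpha if alpha is not None else self.alpha,
                            pair_ids=zmat.pair_ids,
                            config_set=S.describe())

    def predict(self, X) -> np.ndarray:
        """Boolean rejection flags at the nominal FDR level ``alpha``."""
        return self.infer(X).reject

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per row under the assembled model."""
        check_is_fitted(self, "model_")
        zmat = self._as_zmatrix(X)
        from .inference import _log_densities
        from scipy.special import logsumexp
        logd = _log_densities(zmat.Z, self.model_)
        lw = logd + np.log(self.model_.probs)[None, :]
        return float(logsumexp(lw, axis=1).mean())
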