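"""PCA of the three-variable breathing/uptake space.

Baseline breathing frequency, baseline tidal volume and the VO2 at a fixed
reference ventilation strongly co-vary across patients — cohort trajectories
lie close to a plane in this 3-space.  Projecting onto principal components
(computed here by eigendecomposition of the correlation matrix; variables are
standardized because their units are incommensurate) condenses the breathing
pattern into a single leading score.  The polar angle theta of the first
loading relative to the breathing-frequency axis summarizes its orientation,
and the fraction of total-energy variance explained by an ordinary regression
of performance on the first-PC score quantifies how much of the performance
spread the leading component captures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["PCAResult", "BreathingPatternPCA", "pca_performance", "PCA_VARIABLES"]

#: The three co-varying variables entering the decomposition, in fixed order.
PCA_VARIABLES = ("baseline_bf", "baseline_vt", "vo2_at_fixed_ve")


@dataclass
class PCAResult:
    loadings: np.ndarray  # (3, 3), orthonormal columns
    explained_variance_ratio: np.ndarray  # sums to 1
    scores: np.ndarray  # (n_patients, 3)
    theta: float  # polar angle of PC1 w.r.t. the BF axis, radians in [0, pi/2]
    performance_r2_pc1: float  # R^2 of total energy ~ PC1 score


class BreathingPatternPCA(TransformerMixin, BaseEstimator):
    """Standardize-then-PCA transformer for the breathing/uptake variables.

    Eigendecomposition of the sample correlation matrix; components are sorted
    by decreasing eigenvalue and each loading is sign-fixed to a non-negative
    breathing-frequency component.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X: np.ndarray, y=None) -> "BreathingPatternPCA":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 4:
            raise ValueError("need at least 4 patients for a meaningful PCA")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in PCA input")
        if np.unique(X, axis=0).shape[0] < 2:
            raise ValueError("rank-deficient input: fewer than 2 distinct rows")
        self.mean_ = X.mean(axis=0)
        if self.standardize:
            scale = X.std(axis=0, ddof=1)
            self.scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.scale_ = np.ones(p)
        Z = (X - self.mean_) / self.scale_
        cov = Z.T @ Z / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.maximum(eigvals[order], 0.0)
        eigvecs = eigvecs[:, order]
        # sign convention: first (BF) coordinate of every loading non-negative
        signs = np.where(eigvecs[0, :] < 0, -1.0, 1.0)
        self.components_ = eigvecs * signs
        total = eigvals.sum()
        self.explained_variance_ = eigvals
        self.explained_variance_ratio_ = eigvals / total if total > 0 else eigvals
        self.n_features_in_ = p
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return ((X - self.mean_) / self.scale_) @ self.components_


def pca_performance(features: pd.DataFrame) -> PCAResult:
    """PCA of (baseline BF, baseline VT, VO2 at fixed VE) plus performance attribution.

    ``features`` must carry the :data:`PCA_VARIABLES` columns and
    ``total_energy_kJ`` (the performance metric).
    """
    missing = [c for c in PCA_VARIABLES if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks column(s): {', '.join(missing)}")
    X = features.loc[:, list(PCA_VARIABLES)].to_numpy(dtype=float)
    model = BreathingPatternPCA().fit(X)
    scores = model.transform(X)

    pc1 = model.components_[:, 0]
    theta = float(np.arccos(np.clip(abs(pc1[0]), -1.0, 1.0)))

    r2 = np.nan
    if "total_energy_kJ" in features.columns:
        energy = features["total_energy_kJ"].to_numpy(dtype=float)
        s1 = scores[:, 0]
        A = np.column_stack([np.ones_like(s1), s1])
        coef, *_ = np.linalg.lstsq(A, energy, rcond=None)
        resid = energy - A @ coef
        ss_tot = float(np.sum((energy - energy.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0

    return PCAResult(
        loadings=model.components_,
        explained_variance_ratio=model.explained_variance_ratio_,
        scores=scores,
        theta=theta,
        performance_r2_pc1=float(r2),
    )
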