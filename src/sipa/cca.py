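"""Canonical correlation analysis over paired compound/protein descriptors.

Each known compound–target interaction contributes one paired observation:
the compound's descriptor vector (block X) and the protein's descriptor
vector (block Y).  CCA finds linear combinations of each block maximising
their correlation; the canonical correlations r_1 >= ... >= r_s
(s = min(p, q)) measure how strongly the two descriptor spaces co-vary
across interacting pairs.

Significance of each variate is assessed with Bartlett's sequential
chi-square approximation on Wilks' lambda.  Feature descriptors are then
selected by their structure loadings (correlation of an original descriptor
with a canonical variate) on the variates that are both strong
(r_k > r_min) and significant (p_k < alpha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)


@dataclass
class PairedDescriptorSample:
    """Row-paired descriptor blocks; one row per known compound–target edge."""

    X: pd.DataFrame
    Y: pd.DataFrame
    pairs: list
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.X)


@dataclass
class FeatureSelection:
    """Descriptor subsets defining the compound/protein correlation space."""

    compound_descriptors: list
    protein_descriptors: list
    provenance: dict = field(default_factory=dict)


def build_paired_sample(net, compound_dm: pd.DataFrame, protein_dm: pd.DataFrame,
                        provenance: str = "known") -> PairedDescriptorSample:
    """Assemble the paired (X, Y) sample from the network's CT edges.

    Edges whose compound or protein is absent from its descriptor table are
    dropped and counted.  Rows are ordered by sorted (compound, protein) id.
    """
    pairs = []
    dropped = 0
    for e in net.edges_of_type("CT", provenance=provenance):
        c, t = (e.a, e.b) if net.entities[e.a].kind == "compound" else (e.b, e.a)
        if c in compound_dm.index and t in protein_dm.index:
            pairs.append((c, t))
        else:
            dropped += 1
    pairs.sort()
    if not pairs:
        raise ValueError("no usable compound-target edges for the paired sample")
    if dropped:
        log.warning("dropped %d CT edges missing descriptor rows", dropped)
    X = compound_dm.loc[[c for c, _ in pairs]].reset_index(drop=True)
    Y = protein_dm.loc[[t for _, t in pairs]].reset_index(drop=True)
    return PairedDescriptorSample(X=X, Y=Y, pairs=pairs, n_dropped=dropped)


def _inv_sqrt(mat: np.ndarray, ridge: float) -> np.ndarray:
    if ridge:
        mat = mat + ridge * np.eye(len(mat))
    w, v = linalg.eigh(mat)
    if w.min() <= 0:
        raise np.linalg.LinAlgError(
            "within-set covariance is singular; add ridge or drop collinear columns"
        )
    return v @ np.diag(1.0 / np.sqrt(w)) @ v.T


class CanonicalCorrelationModel(BaseEstimator):
    """Classical CCA via SVD of the whitened cross-covariance.

    Columns of both blocks are standardised to zero mean and unit sample
    variance (statistics stored for reuse on held-out data); the canonical
    correlations are the singular values of
    ``Sxx^{-1/2} Sxy Syy^{-1/2}``.  Weights are scaled so the canonical
    variates have unit sample variance.  Bartlett's sequential chi-square
    test supplies per-variate p-values.

    Parameters
    ----------
    ridge : float, default 0
        Regulariser added to the diagonals of the within-set covariance
        matrices before whitening; use a small positive value when the
        descriptor blocks are collinear or n is close to max(p, q).

    Attributes
    ----------
    correlations_ : (s,) canonical correlations, descending, clipped to [0, 1]
    x_weights_, y_weights_ : (p, s) and (q, s) weight matrices on the
        standardised columns
    x_loadings_, y_loadings_ : structure loadings (descriptor-variate
        Pearson correlations)
    wilks_, chi2_, dof_, pvalues_ : Bartlett sequential test per variate
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X, Y=None):
        if Y is None:
            raise ValueError("CanonicalCorrelationModel.fit requires both blocks")
        self.x_names_ = list(X.columns) if isinstance(X, pd.DataFrame) else \
            [f"x{i}" for i in range(np.asarray(X).shape[1])]
        self.y_names_ = list(Y.columns) if isinstance(Y, pd.DataFrame) else \
            [f"y{i}" for i in range(np.asarray(Y).shape[1])]
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n, p = X.shape
        q = Y.shape[1]
        if Y.shape[0] != n:
            raise ValueError("X and Y must have the same number of rows")
        if n < 3:
            raise ValueError("CCA needs at least 3 paired observations")
        if n <= max(p, q) and not self.ridge:
            raise ValueError(
                f"n={n} <= max(p, q)={max(p, q)}: within-set covariance is "
                "singular; use a ridge or select fewer descriptors"
            )
        self.x_mean_, self.y_mean_ = X.mean(0), Y.mean(0)
        self.x_sd_ = X.std(0, ddof=1)
        self.y_sd_ = Y.std(0, ddof=1)
        if np.any(self.x_sd_ == 0) or np.any(self.y_sd_ == 0):
            raise ValueError("zero-variance descriptor column; preprocess first")
        Xs = (X - self.x_mean_) / self.x_sd_
        Ys = (Y - self.y_mean_) / self.y_sd_

        Sxx = Xs.T @ Xs / (n - 1)
        Syy = Ys.T @ Ys / (n - 1)
        Sxy = Xs.T @ Ys / (n - 1)
        Kx = _inv_sqrt(Sxx, self.ridge)
        Ky = _inv_sqrt(Syy, self.ridge)
        U, s, Vt = linalg.svd(Kx @ Sxy @ Ky, full_matrices=False)
        k = min(p, q)
        self.correlations_ = np.clip(s[:k], 0.0, 1.0)
        Wx = Kx @ U[:, :k]
        Wy = Ky @ Vt.T[:, :k]
        # unit sample variance of each variate (exact only at ridge 0)
        vx = Xs @ Wx
        vy = Ys @ Wy
        Wx /= vx.std(0, ddof=1)
        Wy /= vy.std(0, ddof=1)
        self.x_weights_, self.y_weights_ = Wx, Wy
        vx = Xs @ Wx
        vy = Ys @ Wy
        self.x_loadings_ = _cross_corr(Xs, vx)
        self.y_loadings_ = _cross_corr(Ys, vy)
        self.n_, self.p_, self.q_ = n, p, q
        self._bartlett(n)
        return self

    # -- significance --------------------------------------------------

    def _bartlett(self, n: int):
        r = self.correlations_
        s = len(r)
        p, q = self.p_, self.q_
        lam = np.array([np.prod(1.0 - r[k:] ** 2) for k in range(s)])
        lam = np.clip(lam, np.finfo(float).tiny, 1.0)
        mult = n - 1 - (p + q + 1) / 2.0
        dof = np.array([(p - k) * (q - k) for k in range(s)], dtype=float)
        if mult <= 0:
            log.warning("sample too small for Bartlett test (n=%d, p=%d, q=%d); "
                        "p-values set to 1", n, p, q)
            chi2 = np.zeros(s)
            pvals = np.ones(s)
        else:
            chi2 = -mult * np.log(lam)
            pvals = stats.chi2.sf(chi2, dof)
        self.wilks_, self.chi2_, self.dof_, self.pvalues_ = lam, chi2, dof, pvals

    # -- projection ----------------------------------------------------

    def transform(self, X=None, Y=None):
        """Project new rows onto the canonical variates (either block)."""
        out = []
        if X is not None:
            Xs = (np.asarray(X, float) - self.x_mean_) / self.x_sd_
            out.append(Xs @ self.x_weights_)
        if Y is not None:
            Ys = (np.asarray(Y, float) - self.y_mean_) / self.y_sd_
            out.append(Ys @ self.y_weights_)
        return out[0] if len(out) == 1 else tuple(out)


def _cross_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations corr(A[:, i], B[:, j])."""
    A = (A - A.mean(0)) / A.std(0, ddof=1)
    B = (B - B.mean(0)) / B.std(0, ddof=1)
    return A.T @ B / (len(A) - 1)


def fit_cca(sample: PairedDescriptorSample, ridge: float = 0.0) -> CanonicalCorrelationModel:
    """Fit classical CCA on a paired descriptor sample."""
    return CanonicalCorrelationModel(ridge=ridge).fit(sample.X, sample.Y)


def canonical_significance(model: CanonicalCorrelationModel, n: int) -> CanonicalCorrelationModel:
    """(Re)compute Bartlett sequential p-values for sample size ``n``."""
    model._bartlett(n)
    return model


def select_feature_descriptors(
    model: CanonicalCorrelationModel,
    r_min: float = 0.8,
    alpha: float = 0.01,
    loading_cutoff: float = 0.3,
) -> FeatureSelection:
    """Pick the descriptors that define the correlation space.

    Contributing variates satisfy r_k > ``r_min`` and p_k < ``alpha``; a
    descriptor is selected when its absolute structure loading on any
    contributing variate reaches ``loading_cutoff``.
    """
    contributing = [
        k for k in range(len(model.correlations_))
        if model.correlations_[k] > r_min and model.pvalues_[k] < alpha
    ]
    if not contributing:
        raise ValueError(
            f"no significant canonical variate at r_min={r_min}, alpha={alpha}"
        )
    x_sel = np.zeros(model.p_, dtype=bool)
    y_sel = np.zeros(model.q_, dtype=bool)
    for k in contributing:
        x_sel |= np.abs(model.x_loadings_[:, k]) >= loading_cutoff
        y_sel |= np.abs(model.y_loadings_[:, k]) >= loading_cutoff
    compound = [model.x_names_[i] for i in range(model.p_) if x_sel[i]]
    protein = [model.y_names_[i] for i in range(model.q_) if y_sel[i]]
    if not compound or not protein:
        raise ValueError(
            "selection is empty at loading_cutoff=%.3g; lower the cutoff" % loading_cutoff
        )
    return FeatureSelection(
        compound_descriptors=compound,
        protein_descriptors=protein,
        provenance={
            "r_min": r_min,
            "alpha": alpha,
            "loading_cutoff": loading_cutoff,
            "contributing_variates": contributing,
            "correlations": [float(model.correlations_[k]) for k in contributing],
        },
    )
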