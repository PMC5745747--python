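"""Gene-wise MAD normalization and the two-step qRT-PCR sample normalization.

Every platform is brought to a common range gene by gene: subtract the gene's
median and divide by its median absolute deviation (MAD), so that genes with a
large fold change between phenotypes sit positive under one phenotype and
negative under the other. Genes with MAD < 0.1 carry too little variability to
help a classifier and are filtered out first.

qRT-PCR panels measured relative to 18S rRNA arrive on an inverted scale
(larger value = lower expression) with per-sample shift biases; they are
centered per sample, sign-flipped, and then MAD-normalized gene-wise against a
pooled reference cohort so a single new sample can be placed on the training
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import ExpressionMatrix

CENTER_METHODS = ("arithmetic_mean", "geometric_mean", "median")


@dataclass
class NormalizationConfig:
    center_method: str = "median"
    mad_min: float = 0.1
    mad_constant: float = 1.0

    def __post_init__(self):
        if self.center_method not in CENTER_METHODS:
            raise ValueError(f"center_method must be one of {CENTER_METHODS}")
        if self.mad_min < 0:
            raise ValueError("mad_min must be >= 0")
        if self.mad_constant <= 0:
            raise ValueError("mad_constant must be > 0")


def mad(x: np.ndarray, axis=None) -> np.ndarray:
    """Raw median absolute deviation (no normal-consistency constant)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis)


class MADScaler(TransformerMixin, BaseEstimator):
    """Robust per-feature scaler: x -> (x - median) / (mad_constant * MAD).

    Operates on samples x features arrays (sklearn orientation); for a
    genes x samples ``ExpressionMatrix`` use :func:`mad_normalize_genes`.

    Parameters
    ----------
    mad_constant : float, default=1.0
        Multiplier on the raw MAD. 1.0 leaves the MAD on its raw scale;
        1.4826 would make the scale consistent with a normal SD.

    Attributes
    ----------
    center_ : ndarray of shape (n_features,)
        Per-feature medians.
    scale_ : ndarray of shape (n_features,)
        ``mad_constant * MAD`` per feature.
    """

    def __init__(self, mad_constant: float = 1.0):
        self.mad_constant = mad_constant

    def fit(self, X, y=None, feature_names=None):
        X = check_array(X, dtype=float)
        if self.mad_constant <= 0:
            raise ValueError("mad_constant must be > 0")
        self.center_ = np.median(X, axis=0)
        mads = mad(X, axis=0)
        zero = np.flatnonzero(mads == 0)
        if zero.size:
            names = (
                [feature_names[i] for i in zero]
                if feature_names is not None
                else zero.tolist()
            )
            raise ValueError(
                f"zero MAD for features {names}; filter low-MAD genes first"
            )
        self.scale_ = self.mad_constant * mads
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = check_array(X, dtype=float)
        return (X - self.center_) / self.scale_


def gene_mads(em: ExpressionMatrix) -> pd.Series:
    """Per-gene raw MAD across samples."""
    return pd.Series(mad(em.values, axis=1), index=em.gene_ids)


def mad_normalize_genes(em: ExpressionMatrix, mad_constant: float = 1.0) -> ExpressionMatrix:
    """Gene-wise MAD normalization: each gene row gets median 0, MAD 1/mad_constant."""
    scaler = MADScaler(mad_constant=mad_constant).fit(
        em.values.T, feature_names=em.gene_ids
    )
    out = scaler.transform(em.values.T).T
    return ExpressionMatrix(
        pd.DataFrame(out, index=em.gene_ids, columns=em.sample_ids),
        em.labels.copy(), em.platform,
    )


def filter_low_mad(em: ExpressionMatrix, mad_min: float = 0.1) -> ExpressionMatrix:
    """Drop genes with MAD < ``mad_min`` (strict); keeps MAD == mad_min."""
    keep = gene_mads(em) >= mad_min
    return em.subset_genes([g for g, k in zip(em.gene_ids, keep) if k])


def center_qpcr_samples(em: ExpressionMatrix, method: str = "median") -> ExpressionMatrix:
    """Center each sample and flip the inverted qRT-PCR scale.

    Raw relative-to-18S levels have larger values for lower expression; each
    sample is shifted by its own center (arithmetic mean, geometric mean or
    median) to remove inter-sample bias, then multiplied by -1 so larger
    values mean higher expression.
    """
    if method not in CENTER_METHODS:
        raise ValueError(f"method must be one of {CENTER_METHODS}")
    vals = em.values
    if method == "arithmetic_mean":
        centers = vals.mean(axis=0)
    elif method == "median":
        centers = np.median(vals, axis=0)
    else:
        if np.any(vals <= 0):
            raise ValueError("geometric mean requires strictly positive values")
        centers = np.exp(np.log(vals).mean(axis=0))
    out = -(vals - centers)
    return ExpressionMatrix(
        pd.DataFrame(out, index=em.gene_ids, columns=em.sample_ids),
        em.labels.copy(), em.platform,
    )


def normalize_qpcr_with_reference(
    new_raw: ExpressionMatrix,
    reference_raw: ExpressionMatrix,
    cfg: NormalizationConfig | None = None,
) -> ExpressionMatrix:
    """Normalize new qRT-PCR samples against a stored raw reference cohort.

    The new samples are pooled with the reference, each sample is centered and
    sign-flipped, and gene medians/MADs are estimated on the pooled set (a
    single new sample cannot estimate them alone). Only the new samples'
    normalized values are returned.
    """
    cfg = cfg or NormalizationConfig()
    missing = [g for g in new_raw.gene_ids if g not in reference_raw.data.index]
    if missing:
        raise ValueError(f"genes missing from reference: {missing}")
    ref = reference_raw.subset_genes(new_raw.gene_ids)
    overlap = set(new_raw.sample_ids) & set(ref.sample_ids)
    if overlap:
        raise ValueError(f"sample ids present in both new and reference: {sorted(overlap)}")
    pooled_data = pd.concat([ref.data, new_raw.data], axis=1)
    pooled_labels = pd.concat([ref.labels, new_raw.labels])
    pooled = ExpressionMatrix(pooled_data, pooled_labels, new_raw.platform)
    centered = center_qpcr_samples(pooled, cfg.center_method)
    normalized = mad_normalize_genes(centered, cfg.mad_constant)
    return normalized.subset_samples(new_raw.sample_ids)
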