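"""Summary-metric classification with Cantelli-bound class probabilities.

The summary metric (SM) of a sample is the mean of its MAD-normalized
signature-gene expression after flipping the sign of the genes over-expressed
in HP, so that SM > 0 calls SSA/P and SM < 0 calls HP. A class probability is
attached via one of:

* ``cantelli`` — the distribution-free Cantelli (one-sided Chebyshev) lower
  bound CLB = 1 - sigma^2 / (sigma^2 + a^2) with a = |SM|; assigned only when
  CLB > 0.5 (equivalently |SM| > sigma), otherwise the call is left without a
  probability (uncertain zone),
* ``empirical`` — the CDF of SMs of many random same-size signatures on a
  reference cohort, after standardization,
* ``normal`` — the standard normal CDF of the standardized SM.

Small qRT-PCR panels profile too few genes to estimate the SM distribution,
so for them only the sign label is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io import ExpressionMatrix, Signature

UNCERTAIN = "uncertain"
MODES = ("cantelli", "empirical", "normal")


@dataclass
class SMResult:
    sample_id: str
    sm: float
    sm_std: float
    label: str
    prob_cantelli: float | None = None
    prob_empirical: float | None = None
    prob_normal: float | None = None


def compute_sm(sample: Sequence[float] | pd.Series, sig: Signature) -> float:
    """Mean of direction-signed signature-gene expression for one sample.

    ``sample`` is either a Series indexed by gene id (any superset of the
    signature genes) or an array aligned to the signature's gene order.
    """
    if isinstance(sample, pd.Series):
        missing = [g for g in sig.gene_ids if g not in sample.index]
        if missing:
            raise KeyError(f"sample is missing signature genes: {missing}")
        values = sample[sig.gene_ids].to_numpy(dtype=float)
    else:
        values = np.asarray(sample, dtype=float)
        if values.shape != (len(sig),):
            raise ValueError(f"expected {len(sig)} values, got {values.shape}")
    return float(np.mean(sig.direction * values))


def score_samples(em: ExpressionMatrix, sig: Signature) -> pd.Series:
    """SM per sample of a MAD-normalized matrix covering the signature genes."""
    sub = em.subset_genes(sig.gene_ids)
    sm = (sig.direction[:, None] * sub.values).mean(axis=0)
    return pd.Series(sm, index=em.sample_ids, name="sm")


def classify_sm(sm: float) -> str:
    """Sign rule: SSA/P if SM > 0, HP if SM < 0, uncertain at exactly 0."""
    if sm > 0:
        return "SSA/P"
    if sm < 0:
        return "HP"
    return UNCERTAIN


def cantelli_lower_bound(a: float, sigma: float = 1.0) -> float:
    """CLB = 1 - sigma^2/(sigma^2 + a^2) for a >= 0; strictly increasing in a."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if a < 0:
        raise ValueError("a must be >= 0")
    return 1.0 - sigma**2 / (sigma**2 + a**2)


def cantelli_probability(sm: float, sigma: float = 1.0) -> float | None:
    """Cantelli lower-bound probability for the sign-assigned class.

    Returns the CLB at a = |sm| when it exceeds 0.5 (i.e. |sm| > sigma);
    otherwise ``None`` — the sample sits in the uncertain zone [-sigma, sigma].
    """
    clb = cantelli_lower_bound(abs(sm), sigma)
    return clb if clb > 0.5 else None


@dataclass
class SMDistribution:
    """Pooled SM draws of random same-size signatures on a reference cohort."""

    draws: np.ndarray
    mean: float
    sd: float

    def cdf(self, x: float) -> float:
        return float(np.mean(self.draws <= x))

    def cdf_standardized(self, z: float) -> float:
        return float(np.mean((self.draws - self.mean) / self.sd <= z))


def empirical_sm_distribution(
    reference: ExpressionMatrix,
    signature_size: int,
    n_random: int = 1000,
    seed: int | None = None,
) -> SMDistribution:
    """Estimate the null SM distribution from random signatures.

    Draws ``n_random`` gene sets of ``signature_size`` genes without
    replacement (directions assigned uniformly at random, since the direction
    structure of a random gene set is unknowable), computes the SM of every
    reference sample under each, and pools all draws.
    """
    if reference.n_genes < signature_size:
        raise ValueError("reference has fewer genes than signature_size")
    rng = np.random.default_rng(seed)
    vals = reference.values
    draws = np.empty((n_random, reference.n_samples))
    for i in range(n_random):
        idx = rng.choice(reference.n_genes, signature_size, replace=False)
        signs = rng.choice((-1.0, 1.0), signature_size)
        draws[i] = (signs[:, None] * vals[idx]).mean(axis=0)
    flat = draws.ravel()
    return SMDistribution(flat, float(flat.mean()), float(flat.std(ddof=1)))


def class_probability(
    sm: float,
    mode: str = "cantelli",
    reference: SMDistribution | None = None,
    sigma: float = 1.0,
    sample_id: str = "",
) -> SMResult:
    """Attach a class probability to an SM value.

    With a reference distribution, the SM is standardized by the reference
    mean/SD and sigma = 1 applies; without one, the raw SM is used with the
    caller's sigma (e.g. 0.14 for 15-gene-scale raw SMs).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode in ("empirical", "normal") and reference is None:
        raise ValueError(f"mode {mode!r} requires a reference SM distribution")
    if reference is not None:
        sm_std = (sm - reference.mean) / reference.sd
        eff_sigma = 1.0
    else:
        sm_std = sm / sigma
        eff_sigma = 1.0
    label = classify_sm(sm)
    result = SMResult(sample_id=sample_id, sm=float(sm), sm_std=float(sm_std), label=label)
    if mode == "cantelli":
        result.prob_cantelli = cantelli_probability(sm_std, eff_sigma)
    elif mode == "normal":
        cdf = float(norm.cdf(sm_std))
        result.prob_normal = cdf if sm > 0 else 1.0 - cdf
    else:
        cdf = reference.cdf_standardized(sm_std)
        result.prob_empirical = cdf if sm > 0 else 1.0 - cdf
    return result


def classify_samples(
    em: ExpressionMatrix,
    sig: Signature,
    mode: str | None = "cantelli",
    reference: SMDistribution | None = None,
    sigma: float = 1.0,
) -> list[SMResult]:
    """Score and label every sample; ``mode=None`` emits sign labels only
    (the small-panel qRT-PCR case, where no SM distribution is estimable)."""
    sms = score_samples(em, sig)
    out = []
    for sample_id, sm in sms.items():
        if mode is None:
            out.append(SMResult(sample_id, float(sm), float("nan"), classify_sm(sm)))
        else:
            out.append(class_probability(sm, mode, reference, sigma, sample_id))
    return out


class SummaryMetricClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style wrapper around the summary-metric sign rule.

    Parameters
    ----------
    signature : Signature or None
        Fixed signature to apply. When ``None``, :meth:`fit` derives the
        per-gene directions from the sign of the class mean difference over
        all input features.
    sigma : float, default=1.0
        Cantelli sigma on the scale :meth:`decision_function` operates on.
    classes : tuple, default=("HP", "SSA/P")
        Negative- and positive-SM class names.
    """

    def __init__(self, signature: Signature | None = None, sigma: float = 1.0,
                 classes: tuple = ("HP", "SSA/P")):
        self.signature = signature
        self.sigma = sigma
        self.classes = classes

    def fit(self, X, y=None):
        if self.signature is not None:
            self.signature_ = self.signature
            self.n_features_in_ = len(self.signature)
            self.classes_ = np.asarray(self.classes)
            return self
        X, y = check_X_y(X, y, dtype=float)
        neg, pos = self.classes
        diff = X[y == pos].mean(axis=0) - X[y == neg].mean(axis=0)
        self.signature_ = Signature(
            [f"g{i}" for i in range(X.shape[1])], np.where(diff >= 0, 1, -1)
        )
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.asarray(self.classes)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "signature_")
        X = check_array(X, dtype=float)
        return (X * self.signature_.direction[None, :]).mean(axis=1)

    def predict(self, X):
        sm = self.decision_function(X)
        neg, pos = self.classes
        return np.array([pos if v > 0 else (neg if v < 0 else UNCERTAIN) for v in sm])

    def predict_cantelli(self, X):
        """Cantelli lower bound per sample, NaN inside the uncertain zone."""
        sm = self.decision_function(X)
        return np.array(
            [p if (p := cantelli_probability(v, self.sigma)) is not None else np.nan
             for v in sm]
        )
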