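"""Cross-platform concordant-gene selection by a resampling correlation test.

A gene is a good candidate for a platform-independent signature when its
expression profile correlates between two platforms *because of phenotype*:
drawing equal numbers of HP and SSA/P samples from each platform and pairing
them phenotype-to-phenotype should yield a high Pearson correlation
(rho_true), while drawing the same numbers of samples ignoring labels should
not (rho_random). Both resampling distributions are estimated per gene; the
one-sided hypothesis

    H0: mean(rho_true) <= mean(rho_random) + max_g SD(rho_true ∪ rho_random)
    H1: mean(rho_true) >  mean(rho_random) + max_g SD(rho_true ∪ rho_random)

is tested with a one-sided Mann-Whitney rank-sum test, the global pooled-SD
offset acting as an effect-size guard (with many iterations p-values saturate,
so the offset — optionally scaled by ``offset_multiplier`` — is the effective
selector).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io import ExpressionMatrix


@dataclass
class ConcordanceConfig:
    n_iter: int = 10_000
    alpha: float = 0.05
    offset_multiplier: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ConcordanceResult:
    gene_id: str
    mean_rho_true: float
    mean_rho_random: float
    pooled_sd: float
    p_value: float
    concordant: bool


@dataclass
class ConcordanceTestResult:
    """Per-gene results plus the shared offset and raw draw matrices."""

    results: list[ConcordanceResult]
    offset: float
    rho_true_draws: np.ndarray    # (n_genes, n_iter)
    rho_random_draws: np.ndarray  # (n_genes, n_iter)

    @property
    def concordant_genes(self) -> set[str]:
        return {r.gene_id for r in self.results if r.concordant}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.results],
                "mean_rho_true": [r.mean_rho_true for r in self.results],
                "mean_rho_random": [r.mean_rho_random for r in self.results],
                "pooled_sd": [r.pooled_sd for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "concordant": [r.concordant for r in self.results],
            }
        )


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``a`` with the matching row of ``b``.

    A row that is constant in either matrix has undefined correlation; it is
    recorded as 0, which keeps draw counts balanced and penalizes genes that
    carry no information in a draw.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac * ac).sum(axis=1) * (bc * bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def _class_indices(em: ExpressionMatrix, classes: Sequence[str]) -> list[np.ndarray]:
    labels = em.labels.to_numpy()
    out = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"platform {em.platform!r} needs >=2 samples of class {c!r}")
        out.append(idx)
    return out


def resample_correlations(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    preserve_labels: bool,
    cfg: ConcordanceConfig,
    rng: np.random.Generator | None = None,
    classes: Sequence[str] = ("HP", "SSA/P"),
) -> np.ndarray:
    """Per-gene resampled between-platform Pearson correlations.

    Each iteration draws, without replacement, min(n1, m1) phenotype-1 and
    min(n2, m2) phenotype-2 samples from each platform (``preserve_labels``)
    or the same total count ignoring labels, pairs the drawn columns
    platform-to-platform (phenotype-1 block first), and records each gene's
    Pearson correlation over the paired values.

    Returns an (n_genes, n_iter) array.
    """
    if X.gene_ids != Y.gene_ids:
        raise ValueError("X and Y must share the same gene set in the same order")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    x_cls = _class_indices(X, classes)
    y_cls = _class_indices(Y, classes)
    k = [min(xi.size, yi.size) for xi, yi in zip(x_cls, y_cls)]
    if sum(k) < 3:
        raise ValueError(f"paired draw size {sum(k)} < 3; correlation too degenerate")

    xv, yv = X.values, Y.values
    x_all = np.concatenate(x_cls)
    y_all = np.concatenate(y_cls)
    draws = np.empty((X.n_genes, cfg.n_iter), dtype=float)
    for it in range(cfg.n_iter):
        if preserve_labels:
            xi = np.concatenate([rng.choice(c, ki, replace=False)
                                 for c, ki in zip(x_cls, k)])
            yi = np.concatenate([rng.choice(c, ki, replace=False)
                                 for c, ki in zip(y_cls, k)])
        else:
            xi = rng.choice(x_all, sum(k), replace=False)
            yi = rng.choice(y_all, sum(k), replace=False)
        draws[:, it] = _rowwise_pearson(xv[:, xi], yv[:, yi])
    return draws


def pooled_sds(rho_true: np.ndarray, rho_random: np.ndarray) -> np.ndarray:
    """Per-gene SD of the union of the true and random draw sets."""
    combined = np.concatenate([rho_true, rho_random], axis=1)
    return combined.std(axis=1, ddof=1)


def global_offset(
    rho_true: np.ndarray, rho_random: np.ndarray, offset_multiplier: float = 1.0
) -> float:
    """max over genes of SD(rho_true ∪ rho_random), times ``offset_multiplier``."""
    if rho_true.shape[0] == 0:
        raise ValueError("need at least one gene")
    return float(offset_multiplier * pooled_sds(rho_true, rho_random).max())


def test_concordance(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    cfg: ConcordanceConfig | None = None,
    classes: Sequence[str] = ("HP", "SSA/P"),
) -> ConcordanceTestResult:
    """Run the full concordance test between two platforms.

    Per gene, a one-sided Mann-Whitney rank-sum test compares the rho_true
    draws against (rho_random draws + global offset); a gene is concordant
    when p < ``cfg.alpha`` (unadjusted).
    """
    cfg = cfg or ConcordanceConfig()
    rng = np.random.default_rng(cfg.seed)
    rho_true = resample_correlations(X, Y, True, cfg, rng, classes)
    rho_random = resample_correlations(X, Y, False, cfg, rng, classes)
    sds = pooled_sds(rho_true, rho_random)
    offset = float(cfg.offset_multiplier * sds.max())

    results = []
    for g, gene in enumerate(X.gene_ids):
        t, r = rho_true[g], rho_random[g] + offset
        if np.ptp(t) == 0 and np.ptp(r) == 0 and t[0] == r[0]:
            p = 1.0  # all observations tied; no evidence either way
        else:
            p = float(mannwhitneyu(t, r, alternative="greater",
                                   method="asymptotic").pvalue)
        results.append(
            ConcordanceResult(
                gene_id=gene,
                mean_rho_true=float(rho_true[g].mean()),
                mean_rho_random=float(rho_random[g].mean()),
                pooled_sd=float(sds[g]),
                p_value=p,
                concordant=p < cfg.alpha,
            )
        )
    return ConcordanceTestResult(results, offset, rho_true, rho_random)


class ConcordantGeneSelector:
    """Feature selector keeping genes concordant with a second platform.

    Sklearn-style transformer over samples x genes arrays: ``fit(X, y)``
    runs the concordance test between the training platform and the ``other``
    platform supplied at construction; ``transform`` keeps concordant columns.

    Parameters
    ----------
    other : ExpressionMatrix
        The second platform (same genes, same order, own samples/labels).
    gene_ids : sequence of str
        Gene ids naming the columns of X, matching ``other``'s gene order.
    """

    def __init__(self, other: ExpressionMatrix, gene_ids: Sequence[str],
                 n_iter: int = 10_000, alpha: float = 0.05,
                 offset_multiplier: float = 1.0, random_state: int | None = None,
                 classes: Sequence[str] = ("HP", "SSA/P")):
        self.other = other
        self.gene_ids = list(gene_ids)
        self.n_iter = n_iter
        self.alpha = alpha
        self.offset_multiplier = offset_multiplier
        self.random_state = random_state
        self.classes = classes

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        train = ExpressionMatrix(
            pd.DataFrame(X.T, index=self.gene_ids,
                         columns=[f"s{i}" for i in range(X.shape[0])]),
            pd.Series(np.asarray(y), index=[f"s{i}" for i in range(X.shape[0])]),
        )
        cfg = ConcordanceConfig(n_iter=self.n_iter, alpha=self.alpha,
                                offset_multiplier=self.offset_multiplier,
                                seed=self.random_state)
        self.result_ = test_concordance(train, self.other, cfg, self.classes)
        concordant = self.result_.concordant_genes
        self.support_ = np.array([g in concordant for g in self.gene_ids])
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def concordant_intersection(*results: ConcordanceTestResult) -> set[str]:
    """Genes concordant in every supplied test result."""
    if not results:
        return set()
    genes = results[0].concordant_genes
    for r in results[1:]:
        genes &= r.concordant_genes
    return genes
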