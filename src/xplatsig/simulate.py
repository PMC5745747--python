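"""Synthetic two-platform expression data and qRT-PCR-like panels.

The generator emulates the study design the pipeline targets: two platforms
measuring the same genes on distinct sample cohorts, each sample labeled HP or
SSA/P, with per-gene Gaussian expression on the log2 scale. Three gene
regimes are planted:

* ``concordant`` — phenotype means at ±fc/2 with small within-phenotype SD
  (fold change exceeds within-phenotype variability in both platforms: the
  regime the concordance test should detect),
* ``discordant_de`` — the same ±fc/2 means but within-phenotype SD of
  ``sd_noise`` (fold change drowned by variability: should not be detected),
* ``background`` — mean 0 under both phenotypes.

Optional per-gene platform offsets and per-sample shifts model systematic
platform bias and technical inter-sample bias. The qRT-PCR generator inverts
the scale (larger value = lower expression, as for levels relative to 18S
rRNA) and adds per-sample shift biases, so the full two-step normalization is
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, Signature

REGIMES = ("concordant", "discordant_de", "background")


@dataclass
class SimConfig:
    n_genes: int = 200
    n_concordant: int = 20
    n_de_discordant: int = 20
    n_hp: int = 20          # per platform
    n_ssa: int = 20         # per platform
    fc: float = 1.0         # log2 fold change between phenotypes
    sd_concordant: float = 0.25
    sd_noise: float = 1.0
    platform_bias_sd: float = 0.0
    sample_shift_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_genes, self.n_hp, self.n_ssa) <= 0:
            raise ValueError("counts must be positive")
        if self.n_concordant + self.n_de_discordant > self.n_genes:
            raise ValueError("n_concordant + n_de_discordant must be <= n_genes")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def _platform(cfg: SimConfig, rng: np.random.Generator, means: np.ndarray,
              sds: np.ndarray, tag: str) -> ExpressionMatrix:
    """One platform: columns are HP samples then SSA/P samples."""
    n_samples = cfg.n_hp + cfg.n_ssa
    # means: (n_genes, 2) per-phenotype means; sds: (n_genes,)
    pheno = np.array([0] * cfg.n_hp + [1] * cfg.n_ssa)
    mu = means[:, pheno]
    vals = rng.normal(mu, sds[:, None])
    if cfg.platform_bias_sd > 0:
        vals += rng.normal(0.0, cfg.platform_bias_sd, size=(cfg.n_genes, 1))
    if cfg.sample_shift_sd > 0:
        vals += rng.normal(0.0, cfg.sample_shift_sd, size=(1, n_samples))
    samples = [f"{tag}_HP{i + 1:02d}" for i in range(cfg.n_hp)] + [
        f"{tag}_SSA{i + 1:02d}" for i in range(cfg.n_ssa)
    ]
    labels = pd.Series(["HP"] * cfg.n_hp + ["SSA/P"] * cfg.n_ssa, index=samples)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=_gene_ids(cfg.n_genes), columns=samples),
        labels, platform=tag,
    )


def simulate_two_platform(cfg: SimConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Two platforms measuring the same genes on independent cohorts.

    Returns (platform A, platform B, truth table); the truth table flags each
    gene's regime and its true log2 fold change. Bit-identical for a fixed
    config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    regime = np.array(
        ["concordant"] * cfg.n_concordant
        + ["discordant_de"] * cfg.n_de_discordant
        + ["background"] * (cfg.n_genes - cfg.n_concordant - cfg.n_de_discordant)
    )
    means = np.zeros((cfg.n_genes, 2))  # columns: HP, SSA/P
    de = regime != "background"
    means[de, 0] = -cfg.fc / 2.0
    means[de, 1] = cfg.fc / 2.0
    sds = np.where(regime == "concordant", cfg.sd_concordant, cfg.sd_noise)
    em_a = _platform(cfg, rng, means, sds, "A")
    em_b = _platform(cfg, rng, means, sds, "B")
    truth = pd.DataFrame(
        {"gene_id": genes, "regime": regime, "log2fc": np.where(de, cfg.fc, 0.0)}
    )
    return em_a, em_b, truth


def simulate_qpcr(
    sig: Signature,
    n_hp: int = 24,
    n_ssa: int = 21,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    sample_shift_sd: float = 0.0,
    baseline: float = 10.0,
    seed: int | None = None,
    tag: str = "qpcr",
) -> ExpressionMatrix:
    """Raw qRT-PCR-like panel for the signature genes.

    Latent expression per gene is direction-consistent: SSA/P samples sit at
    +direction*effect/2 and HP samples at -direction*effect/2, with Gaussian
    noise. The scale is then inverted (multiplied by -1, larger = lower
    expression), shifted by a positive baseline, and each sample receives an
    additive shift bias ~ N(0, sample_shift_sd).
    """
    rng = np.random.default_rng(seed)
    n_samples = n_hp + n_ssa
    pheno = np.array([-1.0] * n_hp + [1.0] * n_ssa)  # HP = -1, SSA/P = +1
    direction = sig.direction.astype(float)
    mu = np.outer(direction, pheno) * (effect / 2.0)
    latent = rng.normal(mu, noise_sd)
    raw = baseline - latent  # inverted scale
    if sample_shift_sd > 0:
        raw += rng.normal(0.0, sample_shift_sd, size=(1, n_samples))
    samples = [f"{tag}_HP{i + 1:02d}" for i in range(n_hp)] + [
        f"{tag}_SSA{i + 1:02d}" for i in range(n_ssa)
    ]
    labels = pd.Series(["HP"] * n_hp + ["SSA/P"] * n_ssa, index=samples)
    return ExpressionMatrix(
        pd.DataFrame(raw, index=sig.gene_ids, columns=samples), labels, platform=tag
    )
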