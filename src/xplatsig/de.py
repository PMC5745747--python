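"""Differential-expression thresholding and the anatomical-location Venn filter.

The pipeline consumes DE result tables from three two-group comparisons of
colon biopsies — control-right vs control-left (CR_CL), HP vs SSA/P and CR vs
SSA/P — and partitions the called genes so that genes whose differential
expression is explainable by anatomical location (right vs left colon) can be
excluded before signature training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


def call_de(table: pd.DataFrame, lfc_min: float = 0.5, q_max: float = 0.05) -> set[str]:
    """Genes with |log2 fold change| > ``lfc_min`` and BH-adjusted q < ``q_max``.

    Both inequalities are strict; boundary genes are excluded.
    """
    mask = (table["log2fc"].abs() > lfc_min) & (table["q"] < q_max)
    return set(table.loc[mask, "gene_id"])


@dataclass(frozen=True)
class VennPartition:
    """Disjoint regions of the three-comparison Venn diagram.

    ``ssa_specific`` (DE in both HP_SSA/P and CR_SSA/P but not CR_CL) is the
    candidate pool for signature training; ``triple_intersection`` is excluded
    downstream; the location regions capture genes confounded with anatomical
    position.
    """

    ssa_specific: frozenset
    hp_ssa_only: frozenset
    cr_ssa_only: frozenset
    triple_intersection: frozenset
    location_only: frozenset
    location_hp_ssa: frozenset  # CR_CL ∩ HP_SSA/P, not CR_SSA/P
    location_cr_ssa: frozenset  # CR_CL ∩ CR_SSA/P, not HP_SSA/P

    def regions(self) -> tuple[frozenset, ...]:
        return (self.ssa_specific, self.hp_ssa_only, self.cr_ssa_only,
                self.triple_intersection, self.location_only,
                self.location_hp_ssa, self.location_cr_ssa)


def venn_partition(de_cr_cl: set, de_hp_ssa: set, de_cr_ssa: set) -> VennPartition:
    """Partition three DE gene sets into the seven exclusive Venn regions."""
    cr_cl, hp_ssa, cr_ssa = set(de_cr_cl), set(de_hp_ssa), set(de_cr_ssa)
    return VennPartition(
        ssa_specific=frozenset((hp_ssa & cr_ssa) - cr_cl),
        hp_ssa_only=frozenset(hp_ssa - cr_cl - cr_ssa),
        cr_ssa_only=frozenset(cr_ssa - cr_cl - hp_ssa),
        triple_intersection=frozenset(cr_cl & hp_ssa & cr_ssa),
        location_only=frozenset(cr_cl - hp_ssa - cr_ssa),
        location_hp_ssa=frozenset((cr_cl & hp_ssa) - cr_ssa),
        location_cr_ssa=frozenset((cr_cl & cr_ssa) - hp_ssa),
    )


def same_level(cr_mean: float, hp_mean: float, tol: float = 0.1) -> bool:
    """True when CR and HP mean expressions are at the same level.

    Uses the relative criterion e = |CR - HP| / (CR + HP + 0.01) < tol on
    log2(1+FPKM)-scale group means. A non-positive denominator (possible for
    near-zero log expressions) is flagged not-same-level with a warning.
    """
    denom = cr_mean + hp_mean + 0.01
    if denom <= 0:
        warnings.warn(
            f"same_level denominator {denom:.4g} <= 0; treating as not same level",
            RuntimeWarning,
            stacklevel=2,
        )
        return False
    return abs(cr_mean - hp_mean) / denom < tol
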