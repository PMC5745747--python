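"""Containers and plain-text I/O for expression matrices, DE tables and signatures.

Expression values are stored genes x samples on a log2 scale, with a per-sample
phenotype label (HP, SSA/P, CR, CL or unknown) and a free-text platform tag.
All file formats are delimited text or JSON so fixtures and results stay
human-readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PHENOTYPES = ("HP", "SSA/P", "CR", "CL", "unknown")

SIGNATURE_FORMAT_VERSION = 1
MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """Log-scale gene expression with phenotype labels.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes x samples matrix; index = gene ids, columns = sample ids.
    labels : pandas.Series
        Phenotype per sample, indexed by sample id. Values must be one of
        ``PHENOTYPES``. Missing samples default to ``"unknown"``.
    platform : str
        Free-text platform tag (e.g. ``"rnaseq"``, ``"illumina"``).
    """

    data: pd.DataFrame
    labels: pd.Series = None
    platform: str = ""

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ParseError("expression values must be finite (no NaN/inf)")
        self.data = self.data.astype(float)
        if self.labels is None:
            self.labels = pd.Series("unknown", index=self.data.columns)
        self.labels = pd.Series(self.labels).astype(str)
        self.labels = self.labels.reindex(self.data.columns, fill_value="unknown")
        bad = sorted(set(self.labels) - set(PHENOTYPES))
        if bad:
            raise ParseError(f"unknown phenotype labels: {bad}; allowed: {PHENOTYPES}")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes], self.labels.copy(), self.platform)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data[samples], self.labels[samples], self.platform)

    def subset_labels(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = set(keep)
        samples = [s for s in self.sample_ids if self.labels[s] in keep]
        return self.subset_samples(samples)

    def to_xy(self, classes: Sequence[str] = ("HP", "SSA/P")):
        """Samples-x-genes design matrix and label vector for sklearn estimators."""
        sub = self.subset_labels(classes)
        return sub.values.T, sub.labels.to_numpy(), sub.gene_ids

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.labels.copy(), self.platform)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.data.equals(other.data)
            and self.labels.equals(other.labels)
            and self.platform == other.platform
        )


@dataclass
class Signature:
    """Ordered gene list with per-gene direction (+1 up in SSA/P, -1 up in HP)."""

    gene_ids: list[str]
    direction: np.ndarray

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("signature gene ids must be unique")
        self.direction = np.asarray(self.direction, dtype=int)
        if self.direction.shape != (len(self.gene_ids),):
            raise ValueError("direction must have one sign per gene")
        if not np.all(np.isin(self.direction, (-1, 1))):
            raise ValueError("directions must be +1 or -1")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def direction_of(self, gene: str) -> int:
        return int(self.direction[self.gene_ids.index(gene)])

    def to_dict(self) -> dict:
        return {
            "format_version": SIGNATURE_FORMAT_VERSION,
            "genes": [
                {"gene_id": g, "direction": int(d)}
                for g, d in zip(self.gene_ids, self.direction)
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Signature":
        if d.get("format_version") != SIGNATURE_FORMAT_VERSION:
            raise ParseError(f"unsupported signature format: {d.get('format_version')}")
        genes = d["genes"]
        return cls([g["gene_id"] for g in genes], [g["direction"] for g in genes])


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log_transform_fpkm(fpkm, labels=None, platform: str = "rnaseq") -> ExpressionMatrix:
    """Apply the log2(1 + FPKM) transform to a non-negative abundance matrix.

    Accepts a DataFrame (genes x samples), an array, or an ``ExpressionMatrix``
    holding raw FPKM values. Negative entries are rejected.
    """
    if isinstance(fpkm, ExpressionMatrix):
        df, labels, platform = fpkm.data, fpkm.labels, fpkm.platform
    else:
        df = pd.DataFrame(fpkm)
    vals = df.to_numpy(dtype=float)
    if vals.size and np.nanmin(vals) < 0:
        raise ValueError("FPKM values must be non-negative")
    return ExpressionMatrix(pd.DataFrame(np.log2(1.0 + vals), index=df.index,
                                         columns=df.columns), labels, platform)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def collapse_probes(
    probe_matrix: ExpressionMatrix,
    probe_to_gene: Mapping[str, str],
    group_labels: Sequence[str] = ("HP", "SSA/P"),
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    For genes measured by several probes, the probe whose two-sample Welch
    t-statistic between the two phenotype groups has the largest magnitude is
    retained (ties broken by file order). Probes without a gene mapping are
    dropped.
    """
    a_label, b_label = group_labels
    a_ids = [s for s in probe_matrix.sample_ids if probe_matrix.labels[s] == a_label]
    b_ids = [s for s in probe_matrix.sample_ids if probe_matrix.labels[s] == b_label]

    gene_probes: dict[str, list[str]] = {}
    for probe in probe_matrix.gene_ids:  # rows are probes here
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        gene_probes.setdefault(str(gene), []).append(probe)

    chosen: list[str] = []
    genes: list[str] = []
    for gene, probes in gene_probes.items():
        if len(probes) == 1:
            best = probes[0]
        else:
            if len(a_ids) < 2 or len(b_ids) < 2:
                raise ValueError(
                    "probe selection needs >=2 samples in each group "
                    f"({a_label}: {len(a_ids)}, {b_label}: {len(b_ids)})"
                )
            a = probe_matrix.data.loc[probes, a_ids].to_numpy()
            b = probe_matrix.data.loc[probes, b_ids].to_numpy()
            t = stats.ttest_ind(a, b, axis=1, equal_var=False).statistic
            t = np.where(np.isfinite(t), np.abs(t), -np.inf)
            best = probes[int(np.argmax(t))]  # argmax keeps first on ties
        chosen.append(best)
        genes.append(gene)

    collapsed = probe_matrix.data.loc[chosen].copy()
    collapsed.index = genes
    return ExpressionMatrix(collapsed, probe_matrix.labels.copy(), probe_matrix.platform)


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------

def write_expression_matrix(em: ExpressionMatrix, path, labels_path=None) -> None:
    """Write a genes x samples TSV (first column ``gene_id``) and, optionally,
    a two-column ``sample_id<TAB>label`` companion file."""
    df = em.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    if labels_path is not None:
        lab = em.labels.rename("label")
        lab.index.name = "sample_id"
        lab.to_csv(labels_path, sep="\t")


def read_expression_matrix(path, labels_path=None, platform: str = "") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise ParseError(f"first column must be 'gene_id', got {df.index.name!r}")
    if df.isna().to_numpy().any():
        raise ParseError("missing values are not supported")
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", index_col=0)
        if "label" not in lab.columns:
            raise ParseError("labels file needs columns sample_id, label")
        labels = lab["label"].astype(str)
        labels.index = labels.index.astype(str)
    return ExpressionMatrix(df, labels, platform)


# ---------------------------------------------------------------------------
# DE table I/O
# ---------------------------------------------------------------------------

_CUFFDIFF_COLUMNS = {"gene": "gene_id", "log2(fold_change)": "log2fc",
                     "p_value": "p", "q_value": "q"}


def read_de_table(path) -> pd.DataFrame:
    """Read a per-gene DE table with columns gene_id, log2fc, p[, q].

    Cuffdiff ``gene_exp.diff`` headers (gene, log2(fold_change), p_value,
    q_value) are accepted and renamed. If q is absent it is filled by BH
    adjustment of p.
    """
    df = pd.read_csv(path, sep="\t")
    if set(_CUFFDIFF_COLUMNS) <= set(df.columns):
        df = df[list(_CUFFDIFF_COLUMNS)].rename(columns=_CUFFDIFF_COLUMNS)
    required = {"gene_id", "log2fc", "p"}
    if not required <= set(df.columns):
        raise ParseError(f"DE table needs columns {sorted(required)}, got {list(df.columns)}")
    df["gene_id"] = df["gene_id"].astype(str)
    if df["gene_id"].duplicated().any():
        raise ParseError("duplicate gene ids in DE table")
    for col in ("p", "q"):
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise ParseError(f"column {col!r} must lie in [0, 1]")
    if "q" not in df.columns:
        df["q"] = bh_adjust(df["p"].to_numpy(dtype=float))
    return df[["gene_id", "log2fc", "p", "q"]]


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON I/O for signatures and models
# ---------------------------------------------------------------------------

def write_signature(sig: Signature, path) -> None:
    Path(path).write_text(json.dumps(sig.to_dict(), indent=2) + "\n")


def read_signature(path) -> Signature:
    return Signature.from_dict(json.loads(Path(path).read_text()))


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
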