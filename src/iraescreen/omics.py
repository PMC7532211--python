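"""Per-sample omics scores and per-cancer-type factor medians.

Derived scores: tumor mutational burden (TMB, nonsilent mutations per
sample), cytolytic activity (geometric mean of GZMA and PRF1 expression)
and mean z-score signature scores over a gene set.  All per-sample factors
are collapsed to one median per cancer type and joined with the observed
ROR vector into a :class:`FactorTable` for screening and model selection.

The signature score here is the mean per-gene z-score of log2(x+1)
expression (sample standard deviation, n-1).  It is a deliberately simple
monotone summary of coordinate up-regulation of a gene set; scores are not
claimed to equal GSVA/ssGSEA enrichment scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: MAF-style variant classifications counted as nonsilent (protein-altering).
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

#: Classifications recognised but counted as silent.
SILENT_CLASSES = frozenset(
    {"Silent", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "Intron", "IGR", "RNA"}
)


def compute_tmb(
    mutations: pd.DataFrame,
    roster: Sequence[str] | None = None,
    nonsilent_classes: frozenset[str] = NONSILENT_CLASSES,
    sample_col: str = "Tumor_Sample_Barcode",
    class_col: str = "Variant_Classification",
    strict: bool = False,
) -> pd.Series:
    """Nonsilent mutation count per sample from a MAF-like table.

    Samples in ``roster`` absent from the table get a count of 0.  Unknown
    classification strings are warned about and treated as silent unless
    ``strict`` is set, in which case they raise ``ValueError``.
    """
    classes = mutations[class_col]
    known = nonsilent_classes | SILENT_CLASSES
    unknown = set(classes) - known
    if unknown:
        msg = f"unknown variant classification(s) treated as silent: {sorted(unknown)}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    counts = (
        mutations.loc[classes.isin(nonsilent_classes), sample_col]
        .value_counts()
        .astype(int)
    )
    if roster is not None:
        counts = counts.reindex(list(roster), fill_value=0).astype(int)
    counts.name = "tmb"
    counts.index.name = "sample"
    return counts


def cytolytic_activity(
    expr: pd.DataFrame,
    marker_genes: Sequence[str] = ("GZMA", "PRF1"),
    offset: float = 0.01,
) -> pd.Series:
    """Geometric mean of cytolytic marker expression per sample.

    ``expr`` is a gene x sample matrix of nonnegative TPM-like values;
    the score is exp(mean(ln(x + offset))) over the marker genes.
    """
    missing = [g for g in marker_genes if g not in expr.index]
    if missing:
        raise KeyError(f"marker gene(s) absent from expression matrix: {missing}")
    vals = expr.loc[list(marker_genes)].to_numpy(dtype=float)
    score = np.exp(np.log(vals + offset).mean(axis=0))
    return pd.Series(score, index=expr.columns, name="cytolytic_activity")


def signature_score(
    expr: pd.DataFrame,
    gene_set: Sequence[str],
    ddof: int = 1,
) -> pd.Series:
    """Mean per-gene z-score of log2(x+1) expression over a gene set.

    z-scores are computed across the samples of the given matrix (call it
    per cancer type for within-type scoring).  Genes absent from the matrix
    are dropped with a warning; genes with zero variance across samples are
    excluded from the mean.
    """
    present = [g for g in gene_set if g in expr.index]
    absent = [g for g in gene_set if g not in expr.index]
    if absent:
        warnings.warn(f"signature genes absent from matrix: {absent}")
    if not present:
        raise KeyError("no signature gene present in the expression matrix")
    x = np.log2(expr.loc[present].to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all signature genes have zero variance across samples")
    if not keep.all():
        warnings.warn(
            f"zero-variance signature gene(s) excluded: "
            f"{[g for g, k in zip(present, keep) if not k]}"
        )
    x = x[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.Series(z.mean(axis=0), index=expr.columns, name="signature_score")


@dataclass
class FactorTable:
    """Cancer-type x factor matrix of per-type medians, plus the ROR vector.

    ``factors`` has one row per cancer type; missing medians are NaN, never
    silently zero.  ``ror`` is aligned on the same index once joined.
    """

    factors: pd.DataFrame
    ror: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.factors.index.has_duplicates:
            raise ValueError("one row per cancer type required")
        if self.ror is not None:
            self.ror = self.ror.reindex(self.factors.index)

    @property
    def cancer_types(self) -> list[str]:
        return list(self.factors.index)

    def with_ror(self, ror: pd.Series) -> "FactorTable":
        return FactorTable(factors=self.factors, ror=ror)

    def to_tsv(self, path) -> None:
        df = self.factors.copy()
        if self.ror is not None:
            df.insert(0, "ror", self.ror)
        df.index.name = "cancer_type"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FactorTable":
        df = pd.read_csv(path, sep="\t", index_col="cancer_type")
        ror = None
        if "ror" in df.columns:
            ror = df.pop("ror")
        return cls(factors=df, ror=ror)


def aggregate_medians(
    per_sample: pd.DataFrame,
    sample_types: pd.Series,
) -> FactorTable:
    """Collapse per-sample factor values to per-cancer-type medians.

    ``per_sample`` is sample x factor; ``sample_types`` maps sample id to
    cancer type.  The median uses the midpoint of the two central order
    statistics for even n.  A type with no observed value for a factor gets
    NaN.
    """
    unlabeled = per_sample.index.difference(sample_types.index)
    if len(unlabeled):
        raise ValueError(f"unlabeled sample(s): {list(unlabeled[:10])}")
    labels = sample_types.loc[per_sample.index]
    medians = per_sample.groupby(labels.to_numpy()).median()
    medians.index.name = "cancer_type"
    return FactorTable(factors=medians.sort_index())
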