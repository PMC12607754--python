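"""Count-table pre-filtering, CPM normalization, and gene-set day profiles.

Targeted-sequencing count tables (genes x samples) carry a differentiation
day per sample.  Quality filtering removes samples with library size below
0.2 million reads or mean count per gene below 1.5 (strict '<': equality
survives).  Counts are normalized to counts per million (CPM): each entry
divided by its sample's total mapped reads, times 1e6, so every retained
column sums to exactly one million.  The gene-set day matrix is log2 of the
*mean* CPM per day (log2-of-mean, matching heatmap conventions); zero means
become a -inf sentinel unless a pseudocount is supplied, keeping the choice
visible rather than silently shifting values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError

__all__ = [
    "CountMatrix",
    "CpmMatrix",
    "GeneSetDayMatrix",
    "prefilter_samples",
    "cpm",
    "geneset_day_matrix",
    "read_counts",
    "write_counts",
]

DEFAULT_MIN_LIBSIZE = 200_000
DEFAULT_MIN_AVG_GENE_COUNT = 1.5


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer counts (genes x samples) with per-sample day."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids
    sample_meta: pd.DataFrame  # index = sample ids, column 'day'

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValidationError("gene and sample ids must be unique")
        if (c.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if "day" not in self.sample_meta.columns:
            raise ValidationError("sample_meta needs a 'day' column")
        missing = set(c.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without day metadata: {sorted(missing)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class CpmMatrix:
    """Counts-per-million values with the library sizes they came from."""

    values: pd.DataFrame
    library_sizes: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if (v < 0).any():
            raise ValidationError("CPM values must be non-negative")
        sums = v.sum(axis=0)
        if not np.allclose(sums, 1e6, rtol=1e-6):
            raise ValidationError("every CPM column must sum to 1e6")


@dataclass(frozen=True)
class GeneSetDayMatrix:
    """Per-gene, per-day (log2) mean CPM, with unmatched genes reported."""

    values: pd.DataFrame  # index = gene ids, columns = day labels
    missing_genes: tuple[str, ...]
    log2: bool
    pseudocount: float


def prefilter_samples(
    cm: CountMatrix,
    min_libsize: float = DEFAULT_MIN_LIBSIZE,
    min_avg_gene_count: float = DEFAULT_MIN_AVG_GENE_COUNT,
) -> tuple[CountMatrix, list[dict]]:
    """Drop low-quality samples; report who was removed and why.

    A sample is removed when its library size (column sum) is strictly below
    ``min_libsize`` or its mean count per gene (over all table rows) is
    strictly below ``min_avg_gene_count``.
    """
    lib = cm.library_sizes()
    avg = cm.counts.mean(axis=0)
    report = []
    keep = []
    for s in cm.counts.columns:
        reasons = []
        if lib[s] < min_libsize:
            reasons.append("library_size")
        if avg[s] < min_avg_gene_count:
            reasons.append("avg_gene_count")
        if reasons:
            report.append({"sample": s, "reasons": reasons,
                           "library_size": int(lib[s]),
                           "avg_gene_count": float(avg[s])})
        else:
            keep.append(s)
    if not keep:
        raise AnalysisError("pre-filter removed every sample")
    filtered = CountMatrix(cm.counts[keep], cm.sample_meta.loc[keep])
    return filtered, report


def cpm(cm: CountMatrix) -> CpmMatrix:
    """Counts per million: count / library size * 1e6, per sample."""
    lib = cm.library_sizes()
    zero = lib[lib == 0]
    if len(zero):
        raise AnalysisError(f"zero library size for sample(s): {list(zero.index)}")
    values = cm.counts.astype(float) / lib.astype(float) * 1e6
    return CpmMatrix(values, lib, cm.sample_meta.loc[cm.counts.columns])


def geneset_day_matrix(
    cpm_m: CpmMatrix,
    gene_set: Sequence[str],
    day_order: Sequence[str] | None = None,
    log2: bool = True,
    pseudocount: float = 0.0,
) -> GeneSetDayMatrix:
    """Gene x day matrix of (log2) mean CPM for a gene set.

    Day columns follow ``day_order`` when given (unknown labels are an
    error) and first-appearance order of the metadata otherwise.  Genes of
    the set absent from the table are reported in ``missing_genes``, never
    silently dropped.  With ``pseudocount = 0`` a zero mean maps to -inf.
    """
    days_meta = cpm_m.sample_meta["day"]
    seen = list(dict.fromkeys(days_meta))
    if day_order is None:
        day_order = seen
    else:
        unknown = [d for d in day_order if d not in seen]
        if unknown:
            raise ValidationError(f"unknown day label(s): {unknown}")
    present = [g for g in gene_set if g in cpm_m.values.index]
    missing = tuple(g for g in gene_set if g not in cpm_m.values.index)
    if not present:
        raise AnalysisError("none of the gene set's genes are in the table")
    cols = {}
    for day in day_order:
        samples = days_meta.index[days_meta == day]
        cols[day] = cpm_m.values.loc[present, samples].mean(axis=1)
    mat = pd.DataFrame(cols, index=present)
    if log2:
        with np.errstate(divide="ignore"):
            mat = np.log2(mat + pseudocount)
    return GeneSetDayMatrix(mat, missing, log2, pseudocount)


def read_counts(counts_path, meta_path) -> CountMatrix:
    """Read a genes-x-samples TSV plus a (sample_id, day) metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"day": str})
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.sample_meta.to_csv(meta_path, sep="\t")
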