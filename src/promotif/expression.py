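"""Expression quantification from mapped-read count tables.

Two library-size normalizations are provided:

* RPKM = C x 10^9 / (N x L) — reads per kilobase per million mapped reads,
  where C is the gene's mapped-read count, N the sample's total mapped reads
  and L the gene length in base pairs; and
* RPM  = C x 10^6 / N — reads per million, length-unadjusted, for comparing
  one gene across samples of different depth.

N is the externally supplied per-sample library size (total mapped reads),
not recomputed from the table; upstream trimming/alignment/counting is out of
scope.  Replicate statistics (mean, CV%, rank) feed the heatmap-style ranked
views; the optional +1 offset exists only for log-scale display export and is
never used in statistics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionTable",
    "compute_rpkm",
    "compute_rpm",
    "replicate_stats",
    "read_counts_tsv",
    "read_samples_tsv",
]


@dataclass
class CountMatrix:
    """Genes x samples read counts with gene lengths and library sizes.

    ``counts`` is indexed by gene_id with one column per sample;
    ``lengths`` (bp) is indexed by gene_id; ``library_sizes`` (total mapped
    reads) by sample.  Optional ``groups`` labels samples (e.g. control /
    treated) for downstream ratio reports.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("negative read counts")
        if not set(c.index) <= set(self.lengths.index):
            missing = sorted(set(c.index) - set(self.lengths.index))
            raise ValueError(f"genes without a length: {missing}")
        if not set(c.columns) <= set(self.library_sizes.index):
            missing = sorted(set(c.columns) - set(self.library_sizes.index))
            raise ValueError(f"samples without a library size: {missing}")
        self.lengths = self.lengths.reindex(c.index)
        self.library_sizes = self.library_sizes.reindex(c.columns)
        if (self.lengths < 1).any():
            raise ValueError("gene lengths must be >= 1 bp")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        short = self.library_sizes < c.sum(axis=0)
        if short.any():
            raise ValueError(
                f"library size smaller than column sum for samples: "
                f"{sorted(self.library_sizes.index[short])}"
            )


@dataclass
class ExpressionTable:
    """Genes x samples normalized expression values (RPKM or RPM)."""

    values: pd.DataFrame
    metric: str  # "rpkm" or "rpm"
    plus_one: bool = False

    def to_tsv(self, path_or_buf=None):
        return self.values.to_csv(path_or_buf, sep="\t", index_label="gene_id")


def compute_rpkm(counts: CountMatrix, plus_one: bool = False) -> ExpressionTable:
    """RPKM = C x 10^9 / (N x L) per gene per sample.

    ``plus_one`` adds 1 to every value for log-scale heatmap export; leave it
    off for any statistic.
    """
    c = counts.counts.astype(float)
    n = counts.library_sizes.astype(float)
    length = counts.lengths.astype(float)
    vals = c.mul(1e9).div(n, axis=1).div(length, axis=0)
    if plus_one:
        vals = vals + 1.0
    return ExpressionTable(vals, "rpkm", plus_one)


def compute_rpm(counts: CountMatrix, plus_one: bool = False) -> ExpressionTable:
    """RPM = C x 10^6 / N per gene per sample (gene length unused)."""
    c = counts.counts.astype(float)
    n = counts.library_sizes.astype(float)
    vals = c.mul(1e6).div(n, axis=1)
    if plus_one:
        vals = vals + 1.0
    return ExpressionTable(vals, "rpm", plus_one)


def replicate_stats(table: ExpressionTable) -> pd.DataFrame:
    """Per-gene replicate summary: mean, CV%, descending rank, expressed flag.

    CV% is 100 x sample standard deviation (n-1) over the mean, reported as
    missing (NaN) when the mean is 0 or with a single replicate.  Ranking is
    1 = highest mean; ties are broken by table order so every gene gets
    exactly one rank.
    """
    if table.plus_one:
        raise ValueError("replicate statistics must use raw values, not the +1 export")
    v = table.values
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean.where(mean > 0)
    rank = mean.rank(ascending=False, method="first").astype(int)
    return pd.DataFrame(
        {
            "mean": mean,
            "cv_pct": cv,
            "rank": rank,
            "expressed": mean > 0,
        }
    )


def group_ratio(
    table: ExpressionTable, groups: pd.Series, numerator: str, denominator: str
) -> pd.DataFrame:
    """Per-gene mean ratio between two sample groups (e.g. control / treated).

    A report annotation, not a statistical test; genes whose ratio exceeds a
    caller-chosen fold can be flagged as strongly repressed/induced downstream.
    """
    num_cols = groups.index[groups == numerator]
    den_cols = groups.index[groups == denominator]
    if len(num_cols) == 0 or len(den_cols) == 0:
        raise ValueError(f"groups {numerator!r}/{denominator!r} not found")
    num = table.values[num_cols].mean(axis=1)
    den = table.values[den_cols].mean(axis=1)
    return pd.DataFrame({f"mean_{numerator}": num, f"mean_{denominator}": den,
                         "ratio": num / den.where(den > 0)})


def read_counts_tsv(path_or_buf) -> tuple[pd.DataFrame, pd.Series]:
    """Counts TSV: gene_id, length_bp, then one column per sample."""
    if isinstance(path_or_buf, str) and "\t" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf, sep="\t").set_index("gene_id")
    lengths = df.pop("length_bp")
    return df, lengths


def read_samples_tsv(path_or_buf) -> tuple[pd.Series, pd.Series]:
    """Samples TSV: sample_id, total_mapped_reads, group."""
    if isinstance(path_or_buf, str) and "\t" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf, sep="\t").set_index("sample_id")
    groups = df["group"] if "group" in df.columns else pd.Series("all", index=df.index)
    return df["total_mapped_reads"], groups
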