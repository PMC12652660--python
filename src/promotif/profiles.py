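"""Analytical products derived from hit tables.

Given a table of predicted binding sites over a panel of TSS-anchored
promoters, this module produces:

* per-gene upstream/downstream site counts at each stringency tier,
* master-regulator TF (MRTF) sets — TFs with at least one predicted site in
  *every* analyzed promoter, regardless of position,
* gene-specific TF sets — TFs whose predicted sites all fall in exactly one
  promoter (evaluated on the lenient tier),
* autoregulation reports — a TF's sites within the promoter of its own gene,
* proximal-window profiles (default -500..+200 around the TSS), and
* CArG-box consensus matching (CC(A/T)6GG, the MADS-domain binding motif).

TF identity is aggregated at ``tf_name`` level by default (a TF binds a gene
if any of its matrices has a hit there); ``matrix_id`` aggregation is
available for matrix-resolved tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .motif_io import TFGeneMap
from .scanner import HitTable, MotifHit

__all__ = [
    "WindowSpec",
    "PROXIMAL_WINDOW",
    "ProfileTable",
    "MRTFReport",
    "GeneSpecificReport",
    "AutoregReport",
    "classify_region",
    "count_by_region",
    "find_mrtfs",
    "find_gene_specific",
    "detect_autoregulation",
    "proximal_profile",
    "match_carg",
]

CARG_PATTERN = re.compile(r"(?=(CC[AT]{6}GG))")  # its own reverse complement

TIERS = ("lenient", "stringent")


@dataclass(frozen=True)
class WindowSpec:
    """A TSS-relative analysis window (no position 0)."""

    start: int = -5000
    end: int = 1000

    def __post_init__(self) -> None:
        if not (self.start < 0 < self.end):
            raise ValueError(f"window must satisfy start < 0 < end, got {self.start}..{self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end and pos != 0


PROXIMAL_WINDOW = WindowSpec(-500, 200)


def classify_region(hit: "MotifHit | int") -> str:
    """'upstream' or 'downstream' of the TSS, by the hit's 5'-most base.

    There is no position 0: starts <= -1 are upstream, >= +1 downstream.
    A site spanning the TSS is classified by its start.
    """
    start = hit if isinstance(hit, int) else hit.start
    if start == 0:
        raise ValueError("TSS-relative coordinates have no position 0")
    return "upstream" if start < 0 else "downstream"


def _frame(hits: HitTable) -> pd.DataFrame:
    return hits.to_frame() if isinstance(hits, HitTable) else hits


@dataclass
class ProfileTable:
    """Per-gene, per-tier upstream/downstream hit-event counts.

    Events are counted as (matrix, position, strand) occurrences; the lenient
    tier includes the stringent hits (stringency nesting), so stringent counts
    never exceed lenient counts.  A distinct-TF summary is carried alongside.
    """

    counts: pd.DataFrame  # columns: gene_id, tier, upstream, downstream
    distinct_tfs: pd.DataFrame  # columns: gene_id, tier, n_tfs

    def to_tsv(self, path_or_buf=None):
        return self.counts.to_csv(path_or_buf, sep="\t", index=False)


def count_by_region(
    hits: HitTable,
    window: WindowSpec | None = None,
    gene_ids: "set[str] | None" = None,
) -> ProfileTable:
    """Count hit events upstream/downstream of the TSS per gene and tier.

    When ``gene_ids`` is given it defines the promoter panel: hits for genes
    outside it raise, and genes without hits get zero rows.
    """
    window = window or WindowSpec()
    df = _frame(hits)
    if gene_ids is not None:
        unknown = set(df["gene_id"]) - set(gene_ids)
        if unknown:
            raise KeyError(f"hits reference genes outside the promoter set: {sorted(unknown)}")
    genes = sorted(gene_ids) if gene_ids is not None else sorted(df["gene_id"].unique())

    rows, tf_rows = [], []
    for gene in genes:
        sub = df.loc[df["gene_id"] == gene]
        in_win = sub.loc[sub["start"].map(window.contains).astype(bool)]
        for tier in TIERS:
            tier_hits = in_win if tier == "lenient" else in_win[in_win["tier"] == "stringent"]
            up = int((tier_hits["start"] < 0).sum())
            down = int((tier_hits["start"] > 0).sum())
            rows.append({"gene_id": gene, "tier": tier, "upstream": up, "downstream": down})
            tf_rows.append({"gene_id": gene, "tier": tier, "n_tfs": tier_hits["tf_name"].nunique()})
    return ProfileTable(pd.DataFrame(rows), pd.DataFrame(tf_rows))


def _binders(df: pd.DataFrame, aggregation: str) -> pd.DataFrame:
    if aggregation not in ("tf_name", "matrix_id"):
        raise ValueError(f"aggregation must be 'tf_name' or 'matrix_id', got {aggregation!r}")
    return df[[aggregation, "gene_id", "tier"]].rename(columns={aggregation: "tf"})


@dataclass
class MRTFReport:
    """Master-regulator TFs: bound every promoter of the panel at a tier."""

    mrtf_lenient: set[str]
    mrtf_stringent: set[str]
    core: set[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.core is None:
            self.core = self.mrtf_lenient & self.mrtf_stringent

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tf": tf, "lenient": tf in self.mrtf_lenient,
             "stringent": tf in self.mrtf_stringent, "core": tf in self.core}
            for tf in sorted(self.mrtf_lenient | self.mrtf_stringent)
        ]
        return pd.DataFrame(rows, columns=["tf", "lenient", "stringent", "core"])


def find_mrtfs(hits: HitTable, gene_ids: set[str], aggregation: str = "tf_name") -> MRTFReport:
    """TFs predicted to bind all genes of the panel, regardless of position.

    A TF is a lenient MRTF if it has at least one hit (any tier) in every
    gene; a stringent MRTF if it has a stringent-tier hit in every gene.  The
    core is their intersection — equal to the stringent set when both tiers
    come from one scan, but kept general so independently produced tables can
    be intersected.
    """
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    b = _binders(_frame(hits), aggregation)
    target = set(gene_ids)

    def _covering(sub: pd.DataFrame) -> set[str]:
        cov = sub.groupby("tf")["gene_id"].agg(lambda g: set(g) >= target)
        return set(cov[cov].index)

    lenient = _covering(b)
    stringent = _covering(b[b["tier"] == "stringent"])
    return MRTFReport(lenient, stringent)


@dataclass
class GeneSpecificReport:
    """TFs whose lenient-tier hits all fall within a single promoter."""

    by_gene: dict[str, set[str]]

    @property
    def all_tfs(self) -> set[str]:
        return set().union(*self.by_gene.values()) if self.by_gene else set()

    def to_frame(self, hits: HitTable | None = None) -> pd.DataFrame:
        rows = []
        df = _frame(hits) if hits is not None else None
        for gene in sorted(self.by_gene):
            for tf in sorted(self.by_gene[gene]):
                row = {"gene_id": gene, "tf": tf}
                if df is not None:
                    sub = df[(df["gene_id"] == gene) & (df["tf_name"] == tf)]
                    row["n_hits"] = len(sub)
                    row["positions"] = ",".join(str(s) for s in sorted(sub["start"]))
                rows.append(row)
        return pd.DataFrame(rows)


def find_gene_specific(
    hits: HitTable, gene_ids: set[str], aggregation: str = "tf_name"
) -> GeneSpecificReport:
    """TFs binding exclusively one gene of the panel (lenient tier only).

    A TF is listed under gene g iff it has at least one hit and every one of
    its hits (at any tier — the lenient tier contains them all) lies in g.
    """
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    b = _binders(_frame(hits), aggregation)
    b = b[b["gene_id"].isin(gene_ids)]
    by_gene: dict[str, set[str]] = {g: set() for g in gene_ids}
    for tf, genes in b.groupby("tf")["gene_id"]:
        unique = set(genes)
        if len(unique) == 1:
            by_gene[next(iter(unique))].add(tf)
    return GeneSpecificReport({g: s for g, s in by_gene.items() if s})


@dataclass
class AutoregReport:
    """Per TF: predicted sites within the promoter of the TF's own gene."""

    sites: dict[str, list[MotifHit]]  # tf -> own-promoter hits, position-sorted
    tf_gene_map: TFGeneMap

    def has_high_stringency_site(self, tf: str) -> bool:
        return any(h.tier == "stringent" for h in self.sites.get(tf, []))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tf": tf, "gene_id": h.gene_id, "position": h.start, "strand": h.strand,
             "pvalue": h.pvalue, "tier": h.tier}
            for tf in sorted(self.sites)
            for h in self.sites[tf]
        ]
        return pd.DataFrame(rows, columns=["tf", "gene_id", "position", "strand", "pvalue", "tier"])


def detect_autoregulation(
    hits: HitTable,
    tf_gene_map: TFGeneMap,
    gene_ids: "set[str] | None" = None,
    aggregation: str = "tf_name",
) -> AutoregReport:
    """Find each mapped TF's binding sites in its own promoter.

    ``tf_gene_map`` says which promoter is the TF's own gene.  If ``gene_ids``
    (the promoter panel) is supplied, a TF mapped to a gene outside the panel
    raises, naming the TF.
    """
    if gene_ids is not None:
        for tf, gene in tf_gene_map.items():
            if gene not in gene_ids:
                raise KeyError(f"TF {tf!r} maps to gene {gene!r} absent from the promoter set")
    key = "tf_name" if aggregation == "tf_name" else "matrix_id"
    sites: dict[str, list[MotifHit]] = {tf: [] for tf in tf_gene_map}
    for h in hits:
        tf = getattr(h, key)
        if tf in tf_gene_map and h.gene_id == tf_gene_map[tf]:
            sites[tf].append(h)
    for tf in sites:
        sites[tf].sort(key=lambda h: (h.start, h.strand))
    return AutoregReport(sites, tf_gene_map)


def proximal_profile(
    hits: HitTable,
    tf_subset: "set[str] | None" = None,
    window: WindowSpec = PROXIMAL_WINDOW,
    aggregation: str = "tf_name",
) -> pd.DataFrame:
    """Positions of a TF subset's hits inside a central promoter window.

    Returns a frame (gene_id, tf, start, strand, tier) restricted to the
    window; ``tf_subset=None`` keeps every TF.
    """
    df = _frame(hits)
    key = "tf_name" if aggregation == "tf_name" else "matrix_id"
    if tf_subset is not None:
        df = df[df[key].isin(tf_subset)]
    df = df.loc[df["start"].map(window.contains).astype(bool)]
    out = df[["gene_id", key, "start", "strand", "tier"]].rename(columns={key: "tf"})
    return out.sort_values(["gene_id", "tf", "start"]).reset_index(drop=True)


def match_carg(sequence: str, origin: int = 0) -> list[tuple[int, str]]:
    """All CArG-box consensus matches CC(A/T)6GG on the forward strand.

    The pattern equals its own reverse complement, so a forward search covers
    both strands.  Matches may overlap.  Positions are reported in the
    caller's frame: ``origin`` is the coordinate of the sequence's first base.
    """
    seq = sequence.upper()
    return [(m.start() + origin, m.group(1)) for m in CARG_PATTERN.finditer(seq)]
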