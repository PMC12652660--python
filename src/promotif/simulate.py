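"""Seeded synthetic inputs with known ground truth.

Every generator is a pure function of its seed and parameters, so re-running
with the same arguments reproduces identical bytes.  The module emulates the
study's real inputs — a curated motif library, TSS-anchored promoter windows,
and replicated RNA-seq count tables — at controlled difficulty:

* matrix libraries of chosen sharpness (the target per-column consensus
  probability),
* promoter windows of fixed TSS-relative extent with i.i.d. background bases
  and motif consensus words planted at known positions and strands,
* fabricated hit tables with designed master-regulator / gene-specific
  structure for fast unit testing of the profiling layer, and
* negative-binomial (or Poisson) replicate count matrices with specified
  library sizes and per-gene expression rates.

The background is order-0 i.i.d.; promoter A/T-richness can be mimicked via
the composition, but no Markov structure is modeled.  Planted words overwrite
the background (window length is preserved); colliding plants are rejected
rather than shifted so the ground truth stays exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .expression import CountMatrix
import pandas as pd

from .motif_io import (
    BASES,
    PositionFrequencyMatrix,
    PromoterRecord,
    TFGeneMap,
)
from .scanner import HitTable, MotifHit, reverse_complement

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "FixtureExpectation",
    "simulate_pwms",
    "simulate_promoters",
    "make_profile_fixture",
    "simulate_counts",
]


@dataclass(frozen=True)
class PlantSpec:
    """One planted motif occurrence: where a matrix's word goes."""

    gene_id: str
    matrix_id: str
    position: int  # TSS-relative start (5'-most base, forward-strand space)
    strand: str = "+"


@dataclass
class GroundTruth:
    """What the generator actually planted, plus the intended analysis answers."""

    occurrences: list[dict] = field(default_factory=list)
    mrtf_intent: set[str] = field(default_factory=set)
    gene_specific_intent: dict[str, set[str]] = field(default_factory=dict)
    expression_rates: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "occurrences": self.occurrences,
            "mrtf_intent": sorted(self.mrtf_intent),
            "gene_specific_intent": {g: sorted(s) for g, s in sorted(self.gene_specific_intent.items())},
            "expression_rates": self.expression_rates,
        }
        return json.dumps(payload, indent=2)


def simulate_pwms(
    n_matrices: int,
    length: "int | tuple[int, int]" = 10,
    sharpness: float = 0.97,
    seed: int = 0,
    depth: int = 1000,
    id_prefix: str = "SIM",
) -> list[PositionFrequencyMatrix]:
    """Generate count matrices whose per-column consensus probability is
    approximately ``sharpness`` (exactly, when sharpness x depth is integral).

    ``sharpness`` must exceed 0.25 (below that no base can dominate a column)
    and 1.0 puts the whole column mass on a single base.  Consensus bases and
    lengths are drawn from the seeded generator; tf_names are TF000, TF001...
    """
    if not 0.25 < sharpness <= 1.0:
        raise ValueError(f"sharpness must be in (0.25, 1], got {sharpness}")
    lo, hi = (length, length) if isinstance(length, int) else length
    rng = np.random.default_rng(seed)
    cons_count = int(round(sharpness * depth))
    rest = depth - cons_count
    others = [rest // 3 + (1 if r < rest % 3 else 0) for r in range(3)]
    pfms = []
    for k in range(n_matrices):
        L = int(rng.integers(lo, hi + 1))
        counts = np.zeros((4, L), dtype=float)
        cons = rng.integers(0, 4, size=L)
        for j in range(L):
            rest_rows = [b for b in range(4) if b != cons[j]]
            counts[cons[j], j] = cons_count
            for b, c in zip(rest_rows, others):
                counts[b, j] = c
        pfms.append(
            PositionFrequencyMatrix(f"{id_prefix}{k:04d}.1", f"TF{k:03d}", counts)
        )
    return pfms


def simulate_promoters(
    gene_ids: "list[str] | int",
    pwms: list[PositionFrequencyMatrix],
    plants: list[PlantSpec] = (),
    window: tuple[int, int] = (-5000, 1000),
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> tuple[list[PromoterRecord], GroundTruth]:
    """Generate promoter windows with i.i.d. background and planted consensus words.

    Each plant overwrites the background with the matrix's consensus (its
    reverse complement for strand '-') so that a scan reports the occurrence
    at exactly the planted TSS-relative start and strand.  Overlapping plants
    within a gene raise an error naming the pair.
    """
    if isinstance(gene_ids, int):
        gene_ids = [f"GENE{i + 1:02d}" for i in range(gene_ids)]
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or np.any(comp < 0):
        raise ValueError("composition must be four non-negative probabilities summing to 1")
    start, end = window
    length = end - start
    by_id = {p.matrix_id: p for p in pwms}
    rng = np.random.default_rng(seed)

    # draw all backgrounds first so plant layout does not perturb other genes
    seqs = {
        g: rng.choice(list(BASES), size=length, p=comp) for g in gene_ids
    }
    intervals: dict[str, list[tuple[int, int, PlantSpec]]] = {g: [] for g in gene_ids}
    truth = GroundTruth()
    template = PromoterRecord(gene_ids[0], gene_ids[0], "A" * length, start, end)
    for plant in plants:
        if plant.gene_id not in seqs:
            raise KeyError(f"plant references unknown gene {plant.gene_id!r}")
        pfm = by_id.get(plant.matrix_id)
        if pfm is None:
            raise KeyError(f"plant references unknown matrix {plant.matrix_id!r}")
        i = template.tss_to_index(plant.position)
        if i + pfm.length > length:
            raise ValueError(
                f"plant {plant} does not fit: motif of length {pfm.length} "
                f"exceeds window end"
            )
        for a, b, other in intervals[plant.gene_id]:
            if i <= b and a <= i + pfm.length - 1:
                raise ValueError(f"overlapping plants in {plant.gene_id}: {other} and {plant}")
        intervals[plant.gene_id].append((i, i + pfm.length - 1, plant))
        word = pfm.consensus if plant.strand == "+" else reverse_complement(pfm.consensus)
        seqs[plant.gene_id][i : i + pfm.length] = list(word)
        truth.occurrences.append(
            {
                "gene_id": plant.gene_id,
                "matrix_id": plant.matrix_id,
                "tf_name": pfm.tf_name,
                "position": plant.position,
                "strand": plant.strand,
                "word": word,
            }
        )

    # intended analysis answers, derived from the plan
    planted_genes: dict[str, set[str]] = {}
    for occ in truth.occurrences:
        planted_genes.setdefault(occ["tf_name"], set()).add(occ["gene_id"])
    all_genes = set(gene_ids)
    truth.mrtf_intent = {tf for tf, gs in planted_genes.items() if gs >= all_genes}
    for tf, gs in planted_genes.items():
        if len(gs) == 1 and tf not in truth.mrtf_intent:
            truth.gene_specific_intent.setdefault(next(iter(gs)), set()).add(tf)

    promoters = [
        PromoterRecord(g, g, "".join(seqs[g]), start, end) for g in gene_ids
    ]
    return promoters, truth


@dataclass
class FixtureExpectation:
    """The answers a fabricated hit table was built to produce."""

    mrtfs: set[str]
    gene_specific: dict[str, set[str]]
    region_counts: pd.DataFrame  # gene_id, tier, upstream, downstream


def make_profile_fixture(
    gene_ids: "list[str] | int" = 18,
    mrtfs: "list[str] | int" = 3,
    exclusives: "dict[str, list[str]] | int" = 2,
    stringent_mrtf_fraction: float = 1.0,
    window: tuple[int, int] = (-5000, 1000),
    seed: int = 0,
) -> tuple[HitTable, FixtureExpectation]:
    """Fabricate a hit table with designed MRTF / gene-specific structure.

    Bypasses scanning entirely: each designated MRTF gets one hit in every
    gene (a ``stringent_mrtf_fraction`` of genes at the stringent tier), and
    each exclusive TF gets hits in its single assigned gene only.  Integer
    ``exclusives`` are spread round-robin over the genes.  The fixture obeys
    the same invariants the scanner guarantees (tier nesting — a stringent
    hit is a lenient hit with a smaller p-value — and window bounds).
    """
    if isinstance(gene_ids, int):
        gene_ids = [f"GENE{i + 1:02d}" for i in range(gene_ids)]
    if len(gene_ids) < 2:
        raise ValueError(
            "a single-gene panel makes every binder both panel-wide and "
            "gene-specific; use at least 2 genes"
        )
    if isinstance(mrtfs, int):
        mrtfs = [f"MRTF{i:02d}" for i in range(mrtfs)]
    if isinstance(exclusives, int):
        excl: dict[str, list[str]] = {}
        for i in range(exclusives):
            g = gene_ids[i % len(gene_ids)]
            excl.setdefault(g, []).append(f"EXCL{i:02d}")
        exclusives = excl
    overlap = set(mrtfs) & {tf for tfs in exclusives.values() for tf in tfs}
    if overlap:
        raise ValueError(f"TFs designated both MRTF and exclusive: {sorted(overlap)}")
    unknown = set(exclusives) - set(gene_ids)
    if unknown:
        raise KeyError(f"exclusives reference unknown genes: {sorted(unknown)}")
    if not 0.0 <= stringent_mrtf_fraction <= 1.0:
        raise ValueError("stringent_mrtf_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    start, end = window
    positions = [p for p in range(start, end + 1) if p != 0]

    hits: list[MotifHit] = []
    counts: dict[tuple[str, str, str], int] = {}

    def add(tf: str, gene: str, tier: str) -> None:
        pos = int(rng.choice(positions))
        pv = 1e-6 if tier == "stringent" else 3e-5
        hits.append(
            MotifHit(f"MX_{tf}", tf, gene, pos, min(pos + 9, end), "+", 12.0, pv, tier)
        )
        region = "upstream" if pos < 0 else "downstream"
        counts[(gene, "lenient", region)] = counts.get((gene, "lenient", region), 0) + 1
        if tier == "stringent":
            counts[(gene, "stringent", region)] = counts.get((gene, "stringent", region), 0) + 1

    for tf in mrtfs:
        n_str = int(round(stringent_mrtf_fraction * len(gene_ids)))
        stringent_genes = set(gene_ids[:n_str])
        for gene in gene_ids:
            add(tf, gene, "stringent" if gene in stringent_genes else "lenient")
    for gene, tfs in exclusives.items():
        for tf in tfs:
            add(tf, gene, "lenient")

    rows = [
        {"gene_id": g, "tier": t,
         "upstream": counts.get((g, t, "upstream"), 0),
         "downstream": counts.get((g, t, "downstream"), 0)}
        for g in gene_ids
        for t in ("lenient", "stringent")
    ]
    expectation = FixtureExpectation(
        mrtfs=set(mrtfs),
        gene_specific={g: set(tfs) for g, tfs in exclusives.items() if tfs},
        region_counts=pd.DataFrame(rows),
    )
    table = HitTable(hits, {"window": window, "fabricated": True,
                            "lenient_p": 1e-4, "stringent_p": 1e-5})
    return table, expectation


def simulate_counts(
    rates: dict[str, float],
    lengths: dict[str, int],
    library_sizes: "list[int] | dict[str, int]",
    dispersion: float = 0.0,
    seed: int = 0,
    groups: "list[str] | None" = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Replicate count matrices from per-gene expression rates.

    ``rates`` are expected RPKM values; the expected count of gene g in
    sample s is rate_g x N_s x L_g / 1e9.  ``dispersion`` is the
    negative-binomial overdispersion (variance = mu + dispersion x mu^2);
    0 gives Poisson draws.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if set(rates) != set(lengths):
        raise ValueError("rates and lengths must cover the same genes")
    if isinstance(library_sizes, dict):
        sample_ids = list(library_sizes)
        sizes = np.array([library_sizes[s] for s in sample_ids], dtype=float)
    else:
        sample_ids = [f"rep{i + 1}" for i in range(len(library_sizes))]
        sizes = np.asarray(library_sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("library sizes must be positive")

    rng = np.random.default_rng(seed)
    genes = list(rates)
    mu = np.array(
        [[rates[g] * n * lengths[g] / 1e9 for n in sizes] for g in genes]
    )
    if dispersion == 0:
        draws = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        p = r / (r + mu)
        draws = np.where(mu > 0, rng.negative_binomial(np.maximum(r, 1e-12), p), 0)
    counts = pd.DataFrame(draws, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    colsum = counts.sum(axis=0).to_numpy()
    if np.any(colsum > sizes):
        raise ValueError(
            "simulated counts exceed the library size; lower the rates or "
            "raise the library sizes"
        )
    cm = CountMatrix(
        counts,
        pd.Series(lengths, name="length_bp").reindex(genes),
        pd.Series(sizes, index=sample_ids, name="total_mapped_reads"),
        groups=pd.Series(groups, index=sample_ids) if groups is not None else None,
    )
    truth = GroundTruth(expression_rates=dict(rates))
    return cm, truth
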