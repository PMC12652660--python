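"""Matrix and promoter input: JASPAR-format PFMs, TSS-anchored promoter FASTA,
and construction of log-odds position weight matrices.

The scoring model is the classical log-likelihood-ratio PWM: for a motif of
length L with base counts ``n[b][j]`` and a background distribution ``q[b]``,
the weight of base ``b`` at column ``j`` is

    w[b][j] = log2( (n[b][j] + q[b] * s) / (N[j] + s) / q[b] )

where ``N[j]`` is the column sum and ``s`` a total pseudocount distributed
across bases in proportion to the background.  A word's score is the sum of
its per-position weights (bits); positive scores mean the word is more likely
under the motif than under the background.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as _bio_motifs
from Bio import SeqIO

__all__ = [
    "BASES",
    "BASE_INDEX",
    "BackgroundModel",
    "PositionFrequencyMatrix",
    "PositionWeightMatrix",
    "PromoterRecord",
    "TFGeneMap",
    "MotifParseError",
    "PromoterError",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_promoters_fasta",
    "pfm_to_pwm",
    "read_tf_gene_map",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT order


class MotifParseError(ValueError):
    """Raised when a matrix record cannot be parsed or fails validation."""


class PromoterError(ValueError):
    """Raised when a promoter record is inconsistent with its declared window."""


@dataclass(frozen=True)
class BackgroundModel:
    """Independent per-base nucleotide frequencies (order A, C, G, T)."""

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError("background needs exactly four frequencies (A,C,G,T)")
        if np.any(f <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {f.sum()!r}, not 1")
        object.__setattr__(self, "freqs", tuple(float(x) for x in f))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_sequences(cls, sequences: "list[str] | list[PromoterRecord]") -> "BackgroundModel":
        """Estimate frequencies from promoter sequences (N bases ignored)."""
        counts = np.zeros(4, dtype=float)
        for seq in sequences:
            text = seq.sequence if isinstance(seq, PromoterRecord) else seq
            for b, i in BASE_INDEX.items():
                counts[i] += text.upper().count(b)
        if counts.sum() == 0:
            raise ValueError("no A/C/G/T bases found to estimate background from")
        return cls(tuple(counts / counts.sum()))


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Observed base counts per motif column, rows in fixed A,C,G,T order."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise MotifParseError(f"{self.matrix_id}: counts must be 4 x L with L >= 1")
        if np.any(c < 0):
            raise MotifParseError(f"{self.matrix_id}: negative counts")
        if np.any(c.sum(axis=0) <= 0):
            raise MotifParseError(f"{self.matrix_id}: column with no positive count")
        object.__setattr__(self, "counts", c)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Highest-count base per column (ties broken in A,C,G,T order)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log2 likelihood-ratio weights per base per column, plus provenance."""

    matrix_id: str
    tf_name: str
    weights: np.ndarray  # shape (4, L), bits
    background: BackgroundModel
    pseudocount_total: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4:
            raise ValueError(f"{self.matrix_id}: weights must be 4 x L")
        if not np.all(np.isfinite(w)):
            raise ValueError(f"{self.matrix_id}: non-finite weights")
        object.__setattr__(self, "weights", w)

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=0))

    def reverse_complement(self) -> "PositionWeightMatrix":
        """The PWM that scores a forward-strand word as this PWM scores its
        reverse complement."""
        w = self.weights[COMPLEMENT_INDEX, :][:, ::-1]
        return PositionWeightMatrix(
            self.matrix_id, self.tf_name, w, self.background, self.pseudocount_total
        )


@dataclass(frozen=True)
class PromoterRecord:
    """One gene's promoter sequence in a TSS-anchored window.

    Coordinates are EPD-style: there is no position 0, +1 is the first
    transcribed base, so a window from ``window_start`` (< 0) to
    ``window_end`` (> 0) spans ``window_end - window_start`` bases.
    """

    gene_id: str
    gene_symbol: str
    sequence: str
    window_start: int = -5000
    window_end: int = 1000

    def __post_init__(self) -> None:
        if not (self.window_start < 0 < self.window_end):
            raise PromoterError(
                f"{self.gene_id}: window must satisfy start < 0 < end, "
                f"got {self.window_start}..{self.window_end}"
            )
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise PromoterError(f"{self.gene_id}: invalid characters {sorted(bad)}")
        expected = self.window_end - self.window_start
        if len(seq) != expected:
            raise PromoterError(
                f"{self.gene_id}: sequence length {len(seq)} does not match "
                f"window {self.window_start}..{self.window_end} (expected {expected})"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def index_to_tss(self, i: int) -> int:
        """Map a 0-based sequence index to its TSS-relative coordinate."""
        if not 0 <= i < len(self.sequence):
            raise IndexError(f"index {i} outside promoter of length {len(self.sequence)}")
        rel = i + self.window_start
        return rel if rel < 0 else rel + 1

    def tss_to_index(self, pos: int) -> int:
        """Map a TSS-relative coordinate (no 0) to a 0-based sequence index."""
        if pos == 0:
            raise ValueError("TSS-relative coordinates have no position 0")
        i = pos - self.window_start - (1 if pos > 0 else 0)
        if not 0 <= i < len(self.sequence):
            raise IndexError(f"position {pos} outside window {self.window_start}..{self.window_end}")
        return i


class TFGeneMap(dict):
    """Mapping from TF name (or matrix id) to the gene id of the TF's own gene.

    Used to ask whether a TF has predicted sites in its own promoter
    (autoregulation) and to derive binding edges for the network view.
    """

    def validate_against(self, gene_ids: set[str]) -> None:
        missing = {tf: g for tf, g in self.items() if g not in gene_ids}
        if missing:
            tf = sorted(missing)[0]
            raise KeyError(
                f"TF {tf!r} maps to gene {missing[tf]!r} which is not in the promoter set"
            )


def _as_text_stream(stream) -> io.StringIO:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def read_jaspar_pfm(stream) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR plain-text PFM records (2016+ bracketed-row dialect).

    Rows may appear in any base order; they are remapped to A,C,G,T by label.
    A malformed record raises :class:`MotifParseError` naming its matrix id.
    """
    text = _as_text_stream(stream).read()
    records: list[tuple[str, str]] = []  # (header_id, record_text)
    current: list[str] = []
    header = None
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                records.append((header, "\n".join(current)))
            header = line[1:].split()[0] if line[1:].split() else ""
            current = [line]
        elif header is not None:
            current.append(line)
    if header is not None:
        records.append((header, "\n".join(current)))

    pfms: list[PositionFrequencyMatrix] = []
    for matrix_id, rec_text in records:
        try:
            parsed = _bio_motifs.parse(io.StringIO(rec_text + "\n"), "jaspar")
        except Exception as exc:
            raise MotifParseError(f"{matrix_id}: {exc}") from exc
        if len(parsed) != 1:
            raise MotifParseError(f"{matrix_id}: expected one record, got {len(parsed)}")
        m = parsed[0]
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        pfms.append(PositionFrequencyMatrix(m.matrix_id or matrix_id, m.name or "", counts))
    return pfms


def write_jaspar_pfm(pfms: list[PositionFrequencyMatrix]) -> str:
    """Serialize PFMs in the JASPAR bracketed-row dialect (A,C,G,T row order)."""
    out = []
    for p in pfms:
        out.append(f">{p.matrix_id} {p.tf_name}".rstrip())
        for b in BASES:
            row = " ".join(_fmt_count(x) for x in p.counts[BASE_INDEX[b]])
            out.append(f"{b} [ {row} ]")
    return "\n".join(out) + "\n"


def _fmt_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    background: BackgroundModel | None = None,
    pseudocount_total: float = 1.0,
) -> PositionWeightMatrix:
    """Build a log2 likelihood-ratio PWM from a count matrix.

    The pseudocount ``pseudocount_total`` is shared across the four bases in
    proportion to their background frequencies, so a column whose counts are
    proportional to the background always yields zero weights.
    ``pseudocount_total = 0`` is allowed when every count is positive.
    """
    background = background or BackgroundModel.uniform()
    if pseudocount_total < 0:
        raise ValueError("pseudocount_total must be >= 0")
    q = background.array[:, None]  # (4,1)
    n = pfm.counts
    colsum = n.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore"):
        p_site = (n + q * pseudocount_total) / (colsum + pseudocount_total)
        weights = np.log2(p_site / q)
    if not np.all(np.isfinite(weights)):
        raise ValueError(
            f"{pfm.matrix_id}: zero-probability cells; use pseudocount_total > 0"
        )
    return PositionWeightMatrix(
        pfm.matrix_id, pfm.tf_name, weights, background, float(pseudocount_total)
    )


def read_promoters_fasta(stream, window_start: int = -5000, window_end: int = 1000) -> list[PromoterRecord]:
    """Read promoter sequences from FASTA with a shared TSS-relative window.

    Header grammar: ``>gene_id|symbol`` (strict) with a permissive fallback
    where the first whitespace token is the gene_id and the symbol repeats it.
    Every sequence is validated against the declared window length; duplicate
    gene ids are rejected.
    """
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_as_text_stream(stream), "fasta"):
        head = rec.id
        if "|" in head:
            gene_id, _, symbol = head.partition("|")
        else:
            gene_id, symbol = head, head
        if gene_id in seen:
            raise PromoterError(f"duplicate gene_id {gene_id!r} in promoter FASTA")
        seen.add(gene_id)
        records.append(
            PromoterRecord(gene_id, symbol, str(rec.seq), window_start, window_end)
        )
    return records


def write_promoters_fasta(promoters: list[PromoterRecord]) -> str:
    lines = []
    for p in promoters:
        lines.append(f">{p.gene_id}|{p.gene_symbol}")
        for i in range(0, len(p.sequence), 80):
            lines.append(p.sequence[i : i + 80])
    return "\n".join(lines) + "\n"


def read_tf_gene_map(stream) -> TFGeneMap:
    """Two-column TSV (tf_name_or_matrix_id <tab> gene_id), '#' comments allowed."""
    out = TFGeneMap()
    for ln, line in enumerate(_as_text_stream(stream), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"tf-gene map line {ln}: expected two tab-separated columns")
        out[parts[0]] = parts[1]
    return out
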