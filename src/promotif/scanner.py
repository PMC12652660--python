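"""Promoter scanning with exact motif p-values.

Scores are discretized onto an integer grid (``grid_scale`` units per bit;
each weight-matrix cell is rounded once, and a word's discretized score is the
sum of its rounded cells).  The null distribution of the discretized score of
a random background word of motif length is then computed exactly by
position-wise convolution, which makes p-values and score cutoffs exact at the
grid resolution rather than approximations: a scan at threshold p emits
precisely the words whose tail probability P(S >= s) is below p.

Two stringencies are carried through every scan: a lenient threshold
(default p < 1e-4) and a stringent one (default p < 1e-5).  Every reported hit
satisfies the lenient threshold; hits that also pass the stringent one are
tiered "stringent", so stringent hits are a subset of lenient hits by
construction.

Coordinates follow the EPD convention: TSS-relative with no position 0; a
hit's ``start`` is the 5'-most base of the matched window in forward-strand
space on either strand.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif_io import (
    BASE_INDEX,
    BASES,
    BackgroundModel,
    PositionWeightMatrix,
    PromoterRecord,
)

__all__ = [
    "DEFAULT_GRID_SCALE",
    "ScoreDistribution",
    "ScanThresholds",
    "MotifHit",
    "HitTable",
    "UnscorableWordError",
    "integer_weights",
    "score_word",
    "score_distribution",
    "pvalue_of_score",
    "score_cutoff",
    "scan_promoter",
    "scan_collection",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID_SCALE = 10_000
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

HIT_COLUMNS = [
    "matrix_id",
    "tf_name",
    "gene_id",
    "start",
    "end",
    "strand",
    "score_bits",
    "pvalue",
    "tier",
]


class UnscorableWordError(ValueError):
    """A word contains a base (N) the scoring model cannot score."""


def reverse_complement(word: str) -> str:
    return "".join(_RC[b] for b in reversed(word.upper()))


def integer_weights(pwm: PositionWeightMatrix, grid_scale: int = DEFAULT_GRID_SCALE) -> np.ndarray:
    """Round each weight cell to the integer grid (units of 1/grid_scale bits)."""
    if grid_scale < 1:
        raise ValueError("grid_scale must be >= 1")
    return np.rint(pwm.weights * grid_scale).astype(np.int64)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of the discretized score of a background word.

    ``scores`` are the attainable integer scores in increasing order, ``probs``
    their probabilities, and ``tail[i] = P(S >= scores[i])``.
    """

    grid_scale: int
    scores: np.ndarray  # int64, strictly increasing
    probs: np.ndarray  # float64, > 0

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.int64)
        p = np.asarray(self.probs, dtype=float)
        if s.shape != p.shape or s.ndim != 1:
            raise ValueError("scores and probs must be 1-D and aligned")
        if np.any(np.diff(s) <= 0):
            raise ValueError("scores must be strictly increasing")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "probs", p)

    @property
    def tail(self) -> np.ndarray:
        return np.cumsum(self.probs[::-1])[::-1]

    def pvalue_int(self, int_score) -> "float | np.ndarray":
        """P(S >= int_score) for integer grid scores (vectorized)."""
        idx = np.searchsorted(self.scores, int_score, side="left")
        tail_ext = np.append(self.tail, 0.0)
        return tail_ext[idx]

    def cutoff_int(self, p: float) -> int:
        """Smallest integer score s with P(S >= s) < p (strict)."""
        if not 0 < p <= 1:
            raise ValueError("p must be in (0, 1]")
        keep = self.tail >= p
        if not np.any(keep):  # every attainable score already below p
            return int(self.scores[0])
        return int(self.scores[keep][-1]) + 1


def score_word(pwm: PositionWeightMatrix, word: str, strand: str = "+") -> float:
    """Score one word of motif length, in bits; '-' scores its reverse complement."""
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    word = word.upper()
    if strand == "-":
        word = reverse_complement(word)
    if len(word) != pwm.length:
        raise ValueError(f"word length {len(word)} != motif length {pwm.length}")
    if "N" in word:
        raise UnscorableWordError(f"word {word!r} contains N")
    idx = [BASE_INDEX[b] for b in word]
    return float(pwm.weights[idx, range(pwm.length)].sum())


def score_distribution(
    pwm: PositionWeightMatrix,
    background: BackgroundModel | None = None,
    grid_scale: int = DEFAULT_GRID_SCALE,
) -> ScoreDistribution:
    """Exact distribution of the discretized score under the background model.

    Dense dynamic programme over the attainable integer score range: one
    convolution step per motif column, each mixing the four base weights with
    their background probabilities.
    """
    background = background or pwm.background
    iw = integer_weights(pwm, grid_scale)
    q = background.array
    # dense array over the attainable range; index i of `running` holds
    # P(partial score == i + running_lo)
    running = np.ones(1, dtype=float)
    running_lo = 0
    for j in range(pwm.length):
        w = iw[:, j]
        new_lo = running_lo + int(w.min())
        new_hi = running_lo + (len(running) - 1) + int(w.max())
        new = np.zeros(new_hi - new_lo + 1, dtype=float)
        for b in range(4):
            off = running_lo + int(w[b]) - new_lo
            new[off : off + len(running)] += q[b] * running
        running = new
        running_lo = new_lo
    nz = np.nonzero(running)[0]
    return ScoreDistribution(grid_scale, nz + running_lo, running[nz])


def pvalue_of_score(dist: ScoreDistribution, score_bits: float) -> float:
    """P(S >= score) for a score given in bits, rounded to the grid."""
    return float(dist.pvalue_int(int(round(score_bits * dist.grid_scale))))


def score_cutoff(dist: ScoreDistribution, p: float) -> int:
    """Smallest integer grid score whose tail probability is strictly below p."""
    return dist.cutoff_int(p)


@dataclass(frozen=True)
class ScanThresholds:
    """The two stringency levels of a scan (strict 'p <' semantics)."""

    lenient_p: float = 1e-4
    stringent_p: float = 1e-5

    def __post_init__(self) -> None:
        for p in (self.lenient_p, self.stringent_p):
            if not 0 < p <= 1:
                raise ValueError("thresholds must be in (0, 1]")
        if not self.stringent_p < self.lenient_p:
            raise ValueError(
                f"stringent_p ({self.stringent_p}) must be < lenient_p ({self.lenient_p})"
            )


@dataclass(frozen=True)
class MotifHit:
    """One predicted binding site: matrix x gene x TSS-relative start x strand."""

    matrix_id: str
    tf_name: str
    gene_id: str
    start: int  # TSS-relative, 5'-most base of the matched window
    end: int  # TSS-relative, 3'-most base in forward-strand space
    strand: str
    score_bits: float
    pvalue: float
    tier: str  # "lenient" or "stringent"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.tier not in ("lenient", "stringent"):
            raise ValueError(f"bad tier {self.tier!r}")


@dataclass
class HitTable:
    """A list of motif hits plus the provenance of the scan that produced them."""

    hits: list[MotifHit] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def to_frame(self) -> pd.DataFrame:
        if not self.hits:
            return pd.DataFrame(columns=HIT_COLUMNS)
        return pd.DataFrame([vars(h) for h in self.hits], columns=HIT_COLUMNS)

    def to_tsv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: dict | None = None) -> "HitTable":
        hits = [
            MotifHit(
                str(r.matrix_id), str(r.tf_name), str(r.gene_id), int(r.start),
                int(r.end), str(r.strand), float(r.score_bits), float(r.pvalue),
                str(r.tier),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(hits, provenance or {})

    @classmethod
    def from_tsv(cls, path_or_buf) -> "HitTable":
        return cls.from_frame(pd.read_csv(path_or_buf, sep="\t"))

    def to_bed(self, window_start: int) -> str:
        """BED6 with 0-based half-open coordinates inside the scanned window."""
        lines = []
        for h in self.hits:
            a = h.start - window_start - (1 if h.start > 0 else 0)
            score = 0
            if self.provenance.get("max_score_bits"):
                score = int(round(1000 * min(1.0, h.score_bits / self.provenance["max_score_bits"])))
            lines.append(
                f"{h.gene_id}\t{a}\t{a + (h.end - h.start + (0 if h.start * h.end > 0 else -1)) + 1}"
                f"\t{h.matrix_id}\t{score}\t{h.strand}"
            )
        return "\n".join(lines) + ("\n" if lines else "")

    def stringent_only(self) -> "HitTable":
        return HitTable([h for h in self.hits if h.tier == "stringent"], dict(self.provenance))

    def _check_no_duplicates(self) -> None:
        keys = [(h.matrix_id, h.gene_id, h.start, h.strand) for h in self.hits]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (matrix_id, gene_id, start, strand) hits")


def _encode(sequence: str) -> np.ndarray:
    """A,C,G,T -> 0..3; N -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, iw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer score of every length-L window, plus validity (no N) mask."""
    L = iw.shape[1]
    npos = len(codes) - L + 1
    if npos <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    padded = np.vstack([iw, np.zeros((1, L), dtype=np.int64)])  # row 4 = N placeholder
    scores = np.zeros(npos, dtype=np.int64)
    valid = np.ones(npos, dtype=bool)
    for j in range(L):
        col = codes[j : j + npos]
        valid &= col != 4
        scores += padded[col, j]
    return scores, valid


def scan_promoter(
    pwm: PositionWeightMatrix,
    promoter: PromoterRecord,
    thresholds: ScanThresholds | None = None,
    grid_scale: int = DEFAULT_GRID_SCALE,
    dist: ScoreDistribution | None = None,
) -> HitTable:
    """Scan one promoter with one PWM on both strands.

    Emits a hit for every position/strand whose word has exact p-value below
    the lenient threshold; windows containing N are skipped and tallied in the
    provenance as ``masked_windows``.
    """
    thresholds = thresholds or ScanThresholds()
    L = pwm.length
    if len(promoter) < L:
        logger.warning(
            "promoter %s (%d nt) shorter than motif %s (%d nt); empty scan",
            promoter.gene_id, len(promoter), pwm.matrix_id, L,
        )
        return HitTable([], _provenance(promoter, pwm, thresholds, grid_scale, 0))
    if dist is None:
        dist = score_distribution(pwm, grid_scale=grid_scale)
    cut_len = dist.cutoff_int(thresholds.lenient_p)
    cut_str = dist.cutoff_int(thresholds.stringent_p)
    codes = _encode(promoter.sequence)
    iw_fwd = integer_weights(pwm, grid_scale)
    iw_rev = integer_weights(pwm.reverse_complement(), grid_scale)

    hits: list[MotifHit] = []
    masked = 0
    for strand, iw in (("+", iw_fwd), ("-", iw_rev)):
        scores, valid = _window_scores(codes, iw)
        masked += int((~valid).sum())
        idx = np.nonzero(valid & (scores >= cut_len))[0]
        if len(idx) == 0:
            continue
        pvals = dist.pvalue_int(scores[idx])
        for i, pv in zip(idx.tolist(), np.atleast_1d(pvals).tolist()):
            s = int(scores[i])
            hits.append(
                MotifHit(
                    pwm.matrix_id,
                    pwm.tf_name,
                    promoter.gene_id,
                    promoter.index_to_tss(i),
                    promoter.index_to_tss(i + L - 1),
                    strand,
                    s / grid_scale,
                    float(pv),
                    "stringent" if s >= cut_str else "lenient",
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return HitTable(hits, _provenance(promoter, pwm, thresholds, grid_scale, masked))


def _provenance(promoter, pwm, thresholds, grid_scale, masked) -> dict:
    return {
        "window": (promoter.window_start, promoter.window_end),
        "background": pwm.background.freqs,
        "pseudocount_total": pwm.pseudocount_total,
        "lenient_p": thresholds.lenient_p,
        "stringent_p": thresholds.stringent_p,
        "grid_scale": grid_scale,
        "masked_windows": {promoter.gene_id: masked},
        "max_score_bits": pwm.max_score,
    }


def library_checksum(pwms: list[PositionWeightMatrix]) -> str:
    h = hashlib.sha256()
    for p in sorted(pwms, key=lambda x: x.matrix_id):
        h.update(p.matrix_id.encode())
        h.update(np.ascontiguousarray(p.weights).tobytes())
    return h.hexdigest()[:16]


def scan_collection(
    pwms: list[PositionWeightMatrix],
    promoters: list[PromoterRecord],
    thresholds: ScanThresholds | None = None,
    grid_scale: int = DEFAULT_GRID_SCALE,
) -> HitTable:
    """Scan every promoter with every matrix; stable result ordering.

    Score distributions are computed once per matrix and shared across
    promoters.  Duplicate matrix ids in the library are rejected.
    """
    thresholds = thresholds or ScanThresholds()
    ids = [p.matrix_id for p in pwms]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate matrix_ids in library: {dup}")
    all_hits: list[MotifHit] = []
    masked: dict[str, int] = {}
    for pwm in pwms:
        dist = score_distribution(pwm, grid_scale=grid_scale)
        for prom in promoters:
            sub = scan_promoter(pwm, prom, thresholds, grid_scale, dist=dist)
            all_hits.extend(sub.hits)
            for g, m in sub.provenance["masked_windows"].items():
                masked[g] = masked.get(g, 0) + m
    all_hits.sort(key=lambda h: (h.gene_id, h.matrix_id, h.start, h.strand))
    prov = {
        "window": (promoters[0].window_start, promoters[0].window_end) if promoters else None,
        "lenient_p": thresholds.lenient_p,
        "stringent_p": thresholds.stringent_p,
        "grid_scale": grid_scale,
        "n_matrices": len(pwms),
        "n_promoters": len(promoters),
        "masked_windows": masked,
        "library_checksum": library_checksum(pwms),
    }
    table = HitTable(all_hits, prov)
    table._check_no_duplicates()
    return table
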