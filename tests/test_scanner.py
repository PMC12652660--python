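"""Scoring, exact p-value calibration, and promoter scanning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import promotif as pm
from promotif.scanner import (
    integer_weights,
    reverse_complement,
    score_distribution,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


def brute_force_distribution(iw: np.ndarray, q: np.ndarray):
    """Independent oracle: enumerate all 4^L words at the same discretization."""
    L = iw.shape[1]
    digits = (np.arange(4**L)[:, None] // (4 ** np.arange(L - 1, -1, -1))[None, :]) % 4
    scores = iw[digits, np.arange(L)].sum(axis=1)
    probs = q[digits].prod(axis=1)
    uniq, inverse = np.unique(scores, return_inverse=True)
    return uniq, np.bincount(inverse, weights=probs)


def brute_force_cutoff(uniq, probs, p):
    tails = np.cumsum(probs[::-1])[::-1]
    above = uniq[tails >= p]
    return int(above[-1]) + 1 if len(above) else int(uniq[0])


def zero_pwm(L=1):
    return pm.PositionWeightMatrix(
        "Z", "Z", np.zeros((4, L)), pm.BackgroundModel.uniform(), 1.0
    )


class TestScoreWord:
    def test_zero_weight_identity(self):
        assert pm.score_word(zero_pwm(4), "ACGT") == 0.0

    def test_consensus_is_column_max_sum(self, sharp_pwm):
        got = pm.score_word(sharp_pwm, sharp_pwm.consensus)
        assert got == pytest.approx(sharp_pwm.max_score, abs=1e-12)

    @given(DNA.filter(lambda w: len(w) >= 1))
    def test_strand_symmetry(self, word):
        rng = np.random.default_rng(len(word))
        weights = rng.normal(size=(4, len(word)))
        pwm = pm.PositionWeightMatrix("S", "S", weights, pm.BackgroundModel.uniform(), 1.0)
        minus = pm.score_word(pwm, word, "-")
        plus_rc = pm.score_word(pwm, reverse_complement(word), "+")
        assert minus == pytest.approx(plus_rc, abs=1e-12)

    def test_n_is_unscorable(self):
        with pytest.raises(pm.UnscorableWordError):
            pm.score_word(zero_pwm(3), "ANT")


class TestScoreDistribution:
    def test_degenerate_single_mass(self):
        d = score_distribution(zero_pwm(1))
        assert d.scores.tolist() == [0] and d.probs.tolist() == [1.0]

    def test_matches_enumeration_l2(self, rng, uniform_bg):
        counts = rng.integers(1, 25, size=(4, 2)).astype(float)
        pwm = pm.pfm_to_pwm(pm.PositionFrequencyMatrix("L2", "L2", counts), uniform_bg)
        d = score_distribution(pwm)
        uniq, probs = brute_force_distribution(integer_weights(pwm), uniform_bg.array)
        np.testing.assert_array_equal(d.scores, uniq)
        np.testing.assert_array_equal(d.probs, probs)  # dyadic masses: exact

    def test_probability_conservation_random_pwms(self, uniform_bg):
        rng = np.random.default_rng(99)
        for _ in range(50):
            L = int(rng.integers(1, 13))
            counts = rng.integers(1, 40, size=(4, L)).astype(float)
            pwm = pm.pfm_to_pwm(pm.PositionFrequencyMatrix("C", "C", counts), uniform_bg)
            d = score_distribution(pwm)
            assert abs(d.probs.sum() - 1.0) <= 1e-9

    def test_nonuniform_background(self, rng):
        bg = pm.BackgroundModel((0.3, 0.2, 0.2, 0.3))
        counts = rng.integers(1, 25, size=(4, 3)).astype(float)
        pwm = pm.pfm_to_pwm(pm.PositionFrequencyMatrix("B", "B", counts), bg)
        d = score_distribution(pwm)
        uniq, probs = brute_force_distribution(integer_weights(pwm), bg.array)
        np.testing.assert_array_equal(d.scores, uniq)
        np.testing.assert_allclose(d.probs, probs, rtol=1e-12)


class TestPvaluesAndCutoffs:
    def test_p_equal_one_boundary(self):
        # For the all-zero PWM every word scores 0 with P(S >= 0) = 1, which is
        # not < 1; the cutoff is one grid unit above the minimum support score.
        d = score_distribution(zero_pwm(1))
        assert d.cutoff_int(1.0) == 1
        assert d.pvalue_int(0) == 1.0

    def test_sharp_consensus_tail(self, sharp_pwm):
        d = score_distribution(sharp_pwm)
        top = int(integer_weights(sharp_pwm).max(axis=0).sum())
        assert d.pvalue_int(top) == pytest.approx(4.0**-10, rel=0, abs=0)
        assert top >= d.cutoff_int(1e-4) and top >= d.cutoff_int(1e-5)

    def test_cutoff_against_enumeration_l4(self, uniform_bg):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 25, size=(4, 4)).astype(float)
        pwm = pm.pfm_to_pwm(pm.PositionFrequencyMatrix("L4", "L4", counts), uniform_bg)
        d = score_distribution(pwm)
        uniq, probs = brute_force_distribution(integer_weights(pwm), uniform_bg.array)
        assert d.cutoff_int(1e-1) == brute_force_cutoff(uniq, probs, 1e-1)

    def test_invalid_p_rejected(self):
        d = score_distribution(zero_pwm(1))
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                d.cutoff_int(p)

    def test_grid_refinement_bounded_by_cell_mass(self, uniform_bg):
        """Raising grid_scale moves any word's p-value by at most the mass
        that shares one coarse grid cell."""
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 25, size=(4, 5)).astype(float)
        pwm = pm.pfm_to_pwm(pm.PositionFrequencyMatrix("G", "G", counts), uniform_bg)
        coarse = score_distribution(pwm, grid_scale=50)
        fine = score_distribution(pwm, grid_scale=10000)
        iw_c, iw_f = integer_weights(pwm, 50), integer_weights(pwm, 10000)
        max_cell = coarse.probs.max()
        for _ in range(100):
            word = rng.integers(0, 4, size=5)
            sc = int(iw_c[word, range(5)].sum())
            sf = int(iw_f[word, range(5)].sum())
            assert abs(coarse.pvalue_int(sc) - fine.pvalue_int(sf)) <= max_cell + 1e-12


class TestScanPromoter:
    def test_planted_consensus_found_at_minus_1024(self, sharp_pwm):
        rng = np.random.default_rng(5)
        bg = "".join(rng.choice(list("ACGT"), size=6000))
        prom = pm.PromoterRecord("g1", "g1", bg, -5000, 1000)
        i = prom.tss_to_index(-1024)
        seq = bg[:i] + sharp_pwm.consensus + bg[i + 10:]
        prom = pm.PromoterRecord("g1", "g1", seq, -5000, 1000)
        hits = pm.scan_promoter(sharp_pwm, prom)
        at = [h for h in hits if h.start == -1024 and h.strand == "+"]
        assert len(at) == 1 and at[0].tier == "stringent"

    def test_scan_determinism(self, sharp_pwm):
        rng = np.random.default_rng(6)
        prom = pm.PromoterRecord("g", "g", "".join(rng.choice(list("ACGT"), 2000)), -1500, 500)
        a = pm.scan_promoter(sharp_pwm, prom).to_tsv()
        b = pm.scan_promoter(sharp_pwm, prom).to_tsv()
        assert a == b

    def test_short_window_empty_with_warning(self, sharp_pwm, caplog):
        prom = pm.PromoterRecord("tiny", "tiny", "ACGTAC", -3, 3)
        with caplog.at_level("WARNING"):
            hits = pm.scan_promoter(sharp_pwm, prom)
        assert len(hits) == 0 and "tiny" in caplog.text

    def test_n_windows_skipped_and_tallied(self, sharp_pwm):
        seq = sharp_pwm.consensus + "N" + sharp_pwm.consensus
        prom = pm.PromoterRecord("g", "g", seq, -10, 11)
        hits = pm.scan_promoter(sharp_pwm, prom)
        starts = {(h.start, h.strand) for h in hits}
        assert (-10, "+") in starts and (2, "+") in starts
        # windows covering the central N on either strand were skipped
        assert hits.provenance["masked_windows"]["g"] == 2 * 10

    def test_hit_coordinates_span_tss_correctly(self, sharp_pwm):
        # plant so the motif spans the TSS: start at -3 covers -3..-1,+1..+7
        rng = np.random.default_rng(8)
        bg = "".join(rng.choice(list("ACGT"), size=200))
        prom0 = pm.PromoterRecord("g", "g", bg, -100, 100)
        i = prom0.tss_to_index(-3)
        seq = bg[:i] + sharp_pwm.consensus + bg[i + 10:]
        hits = pm.scan_promoter(sharp_pwm, pm.PromoterRecord("g", "g", seq, -100, 100))
        h = next(x for x in hits if x.start == -3 and x.strand == "+")
        assert h.end == 7  # ten bases, no position 0


class TestScanCollection:
    @pytest.fixture
    def small_scan(self):
        pfms = pm.simulate_pwms(3, 8, 0.97, seed=21)
        pwms = [pm.pfm_to_pwm(p) for p in pfms]
        proms, _ = pm.simulate_promoters(3, pfms, [], window=(-800, 200), seed=22)
        return pwms, proms, pm.scan_collection(pwms, proms)

    def test_composition_equals_pairwise_scans(self, small_scan):
        pwms, proms, table = small_scan
        for pwm in pwms:
            for prom in proms:
                solo = pm.scan_promoter(pwm, prom)
                sub = [h for h in table
                       if h.matrix_id == pwm.matrix_id and h.gene_id == prom.gene_id]
                assert sorted((h.start, h.strand, h.pvalue) for h in sub) == \
                    sorted((h.start, h.strand, h.pvalue) for h in solo)

    def test_duplicate_matrix_ids_rejected(self, small_scan):
        pwms, proms, _ = small_scan
        with pytest.raises(ValueError, match="duplicate"):
            pm.scan_collection([pwms[0], pwms[0]], proms)

    def test_empty_library(self, small_scan):
        _, proms, _ = small_scan
        assert len(pm.scan_collection([], proms)) == 0

    def test_stringent_subset_equals_rescan(self, small_scan):
        pwms, proms, table = small_scan
        rescan = pm.scan_collection(pwms, proms, pm.ScanThresholds(1e-5, 1e-6))
        key = lambda h: (h.matrix_id, h.gene_id, h.start, h.strand)
        assert {key(h) for h in table.stringent_only()} == {key(h) for h in rescan}

    def test_threshold_nesting(self, small_scan):
        _, _, table = small_scan
        key = lambda h: (h.matrix_id, h.gene_id, h.start, h.strand)
        stringent = {key(h) for h in table if h.tier == "stringent"}
        lenient = {key(h) for h in table}
        assert stringent <= lenient
        for h in table:
            assert h.pvalue < 1e-4
            assert (h.tier == "stringent") == (h.pvalue < 1e-5)

    def test_scan_strand_symmetry(self):
        """Scanning the reverse-complemented promoter mirrors the hit set."""
        pfms = pm.simulate_pwms(2, 7, 0.9, seed=31)
        pwms = [pm.pfm_to_pwm(p) for p in pfms]
        proms, _ = pm.simulate_promoters(2, pfms, [], window=(-500, 500), seed=32)
        for pwm in pwms:
            for prom in proms:
                fwd = pm.scan_promoter(pwm, prom, pm.ScanThresholds(1e-2, 1e-3))
                rc = pm.PromoterRecord(
                    prom.gene_id, prom.gene_symbol,
                    reverse_complement(prom.sequence),
                    -prom.window_end, -prom.window_start,
                )
                rev = pm.scan_promoter(pwm, rc, pm.ScanThresholds(1e-2, 1e-3))
                n = len(prom.sequence)
                mirrored = set()
                for h in fwd:
                    i = prom.tss_to_index(h.start)
                    j = n - pwm.length - i
                    mirrored.add((rc.index_to_tss(j), "-" if h.strand == "+" else "+",
                                  round(h.score_bits, 6)))
                got = {(h.start, h.strand, round(h.score_bits, 6)) for h in rev}
                assert got == mirrored


def test_hit_table_tsv_round_trip(small_table=None):
    pfms = pm.simulate_pwms(1, 6, 0.95, seed=41)
    pwms = [pm.pfm_to_pwm(pfms[0])]
    proms, _ = pm.simulate_promoters(1, pfms, [pm.PlantSpec("GENE01", pfms[0].matrix_id, -50)],
                                     window=(-200, 100), seed=42)
    table = pm.scan_collection(pwms, proms)
    import io
    buf = io.StringIO(table.to_tsv())
    back = pm.HitTable.from_tsv(buf)
    assert back.to_frame().equals(table.to_frame())
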