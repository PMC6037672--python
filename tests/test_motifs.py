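"""PWM scanning: JASPAR I/O, exact-null thresholds, strand-aware scanning."""

import itertools

import numpy as np
import pytest

from comotif.genomic import GenomicInterval, Peak
from comotif.motifs import (
    GRANULARITY,
    HitMatrix,
    MotifModel,
    MotifParseError,
    build_hit_matrix,
    build_scoring,
    estimate_background,
    hits_from_intervals,
    read_jaspar,
    scan_sequence,
    score_distribution,
    write_jaspar,
)

UNIFORM = np.full(4, 0.25)


def _random_motif(rng, width):
    return MotifModel(
        motif_id=f"R{width}", name="rand", pfm=rng.integers(0, 30, size=(width, 4)) + 1
    )


def _enumerate_scores(model):
    """Brute-force null: score of every 4^w word under the quantized matrix."""
    w = model.width
    scores = []
    for word in itertools.product(range(4), repeat=w):
        scores.append(sum(model.log_odds[i, n] for i, n in enumerate(word)))
    return np.array(scores)


class TestJasparIO:
    JASPAR = (
        ">M1 FIRST\nA [ 4 19 0 ]\nC [ 16 0 20 ]\nG [ 0 1 0 ]\nT [ 0 0 0 ]\n"
        ">M2 SECOND\nA [ 1 2 ]\nC [ 3 4 ]\nG [ 5 6 ]\nT [ 7 8 ]\n"
    )

    def test_two_record_file(self, tmp_path):
        f = tmp_path / "m.jaspar"
        f.write_text(self.JASPAR)
        models = read_jaspar(f)
        assert [m.motif_id for m in models] == ["M1", "M2"]
        assert [m.width for m in models] == [3, 2]
        assert models[0].pfm[1, 0] == 19  # counts preserved exactly

    def test_unequal_row_widths_name_the_record(self, tmp_path):
        f = tmp_path / "m.jaspar"
        f.write_text(">MBAD X\nA [ 1 2 3 ]\nC [ 1 2 ]\nG [ 1 2 3 ]\nT [ 1 2 3 ]\n")
        with pytest.raises(MotifParseError, match="MBAD"):
            read_jaspar(f)

    def test_missing_base_row_names_the_record(self, tmp_path):
        f = tmp_path / "m.jaspar"
        f.write_text(">MMISS X\nA [ 1 2 ]\nC [ 1 2 ]\nG [ 1 2 ]\n")
        with pytest.raises(MotifParseError, match="MMISS"):
            read_jaspar(f)

    def test_roundtrip_preserves_counts(self, tmp_path, rng):
        models = [_random_motif(rng, w) for w in (4, 7, 11)]
        f = tmp_path / "m.jaspar"
        write_jaspar(models, f)
        again = read_jaspar(f)
        for a, b in zip(models, again):
            np.testing.assert_array_equal(a.pfm, b.pfm)

    def test_empty_file(self, tmp_path):
        f = tmp_path / "m.jaspar"
        f.write_text("")
        assert read_jaspar(f) == []


class TestBuildScoring:
    def test_width_one_selects_dominant_base_only(self):
        m = MotifModel("W1", "x", np.array([[10, 0, 0, 0]]))
        sm = build_scoring(m, UNIFORM, pseudocount_fraction=0.01, threshold_pvalue=0.3)
        _, tail = score_distribution(sm.log_odds, UNIFORM)
        # only A passes; null tail at threshold is exactly P(A) = 0.25
        hits = scan_sequence("ACGT", sm)
        fwd_bases = {o for o, s, _ in hits if s == "+"}
        assert fwd_bases == {0}
        assert sm.log_odds[0, 0] >= sm.threshold
        assert all(sm.log_odds[0, n] < sm.threshold for n in (1, 2, 3))

    def test_pvalue_one_accepts_every_word(self, rng):
        m = _random_motif(rng, 4)
        sm = build_scoring(m, UNIFORM, threshold_pvalue=1.0)
        scores = _enumerate_scores(sm)
        assert scores.min() >= sm.threshold - 1e-9  # minimal score is the threshold

    def test_position_probabilities_normalized(self, rng):
        m = _random_motif(rng, 6)
        bg = np.array([0.2, 0.3, 0.3, 0.2])
        sm = build_scoring(m, bg, pseudocount_fraction=0.5)
        probs = bg * 2.0**sm.log_odds
        # quantization moves each entry by at most one lattice step
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=4 * GRANULARITY)

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5, 6])
    def test_dp_tail_matches_exhaustive_enumeration(self, rng, width):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        m = _random_motif(rng, width)
        sm = build_scoring(m, bg, threshold_pvalue=1e-3)
        support, tail = score_distribution(sm.log_odds, bg)
        words = list(itertools.product(range(4), repeat=width))
        word_scores = np.array(
            [sum(sm.log_odds[i, n] for i, n in enumerate(wd)) for wd in words]
        )
        word_probs = np.array(
            [np.prod([bg[n] for n in wd]) for wd in words]
        )
        for s, t in zip(support, tail):
            exact = word_probs[word_scores >= s - GRANULARITY / 2].sum()
            assert t == pytest.approx(exact, abs=1e-9)

    def test_threshold_tail_bound_and_minimality(self, rng):
        for width in (2, 3, 4, 5):
            bg = UNIFORM
            m = _random_motif(rng, width)
            for p in (0.3, 0.05, 1e-3):
                sm = build_scoring(m, bg, threshold_pvalue=p)
                scores = _enumerate_scores(sm)
                tail_at_thr = np.mean(scores >= sm.threshold - 1e-9)
                assert tail_at_thr <= p + 1e-12
                # one lattice step lower the tail must exceed p (minimality)
                lower = sm.threshold - GRANULARITY
                if np.any(scores < sm.threshold - 1e-9):
                    tail_lower = np.mean(scores >= lower - 1e-9)
                    assert tail_lower > p or tail_lower == tail_at_thr

    def test_lower_pvalue_raises_threshold(self, rng):
        m = _random_motif(rng, 5)
        thrs = [
            build_scoring(m, UNIFORM, threshold_pvalue=p).threshold
            for p in (0.5, 0.1, 1e-2, 1e-3)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(thrs, thrs[1:]))

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("Z", "z", np.zeros((0, 4)))

    def test_invalid_background_rejected(self, rng):
        with pytest.raises(ValueError):
            build_scoring(_random_motif(rng, 3), np.array([0.5, 0.5, 0.5, 0.5]))


class TestScanSequence:
    def _aa_motif(self):
        m = MotifModel("AA", "aa", np.array([[50, 1, 1, 1], [50, 1, 1, 1]]))
        return build_scoring(m, UNIFORM, threshold_pvalue=0.07)  # accepts AA only

    def test_sliding_window_hits(self):
        sm = self._aa_motif()
        hits = scan_sequence("AAAA", sm)
        fwd = [(o, s) for o, s, _ in hits if s == "+"]
        assert fwd == [(0, "+"), (1, "+"), (2, "+")]

    def test_n_masks_windows(self):
        sm = self._aa_motif()
        assert scan_sequence("NNNN", sm) == []
        assert [h[:2] for h in scan_sequence("AANA", sm) if h[1] == "+"] == [(0, "+")]

    def test_sequence_shorter_than_motif(self):
        assert scan_sequence("A", self._aa_motif()) == []

    def test_case_insensitive(self):
        sm = self._aa_motif()
        assert len(scan_sequence("aaaa", sm)) == len(scan_sequence("AAAA", sm))

    def test_reverse_strand_hit(self):
        sm = self._aa_motif()
        hits = scan_sequence("GTTG", sm)  # TT revcomp = AA at offset 1
        assert [(o, s) for o, s, _ in hits] == [(1, "-")]

    def test_matches_naive_oracle(self, rng):
        comp = {0: 3, 1: 2, 2: 1, 3: 0}
        bases = "ACGT"
        models = [
            build_scoring(_random_motif(rng, w), UNIFORM, threshold_pvalue=p)
            for w, p in ((4, 0.02), (6, 0.01), (9, 0.005))
        ]
        for _ in range(20):
            codes = rng.integers(0, 4, size=200)
            codes[rng.integers(0, 200, size=5)] = 4  # sprinkle N
            seq = "".join(bases[c] if c < 4 else "N" for c in codes)
            for sm in models:
                w = sm.width
                expected = []
                for o in range(len(seq) - w + 1):
                    window = codes[o : o + w]
                    if np.any(window == 4):
                        continue
                    f = sum(sm.log_odds[i, n] for i, n in enumerate(window))
                    r = sum(
                        sm.log_odds[i, n]
                        for i, n in enumerate(comp[c] for c in window[::-1])
                    )
                    if f >= sm.threshold - 1e-9:
                        expected.append((o, "+"))
                    if r >= sm.threshold - 1e-9:
                        expected.append((o, "-"))
                got = [(o, s) for o, s, _ in scan_sequence(seq, sm)]
                assert sorted(got) == sorted(expected)

    def test_strand_symmetry_on_reverse_complement(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        sm = build_scoring(_random_motif(rng, 5), UNIFORM, threshold_pvalue=0.05)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=120))
        rc = seq.translate(comp)[::-1]
        fwd = scan_sequence(seq, sm)
        rev = scan_sequence(rc, sm)
        L, w = len(seq), sm.width
        mirrored = sorted(
            (L - w - o, "+-"[s == "+"], round(sc, 6)) for o, s, sc in rev
        )
        assert sorted((o, s, round(sc, 6)) for o, s, sc in fwd) == mirrored


class TestHitMatrix:
    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            HitMatrix(["p1"], ["m1", "m2"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            HitMatrix(["p1"], ["m1"], np.array([[-1]]))

    def test_tsv_roundtrip(self, tmp_path, rng):
        hm = HitMatrix(
            ["chr1:0-10", "chr1:20-30"],
            ["m1", "m2", "m3"],
            rng.integers(0, 4, size=(2, 3)),
        )
        f = tmp_path / "hm.tsv"
        hm.write_tsv(f)
        back = HitMatrix.read_tsv(f)
        assert back.peak_index == hm.peak_index
        assert back.motif_index == hm.motif_index
        np.testing.assert_array_equal(back.occupancy, hm.occupancy)


class TestBuildHitMatrix:
    def _genome_and_peaks(self, rng, n_peaks=20, length=4000):
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
        peaks = [
            Peak(interval=GenomicInterval("chr1", i * 200, i * 200 + 150))
            for i in range(n_peaks)
        ]
        return {"chr1": seq}, peaks

    def test_planted_motif_found_in_every_peak(self, rng):
        genome, peaks = self._genome_and_peaks(rng)
        motif = MotifModel(
            "P", "planted", np.eye(4)[rng.integers(0, 4, size=10)] * 97 + 1
        )
        cons = motif.consensus
        seq = list(genome["chr1"])
        for p in peaks:
            mid = p.interval.start + 70
            seq[mid : mid + 10] = cons
        genome["chr1"] = "".join(seq)
        hm = build_hit_matrix(peaks, genome, [motif], threshold_pvalue=1e-4)
        assert np.all(hm.column("P") >= 1)

    def test_all_n_sequence_gives_zero_row(self, rng):
        genome = {"chr1": "N" * 500}
        peaks = [Peak(interval=GenomicInterval("chr1", 0, 400))]
        motif = MotifModel("P", "p", np.ones((4, 4)))
        hm = build_hit_matrix(
            peaks, genome, [motif], background=UNIFORM, threshold_pvalue=0.9
        )
        assert hm.occupancy.sum() == 0

    def test_empty_motif_list(self, rng):
        genome, peaks = self._genome_and_peaks(rng, n_peaks=3)
        hm = build_hit_matrix(peaks, genome, [])
        assert hm.occupancy.shape == (3, 0)
        assert len(hm.peak_index) == 3

    def test_missing_chromosome_dropped_with_warning(self, rng, caplog):
        genome, peaks = self._genome_and_peaks(rng, n_peaks=2)
        peaks.append(Peak(interval=GenomicInterval("chrMISSING", 0, 100)))
        import logging

        with caplog.at_level(logging.WARNING):
            hm = build_hit_matrix(peaks, genome, [], background=UNIFORM)
        assert len(hm.peak_index) == 2
        assert "chrMISSING" in caplog.text

    def test_occupancy_monotone_in_threshold_pvalue(self, rng):
        genome, peaks = self._genome_and_peaks(rng)
        motif = _random_motif(rng, 6)
        occs = [
            build_hit_matrix(
                peaks, genome, [motif], background=UNIFORM, threshold_pvalue=p
            ).occupancy
            for p in (1e-2, 1e-3, 1e-4)
        ]
        assert np.all(occs[0] >= occs[1]) and np.all(occs[1] >= occs[2])

    def test_summit_window_clips_to_peak(self, rng):
        genome, peaks = self._genome_and_peaks(rng, n_peaks=5)
        for p in peaks:
            p.summit = 10
        motif = _random_motif(rng, 6)
        whole = build_hit_matrix(
            peaks, genome, [motif], background=UNIFORM, threshold_pvalue=0.05
        )
        summit = build_hit_matrix(
            peaks, genome, [motif], window="summit", summit_radius=30,
            background=UNIFORM, threshold_pvalue=0.05,
        )
        assert np.all(summit.occupancy <= whole.occupancy)


class TestHitsFromIntervals:
    def test_exact_match_counts_one(self):
        p = Peak(interval=GenomicInterval("chr1", 100, 200))
        hm = hits_from_intervals([p], [GenomicInterval("chr1", 100, 200)], "tf")
        assert hm.occupancy[0, 0] == 1
        assert hm.motif_index == ["tf"]

    def test_abutting_site_counts_zero(self):
        p = Peak(interval=GenomicInterval("chr1", 100, 200))
        hm = hits_from_intervals([p], [GenomicInterval("chr1", 200, 300)], "tf")
        assert hm.occupancy[0, 0] == 0

    def test_matches_all_pairs_oracle(self, rng):
        peaks = []
        for _ in range(60):
            s = int(rng.integers(0, 5000))
            peaks.append(
                Peak(
                    interval=GenomicInterval(
                        f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(10, 400))
                    )
                )
            )
        sites = []
        for _ in range(200):
            s = int(rng.integers(0, 5000))
            sites.append(
                GenomicInterval(f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(5, 100)))
            )
        hm = hits_from_intervals(peaks, sites, "x")
        for i, p in enumerate(peaks):
            exp = sum(1 for s in sites if p.interval.overlaps(s))
            assert hm.occupancy[i, 0] == exp


class TestBackgroundEstimation:
    def test_composition_recovered(self):
        bg = estimate_background(["AACG", "TTNN"])
        np.testing.assert_allclose(bg, [2 / 6, 1 / 6, 1 / 6, 2 / 6], atol=1e-9)

    def test_missing_base_floored_not_zero(self):
        bg = estimate_background(["AAAA"])
        assert bg.min() > 0 and abs(bg.sum() - 1) < 1e-9
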