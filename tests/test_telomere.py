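"""Telomere repeat filters, length measurement, RT and end classification."""

import numpy as np
import pandas as pd
import pytest

from nanotiming.io_formats import GenomeAnnotation, ModReadRecord, revcomp
from nanotiming.rt_profile import RTProfile
from nanotiming.simulate import _tg_run, simulate_telomere_cohort
from nanotiming.telomere import (
    classify_end,
    extract_candidate,
    is_telomeric,
    length_rt_correlation,
    measure_length,
    population_telomere_rt,
    single_telomere_rt,
    window_stats,
)


class TestWindowStats:
    def test_pure_tg_dinucleotide_hand_count(self):
        st = window_stats("TG" * 25)
        assert st.freqGG == 0.0          # fails the GG criterion
        assert st.freqTelo == pytest.approx(1.0)
        assert st.H == pytest.approx(1.0)

    def test_tgtggg_hand_count(self):
        st = window_stats("TGTGGG" * 8)   # 48 nt
        assert st.freqGG == pytest.approx(16 / 47)
        assert st.freqTelo == pytest.approx(1.0)
        assert st.H == pytest.approx(0.9182958, rel=1e-6)

    def test_homopolymer_fails_everything(self):
        st = window_stats("A" * 50)
        assert (st.freqGG, st.freqTelo, st.H) == (0.0, 0.0, 0.0)

    def test_non_acgt_symbols_excluded(self):
        st = window_stats("TGNNTG")
        assert st.freqTelo == pytest.approx(1.0)  # only TG pairs counted

    def test_too_short_window_undefined(self):
        assert np.isnan(window_stats("T").H)


class TestIsTelomeric:
    def test_simulated_repeats_accepted(self):
        rng = np.random.default_rng(0)
        assert is_telomeric(_tg_run(rng, 300))

    def test_embedded_polya_block_rejected(self):
        rng = np.random.default_rng(1)
        run = _tg_run(rng, 300)
        seq = run[:150] + "A" * 60 + run[150:]
        assert not is_telomeric(seq)

    def test_short_candidate_single_window(self):
        assert is_telomeric("TGTGGG" * 5)  # 30 nt < window

    def test_empty_candidate_errors(self):
        with pytest.raises(ValueError):
            is_telomeric("")


class TestMeasureLength:
    def test_pure_repeat_measured_exactly(self):
        rng = np.random.default_rng(2)
        run = _tg_run(rng, 312)
        assert measure_length(run) == 312

    def test_rejected_candidate_returns_none(self):
        assert measure_length("A" * 200) is None

    def test_terminal_fully_failing_windows_trimmed(self):
        rng = np.random.default_rng(3)
        run = _tg_run(rng, 500)
        # a short random flank: windows fully inside it fail all criteria
        flank = "".join(rng.choice(list("ACGT"), size=30))
        measured = measure_length(run + flank)
        assert measured is not None
        assert abs(measured - 500) <= 50  # trim resolution is one window


class TestExtractCandidate:
    def test_cohort_candidates_oriented_g_rich_with_clip(self, small_genome):
        records, truth = simulate_telomere_cohort(small_genome, 21, n_reads=40)
        for rec, (_, row) in zip(records, truth.iterrows()):
            cand = extract_candidate(rec, small_genome.annotation)
            assert cand is not None
            assert cand.end_id == row["end_id"]
            # G-rich orientation regardless of chromosome side
            assert cand.seq.count("G") > cand.seq.count("C")
            assert len(cand.seq) == row["true_length"]

    def test_extraction_is_idempotent(self, small_genome):
        records, _ = simulate_telomere_cohort(small_genome, 22, n_reads=5)
        a = extract_candidate(records[0], small_genome.annotation)
        b = extract_candidate(records[0], small_genome.annotation)
        assert a.seq == b.seq and a.end_id == b.end_id

    def test_internal_read_yields_no_candidate(self, small_genome):
        chrom = next(iter(small_genome.sequences))
        rec = ModReadRecord("mid", chrom, 100_000, "+", np.array([100_010]),
                            np.array([0.5]), aligned_len=5000,
                            seq=small_genome.sequences[chrom][100_000:105_000])
        assert extract_candidate(rec, small_genome.annotation) is None

    def test_left_end_c_rich_read_is_complemented(self, small_genome):
        ann = small_genome.annotation
        (end_id, chrom, side, t_start, t_end) = [e for e in ann.ends() if e[2] == "L"][0]
        seq = small_genome.sequences[chrom][0:t_end + 2000]
        rec = ModReadRecord("lread", chrom, 0, "-", np.array([t_end + 10]),
                            np.array([0.5]), aligned_len=len(seq), seq=seq)
        cand = extract_candidate(rec, ann)
        assert cand.end_id == end_id
        # the forward reference is C(1-3)A at a left end; candidate is TG(1-3)
        assert cand.seq == revcomp(seq[:t_end])
        assert cand.seq.count("G") > cand.seq.count("C")


def _rt_record(chrom, positions, probs, aligned_len, ref_start=0):
    return ModReadRecord("rt", chrom, ref_start, "+", np.asarray(positions),
                         np.asarray(probs), aligned_len=aligned_len)


class TestSingleTelomereRT:
    def test_uniform_probability_window_mean(self, small_genome):
        ann = small_genome.annotation
        end_id, chrom, side, t_start, t_end = [e for e in ann.ends() if e[2] == "L"][0]
        pos = np.arange(t_end + 10, t_end + 990, 37)
        rec = _rt_record(chrom, pos, np.full(pos.size, 0.4), aligned_len=8000)
        got = single_telomere_rt(rec, ann)
        assert got is not None
        assert got[0] == end_id
        assert got[1] == pytest.approx(0.4)

    def test_short_read_filtered(self, small_genome):
        ann = small_genome.annotation
        _, chrom, _, t_start, t_end = [e for e in ann.ends() if e[2] == "L"][0]
        pos = np.arange(t_end + 10, t_end + 990, 37)
        rec = _rt_record(chrom, pos, np.full(pos.size, 0.4), aligned_len=4900)
        end_id, raw, rescaled = single_telomere_rt(rec, ann, rescale_params=(0.05, 0.3))
        assert raw == pytest.approx(0.4)
        assert rescaled is None  # 4.9 kb read: excluded

    def test_parental_read_filtered_by_background(self, small_genome):
        ann = small_genome.annotation
        _, chrom, _, t_start, t_end = [e for e in ann.ends() if e[2] == "L"][0]
        pos = np.arange(t_end + 10, t_end + 990, 37)
        rec = _rt_record(chrom, pos, np.full(pos.size, 0.005), aligned_len=8000)
        _, raw, rescaled = single_telomere_rt(rec, ann, rescale_params=(0.05, 0.3))
        assert rescaled is None


def _profile_with(bins):
    df = pd.DataFrame([{"chrom": c, "start": s, "mbc": v, "n_readbins": 5} for c, s, v in bins])
    return RTProfile(df, scale="rescaled", rescale_params=(0.05, 0.3))


def _two_end_annotation(boundary_left, chrom_len=10_000):
    return GenomeAnnotation(
        chrom_lengths={"chr1": chrom_len},
        telomere_repeats=pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, chrom_len - boundary_left],
            "end": [boundary_left, chrom_len], "name": ["l", "r"]}),
    )


class TestPopulationTelomereRT:
    def test_two_bin_weighted_average(self):
        ann = _two_end_annotation(1500)
        prof = _profile_with([("chr1", 1000, 1.2), ("chr1", 2000, 1.8)])
        # window [1500, 2500): half in each grid bin
        assert population_telomere_rt(prof, ann, "chr1_L") == pytest.approx(0.5 * 1.2 + 0.5 * 1.8)

    def test_boundary_on_grid_single_bin(self):
        ann = _two_end_annotation(1000)
        prof = _profile_with([("chr1", 1000, 1.4), ("chr1", 2000, 1.9)])
        assert population_telomere_rt(prof, ann, "chr1_L") == pytest.approx(1.4)

    def test_right_end_mirror_weights(self):
        # right telomere starts at 8500; window [7500, 8500)
        ann = _two_end_annotation(1500)
        prof = _profile_with([("chr1", 7000, 1.1), ("chr1", 8000, 1.7)])
        assert population_telomere_rt(prof, ann, "chr1_R") == pytest.approx(0.5 * 1.1 + 0.5 * 1.7)

    def test_missing_bins_give_nan(self):
        ann = _two_end_annotation(1000)
        prof = _profile_with([("chr1", 5000, 1.5)])
        assert np.isnan(population_telomere_rt(prof, ann, "chr1_L"))


def _classification_annotation(y_rows):
    return GenomeAnnotation(
        chrom_lengths={"chr1": 200_000},
        telomere_repeats=pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 199_700],
            "end": [300, 200_000], "name": ["l", "r"]}),
        x_elements=pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [6000, 192_000],
            "end": [7500, 193_500], "name": ["xl", "xr"]}),
        y_elements=pd.DataFrame(y_rows, columns=["chrom", "start", "end", "name"]),
        centromeres=pd.DataFrame({"chrom": ["chr1"], "start": [99_940], "end": [100_060], "name": ["cen"]}),
    )


class TestClassifyEnd:
    def test_nearby_y_prime_same_arm(self):
        ann = _classification_annotation([("chr1", 500, 5700, "y")])  # 300 bp from X
        assert classify_end(ann, "chr1_L") == "XY'"

    def test_y_prime_only_on_opposite_arm(self):
        ann = _classification_annotation([("chr1", 500, 5700, "y")])
        assert classify_end(ann, "chr1_R") == "X"

    def test_distant_y_prime_is_x(self):
        ann = _classification_annotation([("chr1", 30_000, 35_200, "y")])  # 22.5 kb gap
        assert classify_end(ann, "chr1_L") == "X"

    def test_missing_x_element_errors(self):
        ann = _two_end_annotation(300, chrom_len=200_000)
        with pytest.raises(ValueError, match="X element"):
            classify_end(ann, "chr1_L")

    def test_simulator_all_y_layout_classifies_xy(self):
        from nanotiming.simulate import SimConfig, build_genome
        g = build_genome(SimConfig(n_chrom=2, chrom_length=200_000, y_prime_fraction=1.0, seed=3), 3)
        for end_id, *_ in g.annotation.ends():
            assert classify_end(g.annotation, end_id) == "XY'"


class TestLengthRTCorrelation:
    def _cohort_pairs(self, genome, seed, coupling):
        records, truth = simulate_telomere_cohort(genome, seed, n_reads=500, coupling=coupling)
        pairs = []
        for rec, (_, row) in zip(records, truth.iterrows()):
            rt = single_telomere_rt(rec, genome.annotation, rescale_params=(0.05, 0.3))
            cand = extract_candidate(rec, genome.annotation)
            length = measure_length(cand) if cand else None
            if rt is not None and rt[2] is not None and length is not None:
                pairs.append((length, rt[2]))
        return zip(*pairs)

    def test_independent_cohort_near_zero_rho(self, small_genome):
        rho, _ = length_rt_correlation(*self._cohort_pairs(small_genome, 31, 0.0))
        assert abs(rho) < 0.1

    def test_imposed_coupling_detected(self, small_genome):
        rho, p = length_rt_correlation(*self._cohort_pairs(small_genome, 31, 0.5))
        assert rho < -0.3
        assert p < 1e-6

    def test_ties_handled_with_average_ranks(self):
        rho, _ = length_rt_correlation([300, 300, 310, 320], [1.2, 1.2, 1.5, 1.9])
        assert np.isfinite(rho)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            length_rt_correlation([1, 2], [3, 4])
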