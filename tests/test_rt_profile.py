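"""Per-read binning, profile aggregation, rescaling and comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanotiming.io_formats import ModReadRecord
from nanotiming.rt_profile import (
    RTProfile,
    bin_read,
    compare_profiles,
    compute_profile,
    is_parental,
    rescale_profile,
)

SIZES = {"chr1": 100_000}


def _rec(positions, probs, chrom="chr1"):
    return ModReadRecord("r", chrom, int(min(positions)) if len(positions) else 0, "+",
                         np.asarray(positions), np.asarray(probs),
                         aligned_len=(int(max(positions)) + 1 if len(positions) else 0))


def _track(means, chrom="chr1", start_bin=0, counts=None, bin_size=1000):
    means = np.asarray(means, dtype=float)
    from nanotiming.rt_profile import ReadBinnedTrack
    return ReadBinnedTrack(
        "t", chrom, (np.arange(len(means)) + start_bin) * bin_size, means,
        np.asarray(counts) if counts is not None else np.full(len(means), 10), bin_size)


class TestBinRead:
    def test_constant_probability_spans_three_bins(self):
        pos = np.arange(100, 2900, 100)
        tr = bin_read(_rec(pos, np.full(pos.size, 0.3)))
        assert tr.bin_starts.tolist() == [0, 1000, 2000]
        assert np.allclose(tr.means, 0.3)

    def test_two_level_read_hand_average(self):
        # probs 0.1 below 1000, 0.5 from 1000 on, read covering [0, 2500)
        pos = np.arange(50, 2500, 50)
        probs = np.where(pos < 1000, 0.1, 0.5)
        tr = bin_read(_rec(pos, probs))
        assert tr.bin_starts.tolist() == [0, 1000, 2000]
        assert np.allclose(tr.means, [0.1, 0.5, 0.5])

    def test_bin_without_thymidines_is_absent(self):
        pos = np.array([100, 500, 2100, 2600])  # nothing in [1000, 2000)
        tr = bin_read(_rec(pos, np.full(4, 0.2)))
        assert tr.bin_starts.tolist() == [0, 2000]

    def test_grid_is_genome_anchored(self):
        # same sites shifted by a read-start change still land on the same bins
        tr = bin_read(_rec([1500, 1600], [0.4, 0.6]))
        assert tr.bin_starts.tolist() == [1000]
        assert tr.means[0] == pytest.approx(0.5)


class TestIsParental:
    @pytest.mark.parametrize("means,expected", [
        ([0.0, 0.0, 0.0], True),
        ([0.5, 0.5], False),
        ([0.01, 0.02, 0.03], True),  # median exactly 0.02: inclusive threshold
        ([0.01, 0.03, 0.05], False),
    ])
    def test_median_threshold(self, means, expected):
        assert is_parental(_track(means)) is expected

    def test_empty_track_errors(self):
        with pytest.raises(ValueError):
            is_parental(_track([]))


class TestComputeProfile:
    def test_mean_over_read_bins(self):
        prof = compute_profile([_track([0.1]), _track([0.3])], SIZES)
        assert prof.data["mbc"].tolist() == [pytest.approx(0.2)]
        assert prof.data["n_readbins"].tolist() == [2]

    def test_background_bins_leave_genomic_bin_missing(self):
        prof = compute_profile([_track([0.02]), _track([0.015])], SIZES)
        assert len(prof.data) == 0

    def test_single_surviving_read_bin(self):
        prof = compute_profile([_track([0.4]), _track([0.01])], SIZES)
        assert prof.data["mbc"].tolist() == [pytest.approx(0.4)]
        assert prof.data["n_readbins"].tolist() == [1]

    def test_empty_input_gives_empty_profile(self):
        assert len(compute_profile([], SIZES).data) == 0

    def test_single_track_aggregation_consistency(self):
        tr = _track([0.01, 0.3, 0.5])
        prof = compute_profile([tr], SIZES)
        keep = tr.means > 0.02
        assert np.array_equal(prof.data["start"].to_numpy(), tr.bin_starts[keep])
        assert np.allclose(prof.data["mbc"].to_numpy(), tr.means[keep])

    def test_site_weighted_mean_option(self):
        a = _track([0.1], counts=[1])
        b = _track([0.4], counts=[3])
        prof = compute_profile([a, b], SIZES, site_weighted=True)
        assert prof.data["mbc"].iloc[0] == pytest.approx((0.1 * 1 + 0.4 * 3) / 4)


def _profile_from_values(values):
    n = len(values)
    return RTProfile(pd.DataFrame({
        "chrom": "chr1", "start": np.arange(n) * 1000,
        "mbc": np.asarray(values, dtype=float), "n_readbins": 1}))


class TestRescale:
    def test_percentiles_anchored_exactly(self):
        rng = np.random.default_rng(0)
        prof = _profile_from_values(rng.random(100_000))
        res = rescale_profile(prof)
        lo, hi = np.percentile(res.values, [0.5, 99.5])
        assert lo == pytest.approx(1.0, abs=1e-9)
        assert hi == pytest.approx(2.0, abs=1e-9)

    def test_integer_ramp_tails_fall_outside_unit_band(self):
        res = rescale_profile(_profile_from_values(np.arange(1, 1001)))
        # affine map with interpolated percentiles 5.995 / 995.005
        assert res.values.iloc[0] == pytest.approx(0.9949494949, abs=1e-9)
        assert res.values.iloc[-1] == pytest.approx(2.0050505050, abs=1e-9)
        assert res.rescale_params == pytest.approx((5.995, 995.005))

    def test_idempotent_on_value_set(self):
        prof = _profile_from_values(np.random.default_rng(1).random(5000))
        once = rescale_profile(prof)
        twice = rescale_profile(once)
        assert np.allclose(once.values, twice.values)

    def test_rank_order_preserved(self):
        vals = np.random.default_rng(2).random(1000)
        res = rescale_profile(_profile_from_values(vals))
        assert np.array_equal(np.argsort(vals), np.argsort(res.values.to_numpy()))

    def test_constant_profile_errors(self):
        with pytest.raises(ValueError, match="constant"):
            rescale_profile(_profile_from_values(np.full(100, 0.3)))


def _brute_spearman(a, b):
    """Independent oracle: Pearson correlation of average ranks."""
    def ranks(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x)
        r = np.empty(len(x))
        i = 0
        sorted_x = x[order]
        pos = 1.0 + np.arange(len(x))
        while i < len(x):
            j = i
            while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
                j += 1
            r[order[i:j + 1]] = pos[i:j + 1].mean()
            i = j + 1
        return r
    ra, rb = ranks(a), ranks(b)
    return float(np.corrcoef(ra, rb)[0, 1])


class TestCompareProfiles:
    def test_identity_and_negation(self):
        x = np.random.default_rng(3).random(50)
        assert compare_profiles(x, x).rho == pytest.approx(1.0)
        assert compare_profiles(x, -x).rho == pytest.approx(-1.0)

    def test_hand_example_against_rank_oracle(self):
        a, b = [1, 2, 3, 4], [1, 3, 2, 4]
        res = compare_profiles(a, b)
        assert res.rho == pytest.approx(0.8)
        assert res.rho == pytest.approx(_brute_spearman(a, b))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_rank_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=30).astype(float)
        b = rng.integers(0, 5, size=30).astype(float)
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            return
        assert compare_profiles(a, b).rho == pytest.approx(_brute_spearman(a, b), abs=1e-12)

    def test_pairwise_complete_joins_on_bins(self):
        a = _profile_from_values([0.1, 0.2, 0.3, 0.4])
        b = _profile_from_values([0.2, 0.1, 0.4, 0.5])
        b.data = b.data[b.data["start"] != 1000]  # drop one bin from b
        res = compare_profiles(a, b)
        assert res.n == 3

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(200), rng.random(200)
        base = compare_profiles(a, b).rho
        assert compare_profiles(np.exp(3 * a) + 1, b).rho == pytest.approx(base)
        assert compare_profiles(1 + (a - a.min()) / np.ptp(a), b).rho == pytest.approx(base)

    def test_too_few_common_bins_errors(self):
        with pytest.raises(ValueError):
            compare_profiles([1.0, 2.0], [2.0, 1.0])

    def test_ols_line_for_presentation(self):
        x = np.arange(10, dtype=float)
        res = compare_profiles(x, 2 * x + 1, fit_line=True)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
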