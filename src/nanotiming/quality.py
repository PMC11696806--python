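"""Profile-quality curves and the intrinsic-noise estimator.

Quality as a function of sequencing depth is assessed by repeatedly
subsampling reads, rebuilding the MBC profile and correlating it against a
reference track (pairwise-complete Spearman). Intrinsic noise is estimated as
the variance of signal differences between consecutive 1 kb bins: RT varies
over 5-10+ kb, so bin-to-bin jumps are mostly method noise. Because nanopore
reads span successive bins, neighbouring bin values are not independent; the
cross-sample mode breaks that dependence by taking consecutive bins from two
independent subsamples, and the shuffled mode calibrates the estimator on a
profile with no positional structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rt_profile import (
    BACKGROUND,
    DEFAULT_BIN_SIZE,
    ReadBinnedTrack,
    RTProfile,
    compare_profiles,
    compute_profile,
)

__all__ = ["subsample_quality", "intrinsic_noise", "NoiseEstimate"]


def subsample_quality(
    tracks: Sequence[ReadBinnedTrack],
    reference: RTProfile | pd.Series,
    chrom_lengths: Mapping[str, int],
    depths: Sequence[int],
    n_rep: int = 100,
    seed: int = 0,
    bin_size: int = DEFAULT_BIN_SIZE,
    background: float = BACKGROUND,
) -> pd.DataFrame:
    """Depth/quality table: for each depth x replicate, draw that many reads
    without replacement, rebuild the profile, and correlate it with the
    reference over pairwise-complete bins.

    Reproducible given ``seed``; raises if a depth exceeds the read count.
    Returns columns (depth, replicate, rho, n_bins, seed).
    """
    n_reads = len(tracks)
    ref_series = reference.indexed() if isinstance(reference, RTProfile) else reference
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > n_reads:
            raise ValueError(f"depth {depth} exceeds available reads ({n_reads})")
        for rep in range(n_rep):
            idx = rng.choice(n_reads, size=depth, replace=False)
            prof = compute_profile((tracks[i] for i in idx), chrom_lengths, bin_size, background)
            joined = pd.concat(
                [prof.indexed().rename("a"), ref_series.rename("b")], axis=1, join="inner"
            )
            cmp = compare_profiles(joined["a"].to_numpy(), joined["b"].to_numpy())
            rows.append({"depth": depth, "replicate": rep, "rho": cmp.rho,
                         "n_bins": cmp.n, "seed": seed})
    return pd.DataFrame(rows)


@dataclass
class NoiseEstimate:
    mode: str  # within_sample | cross_sample | shuffled
    variance: float
    n_pairs: int
    mapped_bases: int | None = None


def _consecutive_pairs(profile: RTProfile, min_coverage: float | None) -> list[tuple[pd.Series, pd.Series]]:
    """Per chromosome, aligned (left bin, right bin) value pairs for strictly
    consecutive defined bins; pairs straddling missing bins are skipped."""
    df = profile.data
    if min_coverage is not None:
        df = df[df["n_readbins"] >= min_coverage]
    pairs = []
    for _, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        adjacent = np.diff(grp["start"].to_numpy()) == profile.bin_size
        left = grp["mbc"].to_numpy()[:-1][adjacent]
        right = grp["mbc"].to_numpy()[1:][adjacent]
        if left.size:
            pairs.append((left, right))
    return pairs


def intrinsic_noise(
    profile: RTProfile,
    mode: str = "within_sample",
    profile_b: RTProfile | None = None,
    coverage_filter: float = 0.25,
    seed: int = 0,
    mapped_bases: int | None = None,
) -> NoiseEstimate:
    """Variance of consecutive-bin signal differences.

    Modes: ``within_sample`` uses one profile's own consecutive bins;
    ``cross_sample`` takes the left bin from ``profile`` and the right bin
    from the independently sampled ``profile_b`` (removing the read-induced
    dependence between neighbours); ``shuffled`` permutes the bin values
    genome-wide first (fixed ``seed``), estimating the no-structure ceiling.
    Bins with coverage below ``coverage_filter`` times the median coverage are
    ignored. Profiles should be on a common (rescaled) scale for
    cross-method comparison.
    """
    min_cov = None
    if coverage_filter and len(profile.data):
        min_cov = coverage_filter * float(profile.data["n_readbins"].median())
    if mode == "shuffled":
        rng = np.random.default_rng(seed)
        data = profile.data.copy()
        if min_cov is not None:
            data = data[data["n_readbins"] >= min_cov].reset_index(drop=True)
        data["mbc"] = rng.permutation(data["mbc"].to_numpy())
        profile = RTProfile(data, profile.bin_size, profile.scale, profile.rescale_params)
        min_cov = None  # already applied
    if mode in ("within_sample", "shuffled"):
        pairs = _consecutive_pairs(profile, min_cov)
        diffs = np.concatenate([r - l for l, r in pairs]) if pairs else np.empty(0)
    elif mode == "cross_sample":
        if profile_b is None:
            raise ValueError("cross_sample mode needs a second, independent profile")
        a = profile.indexed()
        b = profile_b.indexed()
        if min_cov is not None:
            cov_a = profile.data.set_index(["chrom", "start"])["n_readbins"]
            cov_b = profile_b.data.set_index(["chrom", "start"])["n_readbins"]
            a = a[cov_a >= min_cov]
            min_cov_b = coverage_filter * float(profile_b.data["n_readbins"].median())
            b = b[cov_b >= min_cov_b]
        diffs_list = []
        for (chrom, start), val in a.items():
            nxt = (chrom, start + profile.bin_size)
            if nxt in b.index:
                diffs_list.append(b[nxt] - val)
        diffs = np.asarray(diffs_list, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if diffs.size < 2:
        raise ValueError("fewer than 2 consecutive defined bin pairs")
    return NoiseEstimate(mode=mode, variance=float(np.var(diffs)), n_pairs=int(diffs.size),
                         mapped_bases=mapped_bases)
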