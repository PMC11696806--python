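"""Mean-BrdU-content (MBC) replication-timing profiles.

The genome is divided into consecutive, non-overlapping bins anchored at
position 0 of each chromosome (1 kb by default). BrdU probabilities along a
single read are averaged within each bin it intersects; the genomic profile
averages, per bin, the read-level bin values that exceed the basecaller
background (0.02), which removes parental DNA and DNA replicated before the
label was added. Raw MBC is high in early- and low in late-replicating DNA;
profiles are linearly rescaled so the 0.5th/99.5th percentiles sit at 1 (end
of S phase) and 2 (start of S phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ModReadRecord

__all__ = [
    "ReadBinnedTrack",
    "RTProfile",
    "bin_read",
    "bin_reads",
    "is_parental",
    "compute_profile",
    "rescale_profile",
    "rescale_values",
    "compare_profiles",
    "DEFAULT_BIN_SIZE",
    "BACKGROUND",
]

DEFAULT_BIN_SIZE = 1000
#: Background level of the BrdU detection model; read-level bins at or below
#: this mean probability are treated as BrdU-free.
BACKGROUND = 0.02


@dataclass
class ReadBinnedTrack:
    """Per-read mean BrdU probability on the genome-anchored bin grid.

    Only bins containing at least one thymidine site are present.
    """

    read_id: str
    chrom: str
    bin_starts: np.ndarray  # ascending, multiples of bin_size
    means: np.ndarray       # mean probability per bin, in [0, 1]
    n_t_sites: np.ndarray   # sites contributing to each bin, >= 1
    bin_size: int = DEFAULT_BIN_SIZE


@dataclass
class RTProfile:
    """Genome-wide MBC profile on the fixed bin grid.

    ``data`` has columns (chrom, start, mbc, n_readbins); missing bins are
    absent rows, never zeros. ``scale`` is ``"raw"`` or ``"rescaled"``;
    ``rescale_params`` stores the raw values mapped to the low/high anchors.
    """

    data: pd.DataFrame
    bin_size: int = DEFAULT_BIN_SIZE
    scale: str = "raw"
    rescale_params: tuple[float, float] | None = None

    @property
    def values(self) -> pd.Series:
        return self.data["mbc"]

    def indexed(self) -> pd.Series:
        """MBC values indexed by (chrom, start), for bin-wise joins."""
        return self.data.set_index(["chrom", "start"])["mbc"]

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out["end"] = out["start"] + self.bin_size
        return out[["chrom", "start", "end", "mbc", "n_readbins"]]


def bin_read(record: ModReadRecord, bin_size: int = DEFAULT_BIN_SIZE) -> ReadBinnedTrack:
    """Average a read's per-thymidine probabilities in each grid bin.

    Bins with zero thymidine sites are omitted; partial-overlap bins keep
    whatever sites they contain.
    """
    if record.t_positions.size == 0:
        empty = np.empty(0)
        return ReadBinnedTrack(record.read_id, record.chrom, empty.astype(np.int64), empty, empty.astype(np.int64), bin_size)
    idx = record.t_positions // bin_size
    first = idx[0]
    rel = idx - first
    counts = np.bincount(rel)
    sums = np.bincount(rel, weights=record.t_probs)
    keep = counts > 0
    starts = ((first + np.flatnonzero(keep)) * bin_size).astype(np.int64)
    return ReadBinnedTrack(
        record.read_id, record.chrom, starts,
        sums[keep] / counts[keep], counts[keep].astype(np.int64), bin_size,
    )


def bin_reads(records: Iterable[ModReadRecord], bin_size: int = DEFAULT_BIN_SIZE) -> list[ReadBinnedTrack]:
    return [bin_read(r, bin_size) for r in records]


def is_parental(track: ReadBinnedTrack, threshold: float = BACKGROUND) -> bool:
    """True iff the read's median bin-level BrdU content is <= threshold,
    i.e. the molecule looks BrdU-free (parental DNA)."""
    if track.means.size == 0:
        raise ValueError(f"{track.read_id}: empty track")
    return bool(np.median(track.means) <= threshold)


def compute_profile(
    tracks: Iterable[ReadBinnedTrack],
    chrom_lengths: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    background: float = BACKGROUND,
    site_weighted: bool = False,
) -> RTProfile:
    """Aggregate read-level bins into a genomic MBC profile.

    Per genomic bin, the unweighted mean over all read-level bins whose mean
    BrdU signal is strictly above ``background`` (the bin-level filter also
    removes parental reads, so no separate read filter is applied). Set
    ``site_weighted`` to weight read-level bins by their thymidine counts
    instead. Bins with no surviving read-level bin are missing.
    """
    nbins = {c: -(-int(L) // bin_size) for c, L in chrom_lengths.items()}
    sums = {c: np.zeros(n) for c, n in nbins.items()}
    wts = {c: np.zeros(n) for c, n in nbins.items()}
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in nbins.items()}
    for tr in tracks:
        if tr.chrom not in sums:
            raise ValueError(f"track {tr.read_id} on unknown chromosome {tr.chrom!r}")
        keep = tr.means > background
        if not np.any(keep):
            continue
        idx = tr.bin_starts[keep] // bin_size
        w = tr.n_t_sites[keep].astype(float) if site_weighted else np.ones(keep.sum())
        np.add.at(sums[tr.chrom], idx, tr.means[keep] * w)
        np.add.at(wts[tr.chrom], idx, w)
        np.add.at(counts[tr.chrom], idx, 1)
    frames = []
    for chrom in chrom_lengths:
        defined = counts[chrom] > 0
        if not np.any(defined):
            continue
        idx = np.flatnonzero(defined)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": idx * bin_size,
            "mbc": sums[chrom][idx] / wts[chrom][idx],
            "n_readbins": counts[chrom][idx],
        }))
    if not frames:
        data = pd.DataFrame(columns=["chrom", "start", "mbc", "n_readbins"])
    else:
        data = pd.concat(frames, ignore_index=True)
    return RTProfile(data=data, bin_size=bin_size, scale="raw")


def rescale_values(values: np.ndarray | pd.Series, params: tuple[float, float],
                   lo: float = 1.0, hi: float = 2.0) -> np.ndarray | pd.Series:
    """Apply a stored rescaling (affine map sending params to (lo, hi))."""
    p_low, p_high = params
    return lo + (values - p_low) * (hi - lo) / (p_high - p_low)


def rescale_profile(
    profile: RTProfile,
    p_low: float = 0.5,
    p_high: float = 99.5,
    lo: float = 1.0,
    hi: float = 2.0,
) -> RTProfile:
    """Linearly rescale so the ``p_low``/``p_high`` percentiles of the value
    distribution map to ``lo``/``hi`` (default: 1 = end of S, 2 = start of S).

    Percentiles use linear interpolation between order statistics. Values in
    the percentile tails fall outside [lo, hi] and are not clipped. Raises on
    constant profiles, where the map is undefined.
    """
    vals = profile.values.to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least two defined bins to rescale")
    q_low, q_high = np.percentile(vals, [p_low, p_high])
    if q_high == q_low:
        raise ValueError("constant profile: rescaling map undefined")
    data = profile.data.copy()
    data["mbc"] = rescale_values(data["mbc"], (q_low, q_high), lo, hi)
    return RTProfile(data=data, bin_size=profile.bin_size, scale="rescaled",
                     rescale_params=(float(q_low), float(q_high)))


class ProfileComparison(NamedTuple):
    rho: float
    pvalue: float
    n: int
    slope: float | None = None
    intercept: float | None = None


def compare_profiles(
    a: RTProfile | pd.Series | Sequence[float],
    b: RTProfile | pd.Series | Sequence[float],
    fit_line: bool = False,
) -> ProfileComparison:
    """Spearman rank correlation between two profiles over pairwise-complete
    bins (average ranks for ties; two-sided p).

    Profiles are joined on (chrom, start); bare sequences are assumed already
    aligned. Rank correlation is invariant to rescaling of either input.
    Optionally returns an ordinary least-squares line as a presentation aid.
    """
    if isinstance(a, RTProfile) and isinstance(b, RTProfile):
        joined = pd.concat([a.indexed().rename("a"), b.indexed().rename("b")], axis=1, join="inner")
        x, y = joined["a"].to_numpy(float), joined["b"].to_numpy(float)
    else:
        x = np.asarray(a.values if isinstance(a, RTProfile) else a, dtype=float)
        y = np.asarray(b.values if isinstance(b, RTProfile) else b, dtype=float)
        if x.shape != y.shape:
            raise ValueError("aligned value arrays must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("fewer than 3 pairwise-complete bins")
    rho, p = stats.spearmanr(x, y)
    slope = intercept = None
    if fit_line:
        slope, intercept = np.polyfit(x, y, 1)
        slope, intercept = float(slope), float(intercept)
    return ProfileComparison(float(rho), float(p), int(x.size), slope, intercept)
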