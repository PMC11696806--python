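"""Telomeric repeat length and replication timing of individual telomeres.

Budding-yeast telomeres are 300 +/- 75 bp of degenerate TG(1-3) repeats
(C(1-3)A on the complementary strand). Reads whose primary alignment reaches
the terminal telomeric repeats of a chromosome end carry the molecule's own
repeat tract, partly aligned to the reference repeats and partly in the
outward soft clip. Candidate sequences are oriented centromere-to-telomere,
complemented to the G-rich strand, and filtered on composition in 50-nt
sliding windows: fraction of GG dinucleotides, summed GG+TG+GT fraction, and
mononucleotide Shannon entropy; a candidate passing in >= 90% of windows is
accepted and measured. Single-molecule telomere RT is the mean BrdU
probability in the 1 kb immediately internal to the terminal repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeAnnotation, ModReadRecord, revcomp
from .rt_profile import BACKGROUND, RTProfile, rescale_values

__all__ = [
    "WindowStats",
    "WindowCriteria",
    "TelomereCandidate",
    "TelomereMeasurement",
    "extract_candidate",
    "window_stats",
    "window_pass_fraction",
    "is_telomeric",
    "measure_length",
    "single_telomere_rt",
    "population_telomere_rt",
    "classify_end",
    "length_rt_correlation",
    "measure_telomeres",
    "SUBTELOMERE_WINDOW",
]

#: Chromosome-end neighbourhood (bp) within which a read can contribute.
SUBTELOMERE_WINDOW = 10_000


class WindowStats(NamedTuple):
    freqGG: float
    freqTelo: float
    H: float


@dataclass(frozen=True)
class WindowCriteria:
    """Acceptance bounds for 50-nt windows of candidate telomeric sequence."""

    window: int = 50
    step: int = 1
    freq_gg: tuple[float, float] = (0.05, 0.4)
    freq_telo: tuple[float, float] = (0.79, 1.0)
    entropy: tuple[float, float] = (0.85, 1.7)
    pass_fraction: float = 0.9


DEFAULT_CRITERIA = WindowCriteria()

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def window_stats(seq: str) -> WindowStats:
    """Composition statistics of one window.

    Dinucleotide fractions are over the len-1 overlapping pairs (non-ACGT
    symbols excluded from counts); H is the base-2 Shannon entropy of the
    mononucleotide frequencies. Windows with fewer than 2 valid symbols have
    undefined stats, returned as NaN.
    """
    codes = _encode(seq)
    valid = codes >= 0
    if valid.sum() < 2:
        return WindowStats(float("nan"), float("nan"), float("nan"))
    mono = np.bincount(codes[valid], minlength=4).astype(float)
    p = mono / mono.sum()
    nz = p > 0
    H = float(-(p[nz] * np.log2(p[nz])).sum())
    pair_ok = valid[:-1] & valid[1:]
    a, b = codes[:-1][pair_ok], codes[1:][pair_ok]
    npairs = a.size
    if npairs == 0:
        return WindowStats(0.0, 0.0, H)
    G, T = 2, 3
    gg = int(np.count_nonzero((a == G) & (b == G)))
    tg = int(np.count_nonzero((a == T) & (b == G)))
    gt = int(np.count_nonzero((a == G) & (b == T)))
    return WindowStats(gg / npairs, (gg + tg + gt) / npairs, H)


def _window_pass_matrix(seq: str, criteria: WindowCriteria) -> np.ndarray:
    """Boolean (n_windows, 3) matrix of per-window criterion outcomes.

    Vectorized sliding evaluation at step ``criteria.step``; sequences shorter
    than the window are evaluated in a single window holding all nucleotides.
    """
    w = criteria.window
    if len(seq) < w:
        st = window_stats(seq)
        row = np.array([[_within(st.freqGG, criteria.freq_gg),
                         _within(st.freqTelo, criteria.freq_telo),
                         _within(st.H, criteria.entropy)]])
        return row
    codes = _encode(seq)
    valid = (codes >= 0).astype(np.int64)
    n = len(codes)
    starts = np.arange(0, n - w + 1, criteria.step)

    def winsum(ind: np.ndarray, width: int) -> np.ndarray:
        cs = np.concatenate([[0], np.cumsum(ind)])
        return cs[starts + width] - cs[starts]

    # mononucleotide counts per window
    mono = np.stack([winsum((codes == i).astype(np.int64), w) for i in range(4)], axis=1).astype(float)
    tot = mono.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = mono / tot[:, None]
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        H = -(p * logp).sum(axis=1)
    # dinucleotide counts per window (w-1 pair slots per window)
    pair_valid = (valid[:-1] & valid[1:]).astype(np.int64)
    a, b = codes[:-1], codes[1:]
    G, T = 2, 3
    gg = ((a == G) & (b == G)).astype(np.int64)
    tg = ((a == T) & (b == G)).astype(np.int64)
    gt = ((a == G) & (b == T)).astype(np.int64)
    npairs = winsum(pair_valid, w - 1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fgg = winsum(gg, w - 1) / npairs
        ftel = (winsum(gg, w - 1) + winsum(tg, w - 1) + winsum(gt, w - 1)) / npairs
    defined = (tot >= 2) & (npairs > 0)
    out = np.zeros((starts.size, 3), dtype=bool)
    out[:, 0] = defined & (fgg >= criteria.freq_gg[0]) & (fgg <= criteria.freq_gg[1])
    out[:, 1] = defined & (ftel >= criteria.freq_telo[0]) & (ftel <= criteria.freq_telo[1])
    out[:, 2] = defined & (H >= criteria.entropy[0]) & (H <= criteria.entropy[1])
    return out


def _within(x: float, bounds: tuple[float, float]) -> bool:
    return bool(np.isfinite(x)) and bounds[0] <= x <= bounds[1]


def window_pass_fraction(seq: str, criteria: WindowCriteria = DEFAULT_CRITERIA) -> float:
    """Fraction of sliding windows meeting all three criteria."""
    m = _window_pass_matrix(seq, criteria)
    return float(m.all(axis=1).mean())


def is_telomeric(seq: str, criteria: WindowCriteria = DEFAULT_CRITERIA) -> bool:
    """Accept a candidate iff >= ``pass_fraction`` of its windows meet all
    three composition criteria."""
    if not seq:
        raise ValueError("empty candidate sequence")
    return window_pass_fraction(seq, criteria) >= criteria.pass_fraction


@dataclass
class TelomereCandidate:
    """An oriented (centromere-to-telomere, G-rich strand) candidate repeat
    sequence extracted from one read at one chromosome end."""

    end_id: str
    read_id: str
    seq: str
    read_length: int  # full read length in bp, clips included


def extract_candidate(
    record: ModReadRecord,
    annotation: GenomeAnnotation,
    subtelomere_window: int = SUBTELOMERE_WINDOW,
) -> TelomereCandidate | None:
    """Extract the telomere-facing candidate sequence of a read, if any.

    The candidate is the aligned sequence overlapping the terminal telomeric
    repeat interval plus the outward soft clip, oriented centromere to
    telomere and complemented to TG(1-3) if C-rich. Reads not reaching any
    annotated end's repeats-or-10-kb neighbourhood yield ``None``; a read can
    only measure the end its primary alignment overlaps.
    """
    if record.seq is None:
        raise ValueError(f"{record.read_id}: sequence required to extract a telomere candidate")
    for end_id, chrom, side, t_start, t_end in annotation.ends():
        if chrom != record.chrom:
            continue
        if side == "L":
            if record.ref_start > t_end + subtelomere_window:
                continue
            aligned_part = record.seq[: max(0, t_end - record.ref_start)]
            cand_fwd = record.left_clip_seq + aligned_part
            cand = revcomp(cand_fwd)  # centromere -> telomere reads right-to-left
        else:
            if record.ref_end < t_start - subtelomere_window:
                continue
            off = t_start - record.ref_start
            aligned_part = record.seq[max(0, off):]
            cand = aligned_part + record.right_clip_seq
        if not cand:
            continue
        # complement C-rich candidates onto the G-rich strand
        if cand.count("C") > cand.count("G"):
            cand = revcomp(cand)
        return TelomereCandidate(end_id, record.read_id, cand, record.total_length)
    return None


def measure_length(
    candidate: TelomereCandidate | str,
    criteria: WindowCriteria = DEFAULT_CRITERIA,
) -> int | None:
    """Telomeric-repeat length (bp) of an accepted candidate, or None.

    The measured extent trims leading/trailing windows that fail all three
    criteria (non-telomeric flanks); interior windows never trim.
    """
    seq = candidate.seq if isinstance(candidate, TelomereCandidate) else candidate
    if not seq:
        return None
    m = _window_pass_matrix(seq, criteria)
    if m.all(axis=1).mean() < criteria.pass_fraction:
        return None
    some = m.any(axis=1)
    if not some.any():
        return None
    w = min(criteria.window, len(seq))
    first = int(np.argmax(some))
    last = int(len(some) - 1 - np.argmax(some[::-1]))
    return (last * criteria.step + w) - first * criteria.step


def single_telomere_rt(
    record: ModReadRecord,
    annotation: GenomeAnnotation,
    rescale_params: tuple[float, float] | None = None,
    min_read_len: int = 5000,
    rt_floor: float = BACKGROUND,
) -> tuple[str, float, float | None] | None:
    """Single-molecule telomere RT: mean BrdU probability over the thymidine
    sites of the fixed 1 kb genomic window immediately internal to the
    terminal telomeric repeats.

    Returns (end_id, raw, rescaled) or ``None`` when the read covers no such
    window. Reads shorter than ``min_read_len`` or with raw RT at or below the
    detection background are filtered (raw reported, rescaled ``None``) —
    these are excluded from length/RT correlations.
    """
    for end_id, chrom, side, t_start, t_end in annotation.ends():
        if chrom != record.chrom:
            continue
        win = (t_end, t_end + 1000) if side == "L" else (t_start - 1000, t_start)
        sel = (record.t_positions >= win[0]) & (record.t_positions < win[1])
        if not np.any(sel):
            continue
        raw = float(record.t_probs[sel].mean())
        passed = record.total_length > min_read_len and raw > rt_floor
        rescaled = None
        if passed and rescale_params is not None:
            rescaled = float(rescale_values(np.array([raw]), rescale_params)[0])
        return end_id, raw, (rescaled if passed else None)
    return None


def population_telomere_rt(
    profile: RTProfile,
    annotation: GenomeAnnotation,
    end_id: str,
    two_bin: bool = True,
) -> float:
    """Population RT of one chromosome end from a rescaled profile.

    Overlap-weighted mean of the (at most two) grid bins covering the 1 kb
    window adjacent to the terminal repeats; with ``two_bin=False`` only the
    single terminal-most fully-interior bin is used (figure-legend variant).
    Returns NaN if every overlapping bin is missing.
    """
    chrom, side, t_start, t_end = annotation.end(end_id)
    bs = profile.bin_size
    win = (t_end, t_end + bs) if side == "L" else (t_start - bs, t_start)
    series = profile.indexed()
    if not two_bin:
        start = (win[0] // bs) * bs if side == "L" else ((win[1] - 1) // bs) * bs
        return float(series.get((chrom, int(start)), np.nan))
    vals, weights = [], []
    for bstart in range((win[0] // bs) * bs, win[1], bs):
        overlap = min(win[1], bstart + bs) - max(win[0], bstart)
        if overlap <= 0:
            continue
        v = series.get((chrom, int(bstart)), np.nan)
        if np.isfinite(v):
            vals.append(float(v))
            weights.append(overlap)
    if not vals:
        return float("nan")
    return float(np.average(vals, weights=weights))


def classify_end(annotation: GenomeAnnotation, end_id: str, threshold: int = 20_000) -> str:
    """Classify a chromosome end as ``"X"`` or ``"XY'"``.

    XY' iff the gap between the end's X element and the closest Y' element on
    the same chromosome arm is below ``threshold``; restricting to the same
    arm prevents wrong assignments when both arms of a chromosome carry Y'
    elements. Pure function of the annotation. Raises if the end has no X
    element annotated.
    """
    chrom, side, t_start, t_end = annotation.end(end_id)
    cen = annotation.centromeres[annotation.centromeres["chrom"] == chrom]
    cen_mid = float(cen[["start", "end"]].mean(axis=1).iloc[0]) if len(cen) else annotation.chrom_lengths[chrom] / 2

    def on_arm(df: pd.DataFrame) -> pd.DataFrame:
        mids = (df["start"] + df["end"]) / 2
        return df[(df["chrom"] == chrom) & ((mids < cen_mid) if side == "L" else (mids > cen_mid))]

    xs = on_arm(annotation.x_elements)
    if xs.empty:
        raise ValueError(f"{end_id}: no X element annotated on this arm")
    # the end's X element: the arm's X closest to the chromosome end
    key = xs["start"] if side == "L" else -xs["end"]
    x = xs.loc[key.idxmin()]
    ys = on_arm(annotation.y_elements)
    if ys.empty:
        return "X"
    gaps = np.maximum(ys["start"] - x["end"], x["start"] - ys["end"]).clip(lower=0)
    return "XY'" if float(gaps.min()) < threshold else "X"


def length_rt_correlation(lengths: Iterable[float], rts: Iterable[float]) -> tuple[float, float]:
    """Two-sided Spearman correlation between telomeric repeat length and
    single-molecule RT (average ranks for ties). Returns (rho, p)."""
    x = np.asarray(list(lengths), dtype=float)
    y = np.asarray(list(rts), dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 paired measurements")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


@dataclass
class TelomereMeasurement:
    end_id: str
    read_id: str
    repeat_length: int | None
    passed_filters: bool
    single_rt_raw: float | None
    single_rt_rescaled: float | None
    telomere_class: str


def measure_telomeres(
    records: Iterable[ModReadRecord],
    annotation: GenomeAnnotation,
    rescale_params: tuple[float, float] | None = None,
    criteria: WindowCriteria = DEFAULT_CRITERIA,
    min_read_len: int = 5000,
    rt_floor: float = BACKGROUND,
) -> pd.DataFrame:
    """Run the full per-molecule telomere pipeline over a read set.

    Returns one row per read-end contact: measured repeat length (NaN when
    the candidate is rejected), raw and rescaled single-molecule RT (rescaled
    NaN when the >5 kb / >background filters fail), and the end's X / XY'
    class where classifiable.
    """
    classes: dict[str, str] = {}
    for end_id, *_ in annotation.ends():
        try:
            classes[end_id] = classify_end(annotation, end_id)
        except ValueError:
            classes[end_id] = ""
    rows = []
    for rec in records:
        cand = extract_candidate(rec, annotation)
        rt = single_telomere_rt(rec, annotation, rescale_params, min_read_len, rt_floor)
        if cand is None and rt is None:
            continue
        end_id = cand.end_id if cand is not None else rt[0]
        length = measure_length(cand, criteria) if cand is not None else None
        raw = rt[1] if rt is not None else None
        rescaled = rt[2] if rt is not None else None
        rows.append({
            "end_id": end_id,
            "read_id": rec.read_id,
            "repeat_length": length,
            "passed_filters": rescaled is not None,
            "single_rt_raw": raw,
            "single_rt_rescaled": rescaled,
            "telomere_class": classes.get(end_id, ""),
        })
    return pd.DataFrame(rows, columns=[
        "end_id", "read_id", "repeat_length", "passed_filters",
        "single_rt_raw", "single_rt_rescaled", "telomere_class",
    ])
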