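"""Readers and writers for the external formats the pipeline touches.

Modified-base BAM (MM/ML tags), bedGraph signal tracks, BED annotations and
tabular truth files. All genomic coordinates are 0-based half-open; 1-based
numbers appear only in presentation layers. Per-thymidine BrdU probabilities
are stored in BAM as 8-bit integers; byte ``k`` decodes to the quantization-bin
midpoint ``(k + 0.5) / 256`` and probability ``p`` encodes to
``min(floor(p * 256), 255)``, so a round trip is exact to within 1/256.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ModReadRecord",
    "GenomeAnnotation",
    "decode_ml",
    "encode_ml",
    "read_modbam",
    "write_modbam",
    "read_bedgraph",
    "write_bedgraph",
    "read_annotation",
    "write_annotation",
    "write_fasta",
    "revcomp",
    "MOD_CODE",
]

#: SAM base-modification code used for BrdU on thymidine ("T+B").
MOD_CODE = "B"

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def decode_ml(k: np.ndarray | int) -> np.ndarray | float:
    """Decode 8-bit ML byte(s) to probability bin midpoints (k + 0.5) / 256."""
    return (np.asarray(k, dtype=float) + 0.5) / 256.0


def encode_ml(p: np.ndarray | float) -> np.ndarray:
    """Encode probabilities in [0, 1] to 8-bit ML bytes, clamped to 255."""
    arr = np.floor(np.asarray(p, dtype=float) * 256.0).astype(np.int64)
    return np.clip(arr, 0, 255).astype(np.uint8)


@dataclass
class ModReadRecord:
    """One primary-aligned read with per-thymidine BrdU probabilities.

    ``t_positions`` are reference forward-strand coordinates of the aligned
    thymidine sites of the read's template strand (for a ``-`` read these are
    ``A`` positions on the reference forward strand). ``seq`` is the aligned
    portion of the read in forward-genome orientation; clip sequences are also
    kept in forward-genome orientation, ``left_clip_seq`` on the genomic-left
    end (this matches how BAM stores SEQ for both strands).
    """

    read_id: str
    chrom: str
    ref_start: int
    strand: str
    t_positions: np.ndarray
    t_probs: np.ndarray
    left_clip_seq: str = ""
    right_clip_seq: str = ""
    aligned_len: int = 0
    seq: str | None = None

    def __post_init__(self) -> None:
        self.t_positions = np.asarray(self.t_positions, dtype=np.int64)
        self.t_probs = np.asarray(self.t_probs, dtype=float)
        if self.t_positions.shape != self.t_probs.shape:
            raise ValueError(f"{self.read_id}: t_positions/t_probs length mismatch")
        if self.t_positions.size and np.any(np.diff(self.t_positions) <= 0):
            raise ValueError(f"{self.read_id}: t_positions not strictly increasing")
        if self.t_probs.size and (self.t_probs.min() < 0 or self.t_probs.max() > 1):
            raise ValueError(f"{self.read_id}: probabilities outside [0, 1]")
        if self.ref_start < 0:
            raise ValueError(f"{self.read_id}: negative ref_start")
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: strand must be '+' or '-'")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.aligned_len

    @property
    def total_length(self) -> int:
        """Full read length in bp, soft clips included."""
        return self.aligned_len + len(self.left_clip_seq) + len(self.right_clip_seq)


def _template_base(strand: str) -> str:
    # thymidines of a '-' molecule sit at forward-strand 'A's
    return "T" if strand == "+" else "A"


def _forward_query(record: ModReadRecord) -> str:
    if record.seq is None:
        raise ValueError(f"{record.read_id}: record has no sequence")
    if len(record.seq) != record.aligned_len:
        raise ValueError(f"{record.read_id}: seq length != aligned_len")
    return record.left_clip_seq + record.seq + record.right_clip_seq


def _placeholder_seq(record: ModReadRecord) -> str:
    """Aligned-portion sequence with the template base at the annotated sites
    and 'C' elsewhere; used only when a record carries no sequence."""
    base = _template_base(record.strand)
    arr = np.full(record.aligned_len, ord("C"), dtype=np.uint8)
    arr[record.t_positions - record.ref_start] = ord(base)
    return arr.tobytes().decode()


def _mm_ml_tags(record: ModReadRecord, query: str) -> tuple[str, list[int]]:
    """Compose MM/ML for the stored (forward-orientation) query.

    MM deltas refer to the original basecalled read: for '+' reads that is the
    stored query left to right; for '-' reads it is the reverse complement, so
    template thymidines are the stored 'A's counted right to left.
    """
    lc = len(record.left_clip_seq)
    qpos = lc + (record.t_positions - record.ref_start)
    base = _template_base(record.strand)
    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    base_sites = np.flatnonzero(qarr == ord(base))
    if record.strand == "-":
        base_sites = base_sites[::-1]
        qpos = qpos[::-1]
        probs = record.t_probs[::-1]
    else:
        probs = record.t_probs
    ranks = np.searchsorted(base_sites, qpos) if record.strand == "+" else None
    if record.strand == "-":
        # base_sites descending: rank by position from the right end
        ranks = len(base_sites) - 1 - np.searchsorted(base_sites[::-1], qpos)
    if qpos.size and not np.all(base_sites[ranks] == qpos):
        raise ValueError(f"{record.read_id}: annotated site is not a template thymidine")
    deltas = np.diff(np.concatenate([[-1], ranks])) - 1
    mm = f"T+{MOD_CODE}?," + ",".join(map(str, deltas)) + ";" if qpos.size else f"T+{MOD_CODE}?;"
    ml = encode_ml(probs).tolist()
    return mm, ml


def write_modbam(
    records: Iterable[ModReadRecord],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
    genome: Mapping[str, str] | None = None,
) -> None:
    """Write records to a modified-base BAM.

    Records lacking a sequence get one from ``genome`` (reference slice) or,
    failing that, a placeholder with the template base at annotated sites only.
    Output order follows input order, so byte content is deterministic.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for rec in records:
            if rec.chrom not in tid:
                raise ValueError(f"{rec.read_id}: chromosome {rec.chrom!r} absent from header")
            if rec.seq is None and genome is not None:
                rec = ModReadRecord(
                    rec.read_id, rec.chrom, rec.ref_start, rec.strand,
                    rec.t_positions, rec.t_probs, rec.left_clip_seq,
                    rec.right_clip_seq, rec.aligned_len,
                    genome[rec.chrom][rec.ref_start:rec.ref_end],
                )
            query = _forward_query(rec) if rec.seq is not None else (
                rec.left_clip_seq + _placeholder_seq(rec) + rec.right_clip_seq
            )
            mm, ml = _mm_ml_tags(
                rec if rec.seq is not None else ModReadRecord(
                    rec.read_id, rec.chrom, rec.ref_start, rec.strand,
                    rec.t_positions, rec.t_probs, rec.left_clip_seq,
                    rec.right_clip_seq, rec.aligned_len, None),
                query,
            )
            a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
            a.query_name = rec.read_id
            a.reference_id = tid[rec.chrom]
            a.reference_start = rec.ref_start
            a.flag = 16 if rec.strand == "-" else 0
            a.mapping_quality = 60
            a.query_sequence = query
            lc, rc = len(rec.left_clip_seq), len(rec.right_clip_seq)
            cigar = ""
            if lc:
                cigar += f"{lc}S"
            cigar += f"{rec.aligned_len}M"
            if rc:
                cigar += f"{rc}S"
            a.cigarstring = cigar
            a.set_tag("MM", mm)
            if ml:
                a.set_tag("ML", ml)
            bam.write(a)


def read_modbam(
    path: str | Path,
    mod_code: str = MOD_CODE,
    keep_sequence: bool = True,
) -> Iterator[ModReadRecord]:
    """Stream primary-aligned reads from a modified-base BAM.

    Secondary, supplementary and unmapped alignments are skipped. Reads
    without MM/ML tags for ``mod_code`` are skipped with a warning; malformed
    tags raise, naming the read. Reads with zero annotated thymidines in the
    aligned span yield records with empty ``t_positions``.
    """
    skipped = 0
    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.has_tag("MM"):
                skipped += 1
                continue
            try:
                mods = aln.modified_bases or {}
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"malformed MM/ML tag on read {aln.query_name}") from exc
            sites: list[tuple[int, int]] = []
            for (canon, _strand, code), lst in mods.items():
                if canon == "T" and code == mod_code:
                    sites.extend(lst)
            if not sites and f"+{mod_code}" not in str(aln.get_tag("MM")):
                skipped += 1
                continue
            qual_by_qpos = dict(sites)
            q2r = dict(aln.get_aligned_pairs(matches_only=True))
            pos, probs = [], []
            for qpos, qual in sorted(qual_by_qpos.items()):
                rpos = q2r.get(qpos)
                if rpos is not None:
                    pos.append(rpos)
                    probs.append(qual)
            order = np.argsort(pos, kind="stable")
            pos_arr = np.asarray(pos, dtype=np.int64)[order]
            prob_arr = decode_ml(np.asarray(probs, dtype=np.int64)[order]) if len(pos) else np.empty(0)
            cig = aln.cigartuples or []
            lc = cig[0][1] if cig and cig[0][0] == 4 else 0
            rc = cig[-1][1] if len(cig) > 1 and cig[-1][0] == 4 else 0
            query = aln.query_sequence or ""
            aligned_len = aln.reference_end - aln.reference_start
            yield ModReadRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                ref_start=aln.reference_start,
                strand="-" if aln.is_reverse else "+",
                t_positions=pos_arr,
                t_probs=prob_arr,
                left_clip_seq=query[:lc] if lc else "",
                right_clip_seq=query[len(query) - rc:] if rc else "",
                aligned_len=aligned_len,
                seq=(query[lc:len(query) - rc if rc else None] if keep_sequence and query else None),
            )
    if skipped:
        warnings.warn(f"{skipped} read(s) without {mod_code} modification tags were skipped")


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(df: pd.DataFrame, path: str | Path, value_col: str = "value") -> None:
    """Write a 4-column bedGraph (chrom, start, end, value), sorted by
    (chrom, start), values formatted to 6 decimals. Missing bins are simply
    absent lines, never zeros."""
    out = df.loc[:, ["chrom", "start", "end", value_col]].copy()
    out = out.dropna(subset=[value_col]).sort_values(["chrom", "start"], kind="mergesort")
    out[value_col] = out[value_col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into a (chrom, start, end, value) frame, sorted.

    Raises on overlapping intervals within a chromosome.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#", dtype={"chrom": str},
    )
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom", sort=False):
        if np.any(grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]):
            raise ValueError(f"overlapping intervals on {chrom} in {path}")
    return df


# ---------------------------------------------------------------------------
# Annotation


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus interval sets for the pipeline's landmarks.

    Interval frames have columns (chrom, start, end, name); terminal telomeric
    repeat intervals must touch a chromosome end.
    """

    chrom_lengths: dict[str, int]
    telomere_repeats: pd.DataFrame
    x_elements: pd.DataFrame = field(default_factory=lambda: _empty_bed())
    y_elements: pd.DataFrame = field(default_factory=lambda: _empty_bed())
    origins: pd.DataFrame = field(default_factory=lambda: _empty_bed())
    centromeres: pd.DataFrame = field(default_factory=lambda: _empty_bed())

    def __post_init__(self) -> None:
        for attr in ("telomere_repeats", "x_elements", "y_elements", "origins", "centromeres"):
            df = getattr(self, attr)
            for _, row in df.iterrows():
                L = self.chrom_lengths.get(row["chrom"])
                if L is None:
                    raise ValueError(f"{attr}: unknown chromosome {row['chrom']!r}")
                if not (0 <= row["start"] < row["end"] <= L):
                    raise ValueError(
                        f"{attr}: interval {row['chrom']}:{row['start']}-{row['end']} "
                        f"outside chromosome bounds (length {L})"
                    )
        for _, row in self.telomere_repeats.iterrows():
            L = self.chrom_lengths[row["chrom"]]
            if row["start"] != 0 and row["end"] != L:
                raise ValueError(
                    f"telomere interval {row['chrom']}:{row['start']}-{row['end']} "
                    "does not touch a chromosome end (wrong coordinate convention?)"
                )

    def ends(self) -> list[tuple[str, str, str, int, int]]:
        """All annotated chromosome ends as (end_id, chrom, side, start, end),
        sorted; ``end_id`` is e.g. ``chrI_L``."""
        out = []
        for _, row in self.telomere_repeats.iterrows():
            side = "L" if row["start"] == 0 else "R"
            out.append((f"{row['chrom']}_{side}", row["chrom"], side, int(row["start"]), int(row["end"])))
        return sorted(out)

    def end(self, end_id: str) -> tuple[str, str, int, int]:
        for eid, chrom, side, start, end in self.ends():
            if eid == end_id:
                return chrom, side, start, end
        raise KeyError(f"unknown chromosome end {end_id!r}")


def _empty_bed() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "name"])


def _read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return _empty_bed()
    df = df.iloc[:, : min(4, df.shape[1])]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = [f"feat{i}" for i in range(len(df))]
    return df


def read_annotation(
    chrom_sizes: str | Path,
    telomere_repeats: str | Path,
    x_elements: str | Path | None = None,
    y_elements: str | Path | None = None,
    origins: str | Path | None = None,
    centromeres: str | Path | None = None,
) -> GenomeAnnotation:
    """Load an annotation from a chrom-sizes TSV plus one BED per class."""
    sizes = pd.read_csv(chrom_sizes, sep="\t", header=None, names=["chrom", "length"], dtype={"chrom": str})
    lengths = dict(zip(sizes["chrom"], sizes["length"].astype(int)))

    def load(p):
        return _read_bed(p) if p is not None else _empty_bed()

    return GenomeAnnotation(
        chrom_lengths=lengths,
        telomere_repeats=_read_bed(telomere_repeats),
        x_elements=load(x_elements),
        y_elements=load(y_elements),
        origins=load(origins),
        centromeres=load(centromeres),
    )


def read_annotation_dir(directory: str | Path) -> GenomeAnnotation:
    """Load an annotation from a directory laid out by ``write_annotation``."""
    d = Path(directory)
    opt = lambda n: d / n if (d / n).exists() else None
    return read_annotation(
        d / "chrom.sizes", d / "telomere_repeats.bed",
        opt("x_elements.bed"), opt("y_elements.bed"),
        opt("origins.bed"), opt("centromeres.bed"),
    )


def write_annotation(ann: GenomeAnnotation, directory: str | Path) -> None:
    """Write an annotation as chrom.sizes plus one BED file per class."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ann.chrom_lengths.items()).to_csv(d / "chrom.sizes", sep="\t", header=False, index=False)
    for attr in ("telomere_repeats", "x_elements", "y_elements", "origins", "centromeres"):
        df = getattr(ann, attr)
        df.loc[:, ["chrom", "start", "end", "name"]].sort_values(["chrom", "start"]).to_csv(
            d / f"{attr}.bed", sep="\t", header=False, index=False
        )


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Plain-text FASTA writer with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
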