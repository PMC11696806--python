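"""Synthetic-data generator for the full pipeline.

Builds a toy budding-yeast-like genome (random sequence, terminal TG(1-3)
repeats, X/Y' subtelomeric elements with late-firing origins, chromosome-
internal origins) with a deterministic replication-time landscape
t_rep(x) = min over origins of (firing_time + distance / fork_speed), then
draws nanopore-like molecules from an asynchronous population labelled with
BrdU for exactly one doubling time.

Population model. Each molecule comes from a cell at a uniform random cycle
position t0 at label addition. A locus replicating at cycle time u has, at
harvest, parental strands (never labelled), first-round nascent strands
(labelled only where u >= t0, i.e. synthesized after label addition; a read
crossing u = t0 is a "mixed" molecule with an instantaneous transition at the
label-start fork position) and, where u < t0, second-round nascent strands
synthesized inside the label window (labelled, truncated at the label-end
fork position). Strand-copy multiplicities (2:2:4 where the locus
pre-replicated, 2:2 otherwise, evaluated at the read midpoint) make half of
all molecules BrdU-free, matching the roughly-half BrdU-free read bins seen
in real labelling experiments. Labelled thymidine sites incorporate BrdU with
probability MBC(s) = B / (B + T0 * fold**s), the pool-competition model with
exponentially expanding dTTP; reported per-site probabilities add basecaller
noise drawn from two Beta distributions (incorporated sites: mean 0.98;
everything else: mean 0.005, keeping parental 1-kb bin means safely below the
0.02 detection background, as for real parental reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, ModReadRecord, revcomp, write_annotation, write_fasta, write_modbam
from .rt_profile import DEFAULT_BIN_SIZE, ReadBinnedTrack, bin_read

__all__ = [
    "SimConfig",
    "SimGenome",
    "SimReads",
    "build_genome",
    "simulate_population_reads",
    "simulate_telomere_cohort",
    "simulate_to_dir",
]


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate the standard labelling study.

    dTTP kinetics: T0 = 12 uM at S start with an 8-fold rise across S; BrdU
    dose B = 5 uM. Doubling time 90 min with S phase starting at 35 min and
    lasting ~25 min (set by the origin layout). Reads are log-normal with a
    20 kb median; 60,000 of them cover the 12 Mb genome ~100x (~1.3 Gb).
    Telomeres are Normal(300, 75) bp truncated at 50.
    """

    n_chrom: int = 4
    chrom_length: int = 3_000_000
    bin_size: int = DEFAULT_BIN_SIZE
    # replication landscape
    fork_speed: float = 1600.0          # bp/min
    origin_spacing: float = 40_000.0    # mean inter-origin distance, bp
    origin_jitter: float = 8_000.0      # uniform jitter on spacing, bp
    internal_firing: tuple[float, float] = (2.0, 14.0)   # min into S
    subtel_firing: tuple[float, float] = (18.0, 24.0)    # min into S
    # cell cycle
    cycle_min: float = 90.0
    s_start_min: float = 35.0
    # pools
    T0: float = 12.0       # uM dTTP at S start
    fold: float = 8.0      # T(1)/T(0)
    brdu_dose: float = 5.0  # uM, B
    # reads
    read_length_median: float = 20_000.0
    read_length_sigma: float = 0.45     # sigma of log read length
    read_min_length: int = 1000
    n_reads: int = 60_000
    # basecaller noise (Beta(a, b) for reported per-site probabilities)
    hi_beta: tuple[float, float] = (24.5, 0.5)   # incorporated sites, mean 0.98
    bg_beta: tuple[float, float] = (0.05, 9.95)  # background sites, mean 0.005
    noise: bool = True
    background: float = 0.02            # detection-background threshold
    # subtelomere architecture
    tel_mean: float = 300.0
    tel_sd: float = 75.0
    tel_min: float = 50.0
    x_len: int = 1500
    y_len: int = 5200
    y_prime_fraction: float = 0.5       # fraction of ends carrying a Y' element
    seed: int = 0


@dataclass
class SimGenome:
    """Toy genome with annotation and per-bin replication-time ground truth."""

    config: SimConfig
    sequences: dict[str, str]
    annotation: GenomeAnnotation
    truth_bins: pd.DataFrame            # chrom, start, t_rep (min into S), s in [0,1]
    t_rep: dict[str, np.ndarray]        # per-bin replication time
    s_max: float
    origin_firing: pd.DataFrame | None = None  # chrom, start, firing_min
    t_sites: dict[str, np.ndarray] = field(repr=False, default_factory=dict)  # fwd 'T'
    a_sites: dict[str, np.ndarray] = field(repr=False, default_factory=dict)  # fwd 'A'

    def s_of(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Normalized S-progression of positions (via their 1 kb bin)."""
        return self.t_rep[chrom][positions // self.config.bin_size] / self.s_max


#: G-run length distribution of simulated TG(1-3) repeats. Weighted toward
#: single and double G so that dinucleotide (GG ~ 0.27 of pairs) and entropy
#: statistics fall where real budding-yeast telomeric tracts sit; an even mix
#: would be unrealistically G-heavy.
_G_RUN_P = (0.45, 0.35, 0.20)


def _tg_run(rng: np.random.Generator, length: int) -> str:
    """Degenerate TG(1-3) repeat string of exactly ``length`` bp (G-rich)."""
    if length <= 0:
        return ""
    ks = rng.choice([1, 2, 3], size=length, p=_G_RUN_P)  # ample units
    parts = []
    total = 0
    for k in ks:
        parts.append("T" + "G" * int(k))
        total += 1 + int(k)
        if total >= length:
            break
    return "".join(parts)[:length]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = out < lower
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < lower
    return out


def build_genome(config: SimConfig, seed: int | None = None) -> SimGenome:
    """Construct sequence, annotation and replication-time truth.

    Every end carries an X element; a configured subset additionally carries
    a Y' element between the terminal repeats and the X; X and Y' elements
    each contain a late-firing origin, so chromosome ends replicate late, as
    in vivo. t_rep per bin is the lower envelope of one V shape per origin.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = config.chrom_length
    chroms = [f"chr{'I' * (i + 1)}" if i < 3 else "chrIV" for i in range(config.n_chrom)]
    if config.n_chrom > 4:
        chroms = [f"chr{i+1:02d}" for i in range(config.n_chrom)]

    n_ends = 2 * config.n_chrom
    n_y = int(round(config.y_prime_fraction * n_ends))
    y_ends = set(rng.choice(n_ends, size=n_y, replace=False).tolist())

    sequences: dict[str, str] = {}
    tel_rows, x_rows, y_rows, ori_rows, cen_rows = [], [], [], [], []
    bases = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)
    end_idx = 0
    for chrom in chroms:
        seq = bases[rng.integers(0, 4, size=L)].tobytes().decode()
        tel_len = _truncated_normal(rng, config.tel_mean, config.tel_sd, config.tel_min, 2).astype(int)
        left_run = _tg_run(rng, int(tel_len[0]))
        right_run = _tg_run(rng, int(tel_len[1]))
        seq = revcomp(left_run) + seq[len(left_run): L - len(right_run)] + right_run
        sequences[chrom] = seq
        for side, tlen in (("L", int(tel_len[0])), ("R", int(tel_len[1]))):
            has_y = end_idx in y_ends
            if side == "L":
                tel = (0, tlen)
                cursor = tlen
                if has_y:
                    y_rows.append((chrom, cursor, cursor + config.y_len, f"Y'_{chrom}_{side}"))
                    ori_rows.append((chrom, cursor + config.y_len // 2, "subtel"))
                    cursor += config.y_len + 300
                x_rows.append((chrom, cursor, cursor + config.x_len, f"X_{chrom}_{side}"))
                ori_rows.append((chrom, cursor + config.x_len // 2, "subtel"))
            else:
                tel = (L - tlen, L)
                cursor = L - tlen
                if has_y:
                    y_rows.append((chrom, cursor - config.y_len, cursor, f"Y'_{chrom}_{side}"))
                    ori_rows.append((chrom, cursor - config.y_len // 2, "subtel"))
                    cursor -= config.y_len + 300
                x_rows.append((chrom, cursor - config.x_len, cursor, f"X_{chrom}_{side}"))
                ori_rows.append((chrom, cursor - config.x_len // 2, "subtel"))
            tel_rows.append((chrom, tel[0], tel[1], f"TEL_{chrom}_{side}"))
            end_idx += 1
        cen_mid = L // 2 + int(rng.integers(-50_000, 50_000))
        cen_rows.append((chrom, cen_mid - 60, cen_mid + 60, f"CEN_{chrom}"))
        # chromosome-internal origins
        pos = 25_000.0 + rng.uniform(0, config.origin_spacing)
        while pos < L - 25_000:
            ori_rows.append((chrom, int(pos), "internal"))
            pos += config.origin_spacing + rng.uniform(-config.origin_jitter, config.origin_jitter)

    origins = pd.DataFrame(
        [(c, p, p + 1, f"ARS_{c}_{p}") for c, p, kind in ori_rows], columns=["chrom", "start", "end", "name"]
    )
    firing = np.where(
        [kind == "subtel" for _, _, kind in ori_rows],
        rng.uniform(*config.subtel_firing, size=len(ori_rows)),
        rng.uniform(*config.internal_firing, size=len(ori_rows)),
    )
    origins["firing_min"] = firing
    for _, row in origins.iterrows():
        if not (0 <= row["start"] < L):
            raise ValueError(f"origin {row['name']} outside chromosome")

    annotation = GenomeAnnotation(
        chrom_lengths={c: L for c in chroms},
        telomere_repeats=pd.DataFrame(tel_rows, columns=["chrom", "start", "end", "name"]),
        x_elements=pd.DataFrame(x_rows, columns=["chrom", "start", "end", "name"]),
        y_elements=pd.DataFrame(y_rows, columns=["chrom", "start", "end", "name"]),
        origins=origins[["chrom", "start", "end", "name"]],
        centromeres=pd.DataFrame(cen_rows, columns=["chrom", "start", "end", "name"]),
    )

    bs = config.bin_size
    t_rep: dict[str, np.ndarray] = {}
    rows = []
    for chrom in chroms:
        ori = origins[origins["chrom"] == chrom]["start"].to_numpy(float)
        fire = firing[(origins["chrom"] == chrom).to_numpy()]
        nbins = -(-L // bs)
        centers = np.minimum(np.arange(nbins) * bs + bs / 2, L - 0.5)
        t = np.min(fire[None, :] + np.abs(centers[:, None] - ori[None, :]) / config.fork_speed, axis=1)
        t_rep[chrom] = t
        rows.append(pd.DataFrame({"chrom": chrom, "start": np.arange(nbins) * bs, "t_rep": t}))
    truth = pd.concat(rows, ignore_index=True)
    s_max = float(truth["t_rep"].max())
    truth["s"] = truth["t_rep"] / s_max

    genome = SimGenome(
        config=config, sequences=sequences, annotation=annotation,
        truth_bins=truth, t_rep=t_rep, s_max=s_max,
        origin_firing=origins.assign(firing_min=firing)[["chrom", "start", "firing_min"]],
    )
    for chrom in chroms:
        arr = np.frombuffer(sequences[chrom].encode(), dtype=np.uint8)
        genome.t_sites[chrom] = np.flatnonzero(arr == ord("T")).astype(np.int64)
        genome.a_sites[chrom] = np.flatnonzero(arr == ord("A")).astype(np.int64)
    return genome


@dataclass
class SimReads:
    """Output of a population simulation: light per-read tracks, truth, and
    (for small runs) the full records."""

    tracks: list[ReadBinnedTrack]
    truth_reads: pd.DataFrame
    records: list[ModReadRecord] | None = None
    site_truth: dict[str, pd.DataFrame] | None = None


def _site_probs(
    rng: np.random.Generator,
    labelled: np.ndarray,
    mbc: np.ndarray,
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """(reported per-site probabilities, per-site incorporation truth).

    With noise on, labelled sites incorporate BrdU by a Bernoulli draw at the
    pool-model probability and the basecaller reports Beta-distributed values
    (high for incorporated, background otherwise). With noise off the report
    is the exact incorporation probability itself (0 on unlabelled sites), so
    closed-form oracles hold bit-exactly.
    """
    if not config.noise:
        probs = np.where(labelled, mbc, 0.0)
        return probs, labelled.copy()
    incorporated = labelled & (rng.random(labelled.size) < mbc)
    probs = rng.beta(*config.bg_beta, size=labelled.size)
    n_hi = int(incorporated.sum())
    if n_hi:
        probs[incorporated] = rng.beta(*config.hi_beta, size=n_hi)
    return probs, incorporated


def _mbc_of_s(s: np.ndarray, config: SimConfig) -> np.ndarray:
    T = config.T0 * config.fold ** s
    return config.brdu_dose / (config.brdu_dose + T)


def simulate_population_reads(
    genome: SimGenome,
    seed: int,
    n_reads: int | None = None,
    keep_records: bool = False,
    store_site_truth: bool = False,
    with_sequence: bool = False,
) -> SimReads:
    """Draw a BrdU-labelled asynchronous population of nanopore-like reads.

    Deterministic given (genome, seed). Records are kept only on request:
    at the default 60k-read scale the per-site arrays are large, while the
    binned tracks carry everything the profile pipeline needs. Per-site truth
    tables are likewise opt-in for small runs.
    """
    config = genome.config
    n_reads = config.n_reads if n_reads is None else n_reads
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    L = config.chrom_length
    cyc, s_start = config.cycle_min, config.s_start_min

    chrom_idx = rng.integers(0, len(chroms), size=n_reads)
    lengths = np.exp(rng.normal(np.log(config.read_length_median), config.read_length_sigma, size=n_reads))
    lengths = np.maximum(lengths, config.read_min_length).astype(np.int64)
    starts = (rng.random(n_reads) * (L - np.minimum(lengths, L - 1))).astype(np.int64)
    strands = rng.integers(0, 2, size=n_reads)
    t0s = rng.uniform(0, cyc, size=n_reads)
    class_u = rng.random(n_reads)

    tracks: list[ReadBinnedTrack] = []
    records: list[ModReadRecord] | None = [] if keep_records else None
    site_truth: dict[str, pd.DataFrame] | None = {} if store_site_truth else None
    truth_rows = []
    for i in range(n_reads):
        chrom = chroms[chrom_idx[i]]
        start = int(starts[i])
        end = int(min(start + lengths[i], L))
        strand = "+" if strands[i] == 0 else "-"
        sites_all = genome.t_sites[chrom] if strand == "+" else genome.a_sites[chrom]
        lo = np.searchsorted(sites_all, start)
        hi = np.searchsorted(sites_all, end)
        sites = sites_all[lo:hi]
        t0 = float(t0s[i])
        u_mid = s_start + genome.t_rep[chrom][((start + end) // 2) // config.bin_size]
        # strand-copy multiplicities at the read midpoint
        if t0 > u_mid:  # locus replicated before label addition in this cell
            if class_u[i] < 0.25:
                cls = "parental"
            elif class_u[i] < 0.5:
                cls = "nascent_first"
            else:
                cls = "nascent_second"
        else:
            cls = "parental" if class_u[i] < 0.5 else "nascent_first"
        u_sites = s_start + genome.t_rep[chrom][sites // config.bin_size]
        if cls == "parental":
            labelled = np.zeros(sites.size, dtype=bool)
        elif cls == "nascent_first":
            labelled = u_sites >= t0
        else:  # second-round nascent: exists (and is labelled) only where u < t0
            mask = u_sites < t0
            mid_idx = sites.size // 2
            if sites.size == 0 or not mask[min(mid_idx, sites.size - 1)]:
                labelled = mask
            else:
                pre = np.flatnonzero(~mask[:mid_idx])
                post = np.flatnonzero(~mask[mid_idx:])
                lb = int(pre[-1] + 1) if pre.size else 0
                rb = int(mid_idx + post[0]) if post.size else sites.size
                if lb > 0:
                    start = int(sites[lb])
                if rb < sites.size:
                    end = int(sites[rb - 1] + 1)
                sites = sites[lb:rb]
                u_sites = u_sites[lb:rb]
                labelled = np.ones(sites.size, dtype=bool)
        mbc = _mbc_of_s((u_sites - s_start) / genome.s_max, config)
        probs, incorporated = _site_probs(rng, labelled, mbc, config)
        read_id = f"r{i:07d}"
        if cls == "nascent_first":
            n_lab = int(labelled.sum())
            cls_out = "labelled" if n_lab == sites.size else ("pre_label" if n_lab == 0 else "mixed")
        elif cls == "nascent_second":
            cls_out = "labelled"
        else:
            cls_out = "parental"
        rec = ModReadRecord(read_id, chrom, start, strand, sites, probs, aligned_len=end - start)
        tracks.append(bin_read(rec, config.bin_size))
        if records is not None:
            if with_sequence:
                rec.seq = genome.sequences[chrom][start:end]
            records.append(rec)
        if site_truth is not None:
            site_truth[read_id] = pd.DataFrame({"pos": sites, "labelled": labelled, "brdu": incorporated})
        truth_rows.append({
            "read_id": read_id, "chrom": chrom, "start": start, "end": end,
            "strand": strand, "mol_class": cls_out, "t0_min": t0,
            "n_t_sites": sites.size, "n_labelled": int(labelled.sum()),
            "n_brdu": int(incorporated.sum()),
        })
    truth = pd.DataFrame(truth_rows)
    return SimReads(tracks=tracks, truth_reads=truth, records=records, site_truth=site_truth)


def simulate_telomere_cohort(
    genome: SimGenome,
    seed: int,
    n_reads: int = 2000,
    tel_mean: float | None = None,
    tel_sd: float | None = None,
    coupling: float = 0.0,
    anchor_range: tuple[int, int] = (5200, 12_000),
) -> tuple[list[ModReadRecord], pd.DataFrame]:
    """Reads spanning chromosome ends with known true repeat lengths.

    Each molecule carries its own TG(1-3) tract (truncated
    Normal(tel_mean, tel_sd), independent of the reference telomere), aligned
    to the reference repeats up to their length with the overhang soft-
    clipped outward. ``coupling`` shifts a molecule's effective replication
    time by ``coupling * (true_length - tel_mean) / tel_sd`` in normalized S
    units (0 = independence, positive = longer telomeres replicate later).
    Returns (records, truth) with true lengths and label classes.
    """
    config = genome.config
    rng = np.random.default_rng(seed)
    mean = config.tel_mean if tel_mean is None else tel_mean
    sd = config.tel_sd if tel_sd is None else tel_sd
    ends = genome.annotation.ends()
    true_lens = _truncated_normal(rng, mean, sd, config.tel_min, n_reads).astype(int)
    end_choice = rng.integers(0, len(ends), size=n_reads)
    anchors = rng.integers(anchor_range[0], anchor_range[1], size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    t0s = rng.uniform(0, config.cycle_min, size=n_reads)
    class_u = rng.random(n_reads)
    cyc_s = config.s_start_min

    records, truth_rows = [], []
    for i in range(n_reads):
        end_id, chrom, side, t_start, t_end = ends[end_choice[i]]
        n = int(true_lens[i])
        run = _tg_run(rng, n)
        L = config.chrom_length
        if side == "L":
            m = min(n, t_end)  # reference repeat length on this end
            crich = revcomp(run)
            span = (t_end - m, min(t_end + int(anchors[i]), L))
            seq = crich[len(crich) - m:] + genome.sequences[chrom][t_end:span[1]]
            left_clip, right_clip = crich[: len(crich) - m], ""
        else:
            m = min(n, L - t_start)
            span = (max(t_start - int(anchors[i]), 0), t_start + m)
            seq = genome.sequences[chrom][span[0]:t_start] + run[:m]
            left_clip, right_clip = "", run[m:]
        strand = "+" if strands[i] == 0 else "-"
        base = "T" if strand == "+" else "A"
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        sites = (np.flatnonzero(arr == ord(base)) + span[0]).astype(np.int64)
        u_sites = cyc_s + genome.t_rep[chrom][sites // config.bin_size]
        t0 = float(t0s[i])
        u_mid = cyc_s + genome.t_rep[chrom][((span[0] + span[1]) // 2) // config.bin_size]
        if t0 > u_mid:
            cls = "parental" if class_u[i] < 0.25 else ("nascent_first" if class_u[i] < 0.5 else "nascent_second")
        else:
            cls = "parental" if class_u[i] < 0.5 else "nascent_first"
        if cls == "parental":
            labelled = np.zeros(sites.size, dtype=bool)
        elif cls == "nascent_first":
            labelled = u_sites >= t0
        else:
            labelled = np.ones(sites.size, dtype=bool)  # ends pre-replicated: fully labelled second round
        s_eff = (u_sites - cyc_s) / genome.s_max + coupling * (n - mean) / sd
        probs, incorporated = _site_probs(rng, labelled, _mbc_of_s(np.clip(s_eff, 0.0, 1.0), config), config)
        rec = ModReadRecord(
            f"tel{i:05d}", chrom, span[0], strand, sites, probs,
            left_clip_seq=left_clip, right_clip_seq=right_clip,
            aligned_len=span[1] - span[0], seq=seq,
        )
        records.append(rec)
        truth_rows.append({
            "read_id": rec.read_id, "end_id": end_id, "true_length": n,
            "mol_class": cls, "labelled_any": bool(labelled.any()),
        })
    return records, pd.DataFrame(truth_rows)


def simulate_to_dir(
    config: SimConfig,
    out_dir: str | Path,
    seed: int | None = None,
    n_telomere_reads: int = 0,
) -> None:
    """Materialize a simulation on disk: genome.fa, annotation/, reads.bam,
    truth_bins.tsv, truth_reads.tsv (and optionally telomere_reads.bam +
    truth_telomeres.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    genome = build_genome(config, seed)
    write_fasta(genome.sequences, out / "genome.fa")
    write_annotation(genome.annotation, out / "annotation")
    genome.truth_bins.to_csv(out / "truth_bins.tsv", sep="\t", index=False)
    sim = simulate_population_reads(genome, seed + 1, keep_records=True, with_sequence=True)
    write_modbam(sim.records, genome.annotation.chrom_lengths, out / "reads.bam")
    sim.truth_reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    if n_telomere_reads:
        tel_records, tel_truth = simulate_telomere_cohort(genome, seed + 2, n_telomere_reads)
        write_modbam(tel_records, genome.annotation.chrom_lengths, out / "telomere_reads.bam")
        tel_truth.to_csv(out / "truth_telomeres.tsv", sep="\t", index=False)
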