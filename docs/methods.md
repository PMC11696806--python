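# Methods

## Model

A locus replicating at normalized S-phase progression `s` is read out, in a
population labelled with BrdU for one doubling time, with mean BrdU content

```
MBC(s) = B / (B + T(s)),        T(s) = T0 · fold^s
```

where `B` is the BrdUTP concentration (assumed equal to the extracellular
labelling dose — the intracellular conversion efficiency is unknown, so this
is an explicit, configurable assumption) and `T(s)` the exponentially
expanding dTTP pool. Under the defaults `B = 5`, `T0 = 12`, `fold = 8` (µM),
MBC falls quasi-linearly from 0.294 to 0.050 across S phase, which is why the
binned MBC profile can be read directly as an RT profile. The inversion
`T = B · (1/MBC − 1)` is exact on `MBC ∈ (0, 1]`.

Profile construction follows the fixed recipe: 1 kb consecutive bins anchored
at position 0 of each chromosome; per-read bin means of the per-thymidine
probabilities; genomic bin values are the unweighted mean of read-level bins
with signal strictly above the 0.02 detection background (this one filter
removes parental molecules and DNA replicated before label addition, so no
separate read-level pass is applied; a site-weighted mean is available behind
a flag). Missing bins stay missing — a zero would masquerade as late
replication. Chromosome-end partial bins are kept. Rescaling is the affine
map sending the 0.5th/99.5th percentiles (linear interpolation between order
statistics) to 1 and 2; tails are deliberately not clipped into [1, 2].
Profile comparisons use Spearman's rank correlation on pairwise-complete
bins with average ranks for ties, so they are invariant to any rescaling.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 1000 bp | profile grid, anchored at position 0 |
| `background` | 0.02 | basecaller background; read bins ≤ background are BrdU-free |
| rescale percentiles | 0.5 / 99.5 → 1 / 2 | outlier-robust common scale (1 = late, 2 = early) |
| `brdu_dose` (B) | 5 µM | labelling dose; 1 mM saturates incorporation and degrades ranking |
| `T0`, `fold` | 12 µM, 8 | simulated dTTP kinetics across S |
| telomere window criteria | freqGG ∈ [0.05, 0.4], freqTelo ∈ [0.79, 1], H ∈ [0.85, 1.7], 50 nt, ≥ 90 % of windows | composition filter for genuine TG₁₋₃ repeats |
| telomere RT filters | read > 5 kb, raw RT > 0.02 | single-molecule RT kept only for labelled, well-anchored reads |
| X/XY′ threshold | 20 kb | X-to-nearest-same-arm-Y′ gap defining an XY′ end |

## Simulator

The generator emulates the study conditions end to end: a 12 Mb, 4-chromosome
genome (uniform base composition, ~25 % T per strand); terminal TG₁₋₃ repeats
of truncated-Normal(300, 75, ≥ 50) bp; an X element on every end and a Y′
element (with the X, each containing a late-firing origin, 18–24 min) on a
configurable subset, so ends replicate late; chromosome-internal origins
every ~40 kb firing at 2–14 min; constant 1.6 kb/min forks. The
replication-time landscape is deterministic:
`t_rep(x) = min over origins (firing + |x − origin| / v)`, and
`s = t_rep / max(t_rep)` (time-normalized, matching the [0, 1] S-phase axis a
copy-number profile would provide).

Molecules are drawn from cells at a uniform random cycle position `t0` at
label addition (a simplification versus the exponential age structure of a
growing culture; the rank-level quantities tested are insensitive to it).
Tracking strand copies through one doubling gives, at the read midpoint,
multiplicities 2 parental : 2 first-round nascent : 4 second-round labelled
where the locus pre-replicated, and 2 : 2 otherwise — which makes one half of
all molecules BrdU-free, the fraction real labelling experiments show.
First-round nascent strands switch from unlabelled to labelled exactly at the
label-start fork position (the within-read transition is modelled as
instantaneous); second-round strands are truncated at the label-end fork.
Reads are placed uniformly (not copy-number weighted), with log-normal
lengths (median 20 kb); 60,000 reads ≈ 110× coverage.

Basecaller noise: reported per-site probabilities are Beta-distributed with
mean 0.98 on BrdU-incorporated sites (≈ 2 % false-negative weight) and mean
0.005 on all other sites. The background mean sits below the 0.02 detection
threshold because that threshold is the *upper* level of real parental-read
signal: parental 1-kb bin means must fall at or under it for the background
filter to remove them, as they do in real data. A mean-0.02 background would
instead straddle the filter boundary, leak ~half the parental bins into the
profile and add a large additive bias to late-S MBC — behaviour the real
basecaller does not show. With `noise=False` the reported value is the exact
incorporation probability, so closed-form oracles hold bit-exactly.

Simulated TG₁₋₃ tracts draw G-run lengths 1/2/3 with weights 0.45/0.35/0.20;
an even mix would be unrealistically G-heavy (GG in half of the dinucleotide
slots of TGGG-rich windows, entropy below 0.85) and real tracts are dominated
by TG/TGG units. With these weights, tract-wide freqGG ≈ 0.27 and H ≈ 0.95,
inside the acceptance bounds, and ≥ 99 % of simulated wild-type candidates
pass the 90 % window rule.

What the simulator does **not** emulate: sequencing errors in the nucleotide
sequence itself (alignments are exact by construction, so telomere length
recovery is error-free up to window-trim resolution — real data add
basecalling noise the composition filters are designed to absorb);
stochastic cell-to-cell origin firing (the landscape is shared by all
cells); copy-number-weighted read sampling; rDNA arrays; any raw-signal
effects. Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and filters under the stated generative model, not basecaller
calibration on real reads — the real probabilities come from a trained
neural model whose calibration the Beta stand-in does not claim to match.

## Numerical choices

- ML bytes decode to quantization-bin midpoints `(k + 0.5)/256` (unbiased
  under uniform quantization); encoding is `floor(p·256)` clamped to 255, so
  round trips agree within 1/256.
- The kinetics fit is plain nonlinear least squares of `T0·e^{k·s}` without
  an offset term (the alternative with an additive floor is deliberately not
  fitted; the background already enters through MBC). Initialization is
  deterministic — `T0` from the smallest-`s` point, `k` from a log-linear
  regression — so the fit is reproducible.
- Sliding telomere windows step by 1 nt (maximal boundary resolution;
  configurable). Dinucleotide fractions use overlapping pairs with
  denominator `|window| − 1`, the only convention in which a pure repeat
  reaches freqTelo = 1. Entropy is base 2 over mononucleotide frequencies.
  Candidates shorter than 50 nt are scored in a single window. Measured
  length trims only leading/trailing windows that fail *all three* criteria;
  ambiguous interior windows never trim.
- Repeat-length truth comparisons use the cohort's *true* median (the ≥ 50 bp
  truncation shifts the median of a Normal(150, 75) cohort to ≈ 158, so a
  naive "−150 bp" target would be wrong by ~8 bp).
- Consecutive-bin noise pairs straddling missing bins are skipped, never
  imputed (imputation biases the variance down). The coverage filter drops
  bins below a quarter of the median read-bin count.
- Degenerate inputs raise: empty tracks, constant profiles (rescaling map
  undefined), fewer than 3 points/pairs for fits and correlations, mbc ≤ 0
  on inversion.

## Problem sizes

The standard-condition checks run one 12 Mb / 60,000-read simulation
(~30 s each) plus a 1 mM companion and an independent replicate; telomere
cohorts are 2,000 reads. The acceptance script uses the same sizes and
completes in a couple of minutes on one CPU. Unit tests run on a 2 × 300 kb
genome.

## Known limitations

- `B = labelling dose` is an assumption, not a measurement; absolute dTTP
  concentrations inherit its error, though the fold change does not.
- The latest-replicating bins sit closest to the background, so the
  recovered fold change is biased slightly low (≈ −8 % at default noise);
  the bias would grow with a hotter background or a lower dose.
- Reads are attributed to ends solely via their primary alignment; unmapped
  telomeric reads are not rescued.
- bedGraph values are written with 6 decimals; byte-identical round trips
  hold only to that precision.
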