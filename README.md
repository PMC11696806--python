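# nanotiming

Telomere-to-telomere DNA replication-timing (RT) profiles from BrdU-labelled
nanopore reads, for genomicists studying when the genome replicates — without
cell sorting or synchronisation.

## The idea

Asynchronously growing cells are labelled with the thymidine analogue BrdU
for one doubling time, so every locus replicates exactly once inside the
label window. At the replication fork, BrdUTP (concentration *B*) competes
with dTTP (concentration *T*) for incorporation opposite adenine, so the
**mean BrdU content** of DNA replicated at that moment is

```
MBC = B / (B + T)
```

Because the intracellular dTTP pool expands roughly exponentially through
S phase — `T(s) = T0 · fold^s` with `s ∈ [0, 1]` the normalized S-phase
progression — early-replicating DNA incorporates more BrdU than
late-replicating DNA, and the genome-wide MBC profile *is* an RT profile.
Inverting the relationship, `T = B · (1/MBC − 1)`, turns a profile back into
dTTP-pool kinetics. Long nanopore reads additionally map uniquely into
subtelomeric repeats, giving access to the RT and repeat length of
*individual* telomeres.

The package implements the full computational pipeline:

- **io_formats** — modified-base BAM (MM/ML tags, 8-bit probabilities),
  bedGraph, BED annotations;
- **rt_profile** — per-read 1 kb binning, the 0.02 background filter that
  removes parental and pre-label DNA, profile aggregation, 0.5/99.5-percentile
  rescaling onto the 1 (late) – 2 (early) scale, Spearman comparison;
- **dttp_model** — the pool-competition model, exponential kinetics fit,
  forward MBC prediction;
- **telomere** — TG₁₋₃ candidate extraction (aligned repeats + outward soft
  clip, centromere→telomere orientation, C₁₋₃A complementation), 50-nt window
  composition filters (freqGG, freqTelo, Shannon entropy, 90% rule), repeat
  length, single-molecule and population telomere RT, X / XY′ classification;
- **quality** — subsampling depth/quality curves and the bin-to-bin-difference
  intrinsic-noise estimator;
- **simulate** — a synthetic-data generator (origin/fork replication
  landscape, asynchronous labelled population, nanopore-like modBAM output,
  telomere cohorts) with full ground truth, so every stage is testable
  without sequencing data.

## Worked example

```sh
python examples/dttp_kinetics.py
```

simulates a 1.2 Mb genome labelled at 5 µM BrdU, builds the MBC profile,
inverts it and fits the dTTP kinetics:

```
simulated truth:  T0 = 12.0 uM, fold = 8.0
recovered fit:    T0 = 12.42 uM, fold = 7.21  (1198 bins)
predicted MBC at s = 0, 0.5, 1: 0.287, 0.130, 0.053
```

The fit recovers the simulated S-start dTTP concentration within a few
percent; the fold change is slightly compressed by basecaller background on
late-replicating (low-MBC) bins. `examples/profile_from_simulation.py` prints
the companion profile numbers (~50% BrdU-free read bins filtered; Spearman
ρ = 0.991 against the true replication-time ranking), and
`examples/telomere_lengths.py` measures a simulated wild-type telomere cohort
(median 304 bp vs true 304 bp, length ⟂ RT). Each script ends with a line
stating what the numbers mean.

The same analyses are available from the shell:

```sh
nanotiming simulate --out sim/ --seed 3 --n-reads 3000 --telomere-reads 500
nanotiming profile  --bam sim/reads.bam --genome sim/annotation/chrom.sizes \
                    --rescale --out profile.bedGraph
nanotiming dttp     --profile raw.bedGraph --truth-bins sim/truth_bins.tsv \
                    --brdu-dose 5 --out dttp.tsv
nanotiming telomere --bam sim/telomere_reads.bam --annotation sim/annotation \
                    --out telomeres.tsv
```

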