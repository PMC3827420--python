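# Methods

## The analysis model

`tflink` formalises a common integrative design in regulatory genomics:
a transcription factor's *regulated* genes are defined as the
intersection of three per-gene annotations,

1. **bound** — the gene has at least one TF-bound region assigned to it;
2. **motif-bearing bound** — at least one assigned region carries the
   TF's consensus recognition sequence, evidence of direct binding;
3. **responsive** — the gene changes expression when the TF is knocked
   out (fold change, significance and detectability hurdles below).

The chain `regulated ⊆ responsive` and
`regulated ⊆ motif-bearing bound ⊆ bound ⊆ universe` is asserted on
every run.  Cross-condition comparisons (two cell types, resting vs
activated states) are then plain set arithmetic on these per-sample
sets, with significance from exact finite-universe tests.

## Stage-by-stage notes

### Peak calling (`peakcall`)

A sliding window (300 bp, step 100 bp) of treatment 5′-tag counts is
tested against `P(X ≥ k)` for `X ~ Poisson(λ_local)`.  `λ_local` is the
maximum of the genome-wide control rate and the control rate in 1 kb,
5 kb and 10 kb windows centred on the test window — the local maximum
protects against regional background biases.  The larger library is
scaled multiplicatively to the smaller one (applied to expected counts
when the control is larger, to observed counts when the treatment is
larger).  Windows at `p ≤ 1e-5` are merged when ≤ 100 bp apart; the
summit is the densest 50 bp bin of treatment tags.  The genome-wide
control rate is a floor on λ, so empty regions never divide by zero.
No fragment-shift model is fitted: the synthetic tags are generated
unshifted, and externally called peak BEDs are accepted as alternative
input to all downstream stages.

### Regulatory domains and assignment (`annotate`)

Basal domain: 5 kb upstream / 1 kb downstream of the TSS, oriented by
strand.  Extension: each side grows to the nearest neighbouring basal
domain, capped at 1 Mb from the TSS and at chromosome ends.  Domains of
adjacent genes overlap between their basal domains, so an intergenic
peak midpoint can be assigned to two genes — this is why a sample can
have more bound genes than peaks.  The peak *midpoint* (not the summit)
anchors both domain membership and TSS distance; distances are unsigned
and binned at 1 / 5 / 50 kb.  A `nearest` mode restricts each peak to
its closest assigned TSS.

### Motif scanning (`motifs`)

Consensus scanning over IUPAC codes, both strands, overlapping
occurrences allowed; distinct (position, strand) pairs are distinct
hits.  A sequence `N` matches only the pattern code `N`.  Enrichment is
a Z-score of the observed hit total against B = 100 region sets sampled
from the genome with lengths resampled from the observed peaks and
placement outside the peaks themselves; the background seed is
mandatory, so Z-scores are reproducible.  Modules are pairs of hits in
the same region with an edge-to-edge gap ≤ 50 bp (overlap counts as gap
0); same-motif modules need two distinct hits and count each unordered
pair once.  Module enrichment is a density-per-kb ratio between a
region partition and matched background.  Consensus choices
(`TGYGGY`, `MGGAA`, `TGASTCA`) are published cores; position-weight
matrices are out of scope.

### Differential expression (`diffexpr`)

On log2-normalised matrices: fold change is the difference of group
means (a geometric-mean ratio on the linear scale), the location test
is a two-sided two-sample t-test, and a gene must exceed a background
floor in at least one array.  Defaults: fold ≥ 1.5, p < 0.05, raw
(unadjusted) p-values, matching the common practice this design
emulates; a Benjamini–Hochberg mode exists but is off by default.

The **pooled-variance** t-test is the default rather than Welch's.  At
three replicates per group the Satterthwaite approximation costs about
one degree of freedom (df ≈ 3 instead of 4), which measurably lowers
power: in a 400,000-replicate simulation at a 2-fold effect with
replicate sd 0.25, the pooled test passes the full filter for 93.8% of
true effects at an exact 5.0% null rate, Welch only 87.7%.  With equal
group variances — true for the synthetic generator and approximately
true for replicate microarrays — the pooled test is exact.  `welch=True`
switches tests.  Genes with zero variance in both groups but different
means get a floor p of 1e-12 so noiseless fixtures classify
deterministically.

### Integration statistics (`integrate`)

2×2 association: Pearson χ² (no continuity correction, df 1) and
two-sided Fisher (sum of hypergeometric point masses ≤ the observed
mass).  The Fisher routine is a vectorised, margin-grouped
implementation validated against `scipy.stats.fisher_exact` and against
exact integer enumeration of every table with N ≤ 60.  Odds ratios use
the Haldane +0.5 correction when a cell is zero.  Expected overlap of
two lists in a universe of N genes is `n₁n₂/N` with an exact
hypergeometric upper tail (no normal approximation); a seeded
Monte-Carlo mode cross-checks the tail.  For cross-platform
comparisons the universe is the intersection of the two platforms' gene
universes.  Reports round percentages to integers and ratios to one
decimal, mirroring the reporting style of the emulated study; TSV/JSON
outputs keep full precision.

### Pre-ranked GSEA (`gsea`)

Genes ranked by descending |linear fold change| (ties keep stable input
order, recorded in the result).  With weight exponent p (default 1),
hits increment the running sum by `|w|^p / Σ_hits |w|^p`, misses
decrement by `1/(N − N_H)`; ES is the signed extremum.  The null is
1,000 random same-size gene sets (seeded); NES divides ES by the mean
same-sign null ES and the nominal p is the same-sign tail fraction
(reported as an upper bound `1/n_permutations` when no null value is as
extreme).  Note that with p = 1 the null ES distribution is *not*
mean-zero — heavier weights near the top give random sets a positive
drift — which is precisely why normalisation is per sign; the mean-zero
property holds for the unweighted p = 0 statistic, and the test suite
checks both facts.

## The synthetic generator (`simulate`)

The generator emulates the structure of a two-cell-type × two-state
TF-occupancy + knockout-transcriptome study at desk scale.  Defaults
(all in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 2 Mb, uniform ACGT | large enough for ~10 kb gene spacing |
| genes | 400, non-overlapping, alternating strands | sub-megabase regulatory landscape |
| peaks per sample | 240 (85% anchored to gene basal windows, 15% intergenic) | roughly half the genes bound, as in TF occupancy maps |
| peak length | N(300, 80²), min 100 bp | ChIP fragment-scale regions |
| cross-sample overlap | 0.62 | the emulated study's measured peak-overlap fraction |
| motif plant rate | 0.90 | the emulated ~90% consensus-bearing fraction |
| tag background rate | 0.01 / bp | ≈ 30 M uniquely aligned reads on a mammalian genome |
| tag enrichment | 10× inside peaks | λ ≈ 30 per 300 bp window against λ ≈ 3 background |
| DE effect | 2.5-fold (mid of the emulated 1.5–4× span) | planted on 50% of motif-bearing bound genes, 2% of others |
| down/up split | 60/40 | the emulated direction skew |
| replicate noise | N(0, 0.25²) log2, 3 replicates/group | microarray-replicate scale |
| background floor | log2 = 4, 8% of unbound genes kept below | exercises the above-background hurdle |

Design choices worth knowing:

* **Exact motif truth.**  Before planting, all peak footprints are
  scrubbed of incidental consensus occurrences (central-base swaps,
  rescanned to convergence), and planting avoids footprints of peaks
  meant to stay motif-free.  Planted windows are protected when later
  samples/states are planted on the same genome, and motif truth is
  recomputed globally afterwards, so "peak carries a motif" is exact,
  not probabilistic.  Planting overwrites bases (no insertion), keeping
  coordinates fixed.
* **Controlled overlap.**  A configured fraction of sample-A peaks gets
  an overlapping sample-B partner; remaining B peaks are placed clear of
  A, so the measured overlap fraction equals the configured one up to
  rounding.
* **Bound-gene truth** is geometric (peak midpoint inside the target
  gene's basal window), independent of the domain-extension logic it is
  used to test.
* **Noise model**: log-normal expression (Normal on log2), standard for
  intensity arrays.

What the generator does *not* emulate: mappability, GC bias, chromatin
accessibility, sequencing error, probe-level effects, correlated
replicate structure.  Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated model, not performance on real
libraries.

## Problem sizes and determinism

Everything is a pure function of (inputs, seed); reruns are
byte-identical.  The bundled benchmarks run on one CPU in well under a
minute each: peak-caller calibration on a 2 Mb genome with 120 planted
peaks (wider, ≥300 bp, so each contains a fully-covered test window);
DE calibration on 2,000 genes (2-fold effect, sd 0.25, n = 3 — the
measured regime where pooled-test sensitivity is ~94%); end-to-end
regulated-set recovery on the default 400-gene scenario; GSEA null
calibration with 500 random sets × 1,000 permutations on a 1,000-gene
ranking; exhaustive Fisher/hypergeometric enumeration over all ~640k
2×2 tables with N ≤ 60.

## Known limitations

* The peak caller is deliberately minimal: no fragment-shift model, no
  duplicate filtering, no FDR by sample swap; it exists to make the
  occupancy stage self-contained and is not a MACS replacement.
* Consensus (not PWM) motif scanning understates degenerate binding
  sites; Z-scores depend on the background sampler and are comparable
  only within a fixed background model.
* The DE filter operates on raw p-values by design fidelity; with
  thousands of genes the responsive set contains the expected share of
  false positives unless the FDR mode is enabled.
* Gene models carry a single TSS; alternative promoters are not
  represented.
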