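# tflink

Integrative ChIP-seq × transcriptome analysis for transcription-factor
regulatory programs: given TF-bound regions, a gene annotation and WT vs
knockout expression matrices, `tflink` derives the genes a TF *regulates*
— those that are bound (with the TF's consensus motif in a bound region)
**and** differentially expressed upon TF loss — and quantifies how
regulatory programs overlap across cell types and activation states.

The package grew out of the analysis style used for Runx3 in cytotoxic
lymphocytes (CD8⁺ T cells and NK cells, resting vs IL-2-activated), but
every stage is generic: any TF, any pair of conditions.

## What it computes

* **Peak calling (lite)** — sliding-window Poisson test of treatment tag
  counts against a *dynamic local λ* estimated from a control library
  (max of the genome-wide rate and 1/5/10 kb local rates), with the
  larger library scaled to the smaller: `p = P(X ≥ k), X ~ Pois(λ_local)`.
* **Peak→gene association** — GREAT-style basal-plus-extension regulatory
  domains (5 kb up / 1 kb down, extended to the nearest neighbouring
  basal domain, ≤ 1 Mb), assignment by peak midpoint, TSS-distance bins
  (<1 kb, 1–5 kb, 5–50 kb, >50 kb).
* **Motif analysis** — IUPAC consensus scanning on both strands
  (RUNX = `TGYGGY`, ETS = `MGGAA`, AP-1 = `TGASTCA`, all configurable),
  Z-score enrichment against length-matched sampled genomic background,
  and two-motif *modules* (co-occurrences ≤ 50 bp apart).
* **Differential expression filter** — linear fold change ≥ 1.5
  (difference of log2 group means), two-sample t-test p < 0.05, and
  signal above background in ≥ 1 array.
* **Integration statistics** — regulated = responsive ∩ motif-bearing
  bound; 2×2 association tests (Pearson χ², two-sided Fisher); expected
  gene-list overlap `E = n₁n₂/N` with exact hypergeometric tail
  `p = P(X ≥ k)`; direction concordance; printed-style ratio reports.
* **Pre-ranked GSEA** — genes ranked by |linear fold change|; weighted
  running-sum enrichment score, NES and nominal p from a seeded
  random-gene-set permutation null.
* **Synthetic data** — a full two-cell-type × two-state study generator
  with planted ground truth (peak overlap fraction, motif plant rate,
  tag enrichment, DE effects), so every stage is benchmarked against
  known truth without any external download.

## Worked example

```python
from tflink import simulate as sim
from tflink.annotate import build_domains, assign_peaks
from tflink.diffexpr import DEConfig, differential_genes
from tflink.integrate import derive_gene_sets, expected_overlap
from tflink.motifs import MotifConsensus, region_motif_summary

study = sim.simulate_study(sim.SimulationConfig(seed=1))
domains = build_domains(study.genes, study.chrom_sizes)
runx = MotifConsensus("RUNX", "TGYGGY")

sample = "cellA_rest"
assignments = assign_peaks(study.peaks[sample], domains)
_, motif_fraction, hits = region_motif_summary(
    study.peaks[sample], study.genome, [runx])
m = study.expression[sample]
de = differential_genes(m.group_columns("WT"), m.group_columns("KO"),
                        DEConfig(background_floor=4.0))
sets = derive_gene_sets(assignments, hits, de, set(de.index))
print(f"{motif_fraction:.0%} of peaks carry a RUNX motif")
print(f"{len(sets.regulated)} regulated genes "
      f"({len(sets.regulated & study.truth.regulated_genes[sample])} "
      f"match the planted truth)")
```

prints

```
90% of peaks carry a RUNX motif
94 regulated genes (90 match the planted truth)
```

— about 90% of simulated bound regions carry the planted consensus (the
generator's configured rate), and the regulated set recovers the planted
bound-and-responsive genes with high precision.  The expected-by-chance
overlap of two regulated lists follows the closed form: for lists of 231
and 818 genes in a 17,178-gene universe,
`expected_overlap(231, 818, 17_178, observed=38).expected` → `11.0`,
with hypergeometric `p < 1e-10` for 38 observed common genes.

A CLI wraps the same stages end to end
(`tflink run --seed 1 --outdir out`), writing per-stage TSVs and a
`report.json` with every count, fraction, Z and ES/NES computed.

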