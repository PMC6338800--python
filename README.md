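# cistandem

Tools for calling the direct transcriptional targets of a chromatin-associated
long noncoding RNA from perturbation transcriptomics, and for testing whether
those targets' promoters carry an **Alu repeat and an IRF transcription-factor
site in tandem** more often than the genomic background.

## Who this is for

Regulatory genomicists with (i) differential-expression tables from
knockdown and overexpression experiments of a candidate regulator, and
(ii) standard genomic tracks — a TSS table (BED6), a repeat annotation
(RepeatMasker `.out` or BED) and TF binding evidence (ChIP narrowPeak or a
PWM to scan). The package calls the coherent target catalog, annotates
promoters, quantifies cis-element co-occurrence, and maps promoter motifs
back onto the regulator's transcript.

## The statistics at the core

**Coherent target calling.** For KD experiments *e* = 1..m and KI
(overexpression) experiments *f* = 1..k, with per-gene FDR *q* and log2
fold-change:

    gene_set_up = ∩ₑ {g : q ≤ 0.05, log2FC > 0}
    core_up     = gene_set_up ∩ ∩_f {g : q ≤ 0.05, log2FC < 0}

**Tandem co-occurrence enrichment.** Each promoter window (default
TSS −2500/+500 bp, strand-aware) is classified as `both` / `irf_only` /
`alu_only` / `none`. For category counts *x* in a gene set of size *n*
against a background universe of *N* promoters of which *K* carry the
category, over-representation is the hypergeometric tail

    p = P(X ≥ x),  X ~ Hypergeometric(N, K, n)

**Signature.** The tandem-carrying subset of `gene_set_up`, with element
topology (TSS distances, Alu/IRF ordering, inner-edge spacing) summarised
per gene in TSS-relative coordinates (negative = upstream in the
transcription direction).

Also included: two-sided Fisher overlap tests for reagent concordance,
preranked GSEA (weighted Kolmogorov–Smirnov ES, gene-label permutation NES),
PWM scanning and ungapped motif-to-transcript homology, Jonckheere–Terpstra
trend test, ROC/AUC, comparative-Ct (2^−ΔΔCt) quantification, and a fully
seeded synthetic-study generator with planted ground truth.

## Worked example

```python
from cistandem import synth, promoters, de_sets, cooccurrence as cc

cfg = synth.SynthConfig(n_genes=500, n_targets=100, seed=7)
ds = synth.generate_dataset(cfg)

kd = [t for k, t in ds.de_tables.items() if k.startswith("kd")]
ki = [t for k, t in ds.de_tables.items() if k.startswith("ki")]
catalog = de_sets.build_catalog(kd, ki, fdr_max=0.05)

anns = promoters.annotate_promoters(ds.genes, ds.alu_track, ds.irf_track)
rep = cc.category_enrichment({g: anns[g] for g in catalog.core_up}, anns)
ranked = de_sets.rank_by_mean_fc(catalog.core_up, kd)
signature = cc.extract_signature(ranked, anns)
topo = cc.topology_summary([anns[g] for g in signature])
```

Output:

```
core_up size: 100
tandem fraction in targets:   0.59
tandem fraction in background: 0.42
hypergeometric p (both):       1.45e-04
signature: 59 of 100
median TSS distance, IRF vs Alu: 78 vs 1081 bp
```

All 100 planted targets are recovered as the coherent `core_up` set; their
promoters carry the Alu+IRF tandem at the planted elevated rate (0.55 planted,
0.59 observed in this draw) against the genome-like background (0.38 planted),
the enrichment is flagged by the hypergeometric test, and within the tandem
signature the IRF site sits close to the TSS while the Alu lies further
upstream — the topology the analysis is designed to expose.

The same pipeline runs from the shell on files:

```
cistandem simulate --seed 7 --out study/
cistandem report --config pipeline.yaml     # paths + thresholds in YAML
```

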