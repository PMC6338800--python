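# Methods

## The analysis model

The package operationalises a two-part claim about a repressive,
chromatin-associated lncRNA: (1) its direct targets are the genes that
respond *coherently* to perturbation — up when the regulator is silenced
with independent reagents, down when it is ectopically expressed — and
(2) those targets are distinguished by a promoter architecture in which an
Alu/SINE repeat and an IRF-family binding site co-occur in the same promoter
window ("in tandem"), with the IRF site proximal to the TSS and the Alu
upstream of it.

The analysis therefore composes four steps: regulated-set calling from DE
tables (intersection across experiments at FDR ≤ 0.05), strand-aware
promoter annotation from genomic tracks, category enrichment against a
background promoter universe (one-sided hypergeometric), and element
topology/homology summaries. Each step is exposed as an importable module
and as a CLI stage; the pipeline composes them and embeds its full resolved
configuration in the run report, because several parameters (most notably
the promoter window) materially shape the result.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `promoter_up` / `promoter_down` | 2500 / 500 | bases | The window must contain the empirically observed geometry: Alu TSS distances around 1.1 kb median and Alu–IRF spacings up to ~2 kb. A ±2.5 kb/+0.5 kb window holds a full 300-base Alu at maximal spacing. Echoed in every report since results depend on it. |
| `fdr_max` | 0.05 | — | The conventional DE significance threshold; no fold-change cut is applied by default (`min_abs_log2fc = 0`). |
| overlap rule | ≥ 1 bp | — | An element belongs to a promoter if it overlaps the window at all; no minimum-overlap fraction, matching the weakest reading of "presence of a site". |
| tandem definition | co-presence | — | Both element classes present in the window. Ordering and spacing are reported as observations, not imposed as filters; an optional `max_spacing` cutoff exists but is off by default. |
| `score_min` (PWM) | 0.8 | fraction of max log-odds | Absolute log-odds cutoffs are matrix-specific; a fraction of the maximum achievable score transfers across motifs. |
| `weight_exponent` (GSEA) | 1 | — | The weighted KS statistic; 0 recovers the classic unweighted KS. |
| `n_perm` | 1000 | — | Gene-label permutations for the NES null (the only permutation scheme available to preranked input). |

## Coordinate and tie conventions

- All genomic intervals are 0-based half-open (BED) internally; RepeatMasker
  `.out` 1-based inclusive coordinates are converted on read and only
  re-expanded when writing that dialect.
- TSS-relative coordinates map each covered base `p` to `p − tss` (+ strand)
  or `tss − p` (− strand) and normalise to half-open with start < end.
  This position-set convention is applied uniformly; it makes promoter
  windows, element mapping and the strand-symmetry invariant (mirroring the
  genome leaves all relative annotations unchanged) mutually consistent.
- Element TSS distance is edge-based: 0 if the element spans the TSS,
  otherwise the distance of its TSS-facing boundary, `min(|start|, |end|)`
  in relative coordinates. Midpoint-based distance was the alternative;
  edge-based is used and stated because the quantity feeds median distances
  whose interpretation ("how close can the element get") is about edges.
- Spacing is the gap between the two elements' facing edges, 0 when they
  overlap. Medians use the standard midpoint of two central values.
- With several elements of a class in one promoter, topology uses the
  TSS-nearest instance; presence/absence statistics use presence only.
- Gene ranking by mean fold-change averages the tables' native log2 values
  (not linear fold-changes) and breaks ties lexicographically by gene id so
  that rankings are reproducible.
- ES extreme-deviation ties resolve to the earliest position; homology
  alignment ties resolve to the smallest transcript offset, forward strand
  first.
- Ambiguous bases (N) contribute zero log-odds — neither reward nor penalty.
- Duplicate gene ids in a DE table collapse to the record with highest |t|
  (the most-variable-probe rule); duplicate TSS rows keep the first
  occurrence (the first-isoform rule).

## Statistical kernels

- `hypergeom_tail(x, N, K, n)` returns P(X ≥ x) via the scipy survival
  function (log-space internally); it is validated against exact
  integer-arithmetic pmf summation for every parameter combination with
  N ≤ 60.
- Fisher overlap tests are two-sided on the 2×2 table (intersection,
  A-only, B-only, universe − union). The universe size is an explicit
  parameter: it is the number of genes surviving the expression filter and
  must be supplied by the caller rather than guessed.
- Per-category hypergeometric p-values are reported raw, without
  multiple-testing correction across the four categories.
- The Jonckheere–Terpstra statistic counts concordant cross-group pairs
  with ties at ½; the default p uses the normal approximation with the
  three-term tie-corrected variance, and an exact full-enumeration p is
  available for small samples (≈ n ≤ 12). Pure-tie data yield z = 0,
  p = 0.5.
- AUC is Mann–Whitney U / (n₁n₀) with tied scores counted ½.
- Comparative-Ct quantities average replicates before differencing and fix
  amplification efficiency at 2 (no efficiency correction).
- Permutation p for NES is the fraction of same-sign permuted scores at
  least as extreme; NES normalises by the mean |ES| of same-sign
  permutations. When no same-sign permutation exists the result is flagged
  undefined rather than coerced.

## The synthetic-data generator

The generator emulates exactly the statistical structure the analysis
assumes, with planted ground truth carried alongside:

- **Genome and genes.** Random-composition chromosomes; TSS positions drawn
  uniformly with a minimum separation of `2·max(up, down) + 2` bases so
  promoter windows can never collide regardless of the strand pairing of
  neighbours (a minus-strand window extends downstream in genomic
  coordinates, so a naive up+down separation is not sufficient). Strands
  are Bernoulli(½) and every placement is computed in the transcription
  direction, so strand-handling bugs surface immediately.
- **Elements.** Target promoters receive the Alu+IRF tandem with probability
  0.55, background promoters with 0.38; remaining mass splits into
  irf-only/alu-only/none at genome-like proportions (0.19 / 0.30 of the
  background remainder). In a tandem, the IRF site's TSS-facing edge sits
  uniformly 20–160 bp upstream and the Alu is placed further upstream with
  inner-edge spacing uniform on [66, 1973] bp — the observed spacing range
  the defaults are meant to reproduce. Planted Alus carry a fixed 300-base
  consensus-like sequence that is also embedded in the synthetic lncRNA
  transcript, so motif scanning and transcript homology are exercisable
  end-to-end; IRF sites carry an ISRE-like repeat.
- **DE tables.** Target effects are positive-truncated N(2.0, 0.3) log2
  fold-changes, signed + in each KD table and − in each KI table, plus
  N(0, 0.2) noise on all genes; t = log2FC/SE with a t-distribution p
  (10 d.f.) and Benjamini–Hochberg FDR within each table. This reproduces
  the monotone t→FDR structure of moderated-t pipelines without fitting a
  linear model. With `noise_sd = 0` every target is perfectly coherent, so
  catalog recovery is exact by construction and tested as such.
- **Auxiliary tables.** Isoform TPMs with a ~97.6/2.4% class split and a Ct
  table encoding a one-cycle knockdown (RQ ≈ 0.5), for the quantification
  primitives.

What the generator does **not** model: probe-level microarray intensities,
read-level RNA-seq, Alu subfamily phylogeny or sequence divergence, element
density variation along chromosomes, linked/overlapping genes, or any
correlation between expression noise and promoter content. Passing tests on
synthetic data therefore certify the *computational* chain — set algebra,
geometry, enrichment arithmetic, calibration of permutation nulls — not the
biological claim itself, which on real data additionally depends on
annotation quality, promoter-window choice and the background universe.

## Problem sizes and numerics

The test suite and acceptance script run on generated studies of 120–2000
genes on 2–4 chromosomes of 0.4–4 Mb, 100–200 permutation-null repeats at
200 permutations each, and a full oracle sweep of the hypergeometric tail to
N = 60 — sizes at which every oracle comparison is exact or exhaustive while
the whole suite completes in well under a minute of statistics time.
Floating-point comparisons in tests use relative tolerances of 1e-8..1e-12;
the ES running sum is asserted to return to zero within 1e-10.

## Known limitations

- The promoter window and the background universe are the two levers that
  most affect real-data conclusions; both are explicit parameters and are
  echoed into every report, but no sensitivity analysis is automated.
- Homology mapping is ungapped by design; diverged repeat copies with
  indels will under-score.
- The exact JT permutation test is factorial in sample size and guarded to
  small n.
- `category_enrichment` requires the gene set to be contained in the
  annotated background; genes missing from the background must be resolved
  upstream (they are listed in the error).
- Preranked GSEA supports only gene-label permutation; phenotype permutation
  requires expression matrices, which are out of scope.
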