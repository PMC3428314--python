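# exaptscan

Analysis toolkit for studying **exaptation of mobile elements as gene
regulatory sequence**: the co-option of SINE, LINE, LTR-retrotransposon and
DNA-transposon fragments into conserved non-exonic elements (CNEEs) —
intervals under cross-species purifying selection that lie outside any known
mature transcript and serve as a proxy for regulatory DNA.

It is aimed at comparative and regulatory genomicists who have conserved
elements, transcript annotations and RepeatMasker-style repeat annotations
for a reference genome, plus a reference-anchored multiple alignment and a
neutral phylogeny, and want to quantify how much regulatory innovation
mobile elements have contributed and where on the repeat consensus that
innovation concentrates.

## What it computes

* **CNEE derivation and exaptation classification.** Conserved elements
  overlapping any exonic track are removed whole; a surviving element is an
  *exaptation* when a strict majority (> 50%) of its bases carry
  SINE/LINE/LTR/DNA-transposon annotation. The same strict-majority rule
  assigns the element to a repeat family, superfamily and class — an element
  45% L1 and 45% L2 is a LINE exaptation belonging to no single superfamily.
  Summary tables report, per taxon, genomic elements per exaptation and
  genomic bases per exapted base, with quotients truncated to one decimal.
* **Population-genetic constraint.** Derived-allele-frequency (DAF) spectra
  per region set, compared by the Mann–Whitney U rank-shift test (exact
  enumeration for pooled sizes ≤ 12, tie-corrected normal approximation
  otherwise). A downward shift of the spectrum signals ongoing negative
  selection.
* **Rate of evolution.** For each element, the single constant ρ that scales
  every branch of a neutral tree (branch lengths in substitutions/site,
  time-reversible substitution model) to maximise the Felsenstein-pruning
  likelihood of the element's alignment:
  ρ̂ = argmax_ρ Σ_cols log P(column | ρ·T, Q, π). ρ < 1 indicates constraint.
* **Dating.** Each element's branch of origin on the reference lineage, from
  presence/absence in progressively less divergent species groups: the most
  divergent group in which ≥ 50% of the element's bases align fixes the
  branch.
* **Genomic landscape.** Windowed density tracks, the Pearson correlation of
  their first differences, distance-to-nearest-TSS gene-desert depletion
  (one-sided hypergeometric), Monte-Carlo fold enrichment against feature
  tracks, and Kolmogorov–Smirnov distribution comparisons.
* **Consensus profiling and peaks.** Exapted intervals are projected into
  repeat-consensus coordinates (affine interpolation, strand-aware); the
  per-position fold track (exapted base density ÷ genomic insertion density)
  is scanned for runs with fold > 2 supported by ≥ 40 distinct exaptation
  events, and the observed peak count is calibrated by re-placing the
  element set uniformly at random and re-running the whole path. Paralogous
  peak sequences can be stacked into a position weight matrix and compared
  to transcription-factor binding profiles by column correlation with a
  permutation p-value.
* **Synthetic data.** A seeded generator producing a small multi-chromosome
  genome with repeat insertions of known family, consensus span, strand and
  branch of origin, constrained sub-intervals evolving at a reduced rate,
  alignments under a time-reversible model, and segregating sites with
  class-dependent derived-allele frequencies — so every stage is testable
  against known truth.

## Worked example

```python
from exaptscan.simulate import SimConfig, simulate_all
from exaptscan.intervals import derive_cnees, classify_all, summarize_exaptation
from exaptscan.phylo import PhyloModel, fit_scale

res = simulate_all(SimConfig(seed=1))
cnees = derive_cnees(res.conserved_elements(), [res.annotations.exons])
classified = classify_all(cnees, res.hits)
print(summarize_exaptation(classified, res.hits).table.to_string(index=False))
```

```
class superfamily  exapted_elements  exapted_bases  genomic_elements  genomic_bases  elements_per_exaptation  bases_per_exapted_base
Total                            51           4383                80          24148                      1.5                     5.5
  DNA                            15           1176                22           3936                      1.4                     3.3
  DNA hAT-Charlie                15           1176                22           3936                      1.4                     3.3
 LINE                            19           1762                30          14540                      1.5                     8.2
 LINE          L1                19           1762                30          14540                      1.5                     8.2
 SINE                            17           1445                28           5672                      1.6                     3.9
 SINE         Alu                17           1445                28           5672                      1.6                     3.9
```

Of 111 conserved non-exonic elements in this synthetic genome, 51 are
exaptations (majority of bases inside a repeat insertion); the ratio columns
are the genomic/exapted quotients truncated to one decimal. Fitting the rate
scale of one constrained interval that was simulated at 0.30× the neutral
rate:

```python
model = PhyloModel.jukes_cantor(res.config.tree)
ins = next(i for i in res.truth.insertions if i.constrained)
lo, hi = ins.constrained[0]
block = next(b for b in res.blocks if b.chrom == ins.chrom and b.start <= lo < b.end)
aln = {sp: row[lo - block.start:hi - block.start] for sp, row in block.sequences.items()}
print(fit_scale(aln, model))
```

prints `rho = 0.316` over 140 columns — the element is recovered as strongly
constrained.

The same pipeline is scriptable from the shell:

```bash
exaptscan simulate --out fixtures --seed 7
exaptscan classify --conserved fixtures/conserved.bed --exons fixtures/exons.bed \
    --repeats fixtures/repeats.out --out classified.tsv
exaptscan summarize --conserved fixtures/conserved.bed --exons fixtures/exons.bed \
    --repeats fixtures/repeats.out --out summary.tsv
```

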