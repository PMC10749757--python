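# crossgex

Relative cross-species comparison of bulk RNA-seq gene expression.

Comparing expression *magnitudes* directly between species is confounded
by annotation depth, library composition and species-level shifts in
both expression and orthology. `crossgex` instead summarizes each gene's
expression **pattern** within a species — how variable it is across
tissues, how evenly or narrowly it is distributed — and lets those
summaries be compared across species. It is aimed at researchers
choosing a model organism for a gene/tissue of interest, or screening
for genes whose tissue behavior diverges between species.

Six species are supported: human, mouse, rat, zebrafish, fly and worm
(taxon ids 9606, 10090, 10116, 7955, 7227, 6239).

## What it computes

Inputs are long-format expression tables (`gene_id, species, tissue,
sample_id, value`) holding counts, TPM or variance-stabilized (VST)
values, plus local ortholog-group tables in the NCBI `homologene.data`
dialect and identifier cross-reference TSVs. Everything runs offline.

**Preprocessing.** Counts → TPM (per-sample rates `count/length`
rescaled to sum to 10⁶), then a variance-stabilizing transformation for
the negative-binomial family with dispersion trend α(μ) = a₀ + a₁/μ:

    f(q) = log2( (1 + a₁ + 2a₀q + 2√(a₀q(1 + a₁ + a₀q))) / (4a₀) )

The trend is fitted from the data by per-gene moment dispersions
`max(0, (s² − μ̄)/μ̄²)` and least squares against `1/μ̄`. Medians are
taken per (gene, tissue, species) cell, and per-gene profiles are
min–max rescaled to [0, 1].

**Variability (CV).** `sd / median` of a gene's per-tissue median VST
values within a species (`cv_tissue`), or of its per-species medians for
one tissue (`cv_species`). Sample sd uses the n−1 denominator.

**Diversity and specificity.** For a gene with profile p over T tissues
(scaled medians renormalized to sum to 1):

    diversity   D = H(p) / log2 T          H(p) = −Σ p_i log2 p_i
    specificity S = KL(p ‖ uniform) / log2 T = 1 − D

Both lie in [0, 1]; a uniformly expressed gene scores (1, 0), a
single-tissue gene (0, 1). A tissue's diversity is the entropy of its
across-gene profile normalized by log2 G; its *specialization* is the
expression-weighted mean of unnormalized gene specificities divided by
log2 T — high when the tissue mostly expresses tissue-restricted genes.
Four modes slice genes × tissues: `ds_gene`, `ds_gene_all`,
`ds_tissue`, `ds_tissue_all`.

These metrics are for visualization and relative comparison; they are
not test statistics and should not feed downstream inference.

## Worked example

The bundled generator simulates the demonstration design: 5 genes ×
2 species × 5 tissues × 4 samples of NB counts, where gene5 has
strongly tissue-variable means in both species, gene2 is 16-fold
enriched in tissue1 in one species only, and genes 1/3/4 are flat.

```python
import crossgex as cg

table = cg.make_demo_vst(seed=1)           # counts -> VST, 200 records
cv = cg.cv_analysis(table, cg.SelectionSpec(), "cv_tissue")
print(cv.frame[["gene_id", "species", "cv"]].round(3).to_string(index=False))
```

```
gene_id species    cv
  gene1   human 0.021
  gene1   mouse 0.025
  gene2   human 0.267
  gene2   mouse 0.034
  gene3   human 0.023
  gene3   mouse 0.039
  gene4   human 0.024
  gene4   mouse 0.025
  gene5   human 0.277
  gene5   mouse 0.306
```

gene5 has the top CV in both species (high variability everywhere);
gene2's CV is high in human but low in mouse (species-specific
variability); the flat genes sit near zero. The same table through
`ds_from_expression(..., "ds_gene")` gives gene2 specificity 0.824 in
human against 0.157 in mouse — tissue-restricted in one species, broadly
expressed in the other.

The CLI mirrors the library:

```sh
crossgex simulate --seed 1 --vst --out-dir runs/demo
crossgex cv --input runs/demo/vst.tsv --mode cv_tissue --out-dir runs/cv
crossgex ds --input runs/demo/vst.tsv --mode ds_gene --out-dir runs/ds
```

Each run directory contains the result TSVs, a lollipop or
diversity/specificity scatter plot with its plot-ready companion table,
the resolved configuration, input digests and a log.

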