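# Methods

## Scope and model

`crossgex` compares bulk RNA-seq expression *patterns* across six
species rather than expression magnitudes. The unit of analysis is the
long-format record (gene, species, tissue, sample, value); everything
wide (gene × tissue matrices, probability profiles) is derived on
demand, because the two CV modes and four diversity/specificity modes
slice the same records along different axes.

Ortholog and identifier mapping is driven entirely by local tables (the
`homologene.data` dialect and a per-species cross-reference TSV), so the
toolkit is hermetic and testable without network access. One-to-many
resolutions — shared symbols, paralog-expanded ortholog groups — are
always expanded and flagged (`ambiguous` / `one_to_many`), never
collapsed to a first match: the caller must resolve them before a
cross-species join, because a silent collapse corrupts the join
invisibly.

## Variance stabilization

Counts (or count-like TPM values — the transform deliberately accepts
non-integer nonnegative input) are modeled as negative binomial with
`Var = μ + α(μ)μ²` and a two-parameter dispersion trend
`α(μ) = a₀ + a₁/μ`: `a₀` is the asymptotic biological dispersion at
high expression, `a₁` the extra-Poisson term dominating at low means.
Under this trend the stabilizer has the closed form

    f(q) = log2((1 + a₁ + 2a₀q + 2√(a₀q(1 + a₁ + a₀q))) / (4a₀)),

which is strictly increasing and approaches `log2 q` at high
expression. Analytically, `f′(q) = √a₀ / (√(q(1+a₁) + a₀q²) · ln 2)`,
i.e. f is the variance-stabilizing integral normalized to a unit log2
slope at infinity; the test suite checks the closed form against
numerical quadrature of that integrand to 10⁻⁶ (observed agreement
~10⁻¹³), and checks the stabilization property itself: across NB
simulations spanning mean decades 10–10⁴, post-transform variance
varies by under 3× where raw variance varies by over 10×.

The trend is estimated by per-gene moment dispersions
`α̂_g = max(0, (s²_g − μ̄_g)/μ̄_g²)` (n−1 variance) followed by
unweighted least squares of α̂ on `(1, 1/μ̄)` over genes with
`α̂_g > 0` and `μ̄_g > 1`. At least 10 usable genes are required or the
fit fails loudly. If the unconstrained fit leaves the parameter region
(possible on near-Poisson data, where half the moment estimates are
noise-positive), it is refit under nonnegativity and `a₀` floored at
10⁻⁸ — so Poisson-like data yields a valid, vanishing asymptote rather
than an error. This moments-plus-least-squares estimator is simpler
than a gamma-GLM trend fit; parameter recovery on simulated data
(500 genes × 50 samples at α(μ) = 0.05 + 2/μ) is well within 50% for
both parameters. A `log2(x+1)` fallback exists behind an explicit flag
(`fallback_log2`) for tables with too few genes to fit; it is never the
default.

Trends are fitted per species table (recorded in provenance); fitting
per tissue-set was the alternative, but per-species matches the idea
that each species' data arrives as one coherent experiment.

## Medians, scaling, profiles

Medians are taken per (gene, group) cell over samples (even n →
midpoint, the conventional choice). Cells without samples stay missing
(NaN) — never zero-filled, so absent tissues surface rather than
masquerade as silence. Min–max scaling is applied per gene row across
its groups, keeping each gene's profile in [0, 1] independent of its
absolute level; whether to scale rows or the whole matrix was an open
design choice, and per-row is exposed in output metadata. Probability
profiles are the scaled medians renormalized to sum to 1 (within
10⁻¹²), zeros retained.

Degenerate inputs: a constant nonzero gene row min–max scales to all
zeros, which admits no probability normalization; it is resolved to the
uniform profile (diversity 1) and flagged `degenerate`, preserving
auditability. An all-zero or all-missing row is emitted with missing
metrics. A constant vector under `minmax_scale` returns zeros plus a
degeneracy flag.

## Metrics

CV is `sd/median` (n−1 sd) of per-group median VST values — medians,
because the pipeline computes group medians before any cross-group
comparison. Whether to CV over medians or raw sample values is exposed
as `cv.on = medians | samples` (default medians). A median below 10⁻¹²
in magnitude yields a missing CV with reason `zero_median`; fewer than
two values, `insufficient_values`.

Gene diversity is normalized entropy `H(p)/log2 T`; gene specificity is
the normalized divergence from uniform, `KL(p‖u)/log2 T = 1 − D`, which
makes the inverse relation exact at gene level and pins both to [0, 1].
Tissue diversity is `H(q)/log2 G` for the tissue's across-gene profile
q; tissue specialization is `Σ_g q_g·S_g / log2 T` with `S_g` the
*unnormalized* gene specificity in bits — deliberately not `1 − D`, so
tissues land off the anti-diagonal of a diversity/specificity scatter
when they express a mix of broad and restricted genes. The log base is
fixed at 2 throughout.

These metrics are descriptive. They are intended for visualization and
relative comparison, not as test statistics.

## Synthetic data

The generator draws NB counts with `Var = μ + (a₀ + a₁/μ)μ²` — the same
family the stabilizer assumes, closing the loop between simulator and
transform — with per-gene effects: `Flat`, `TissueSpecific(tissue,
fold, species)`, `SpeciesVariable(fold_profile)`, and
`HighVar(sd_multiplier)` (a centred log-fold ramp over tissues, ±2.5 at
multiplier 1, i.e. ~12-fold at the extremes).

The bundled demonstration design is 5 genes × 2 species × 5 tissues ×
4 samples per cell at baseline mean 100 and dispersion (a₀, a₁) =
(0.05, 2): gene5 `HighVar` in both species, gene2 16-fold enriched in
tissue1 in the first species only, genes 1/3/4 flat. These values were
chosen once as a realistic bulk-RNA-seq regime (moderate biological CV
at high expression, strong but plausible tissue enrichment). The demo
VST uses the design's own dispersion trend directly, since five genes
are below the fitting minimum and the demo exercises the metrics, not
trend estimation. Fixture-based tests are ordinal (rankings, orderings
across ≥95 of 100 seeds), never numeric, because only the qualitative
structure of the design is meaningful.

What the generator does *not* emulate: library-size heterogeneity,
batch structure, tissue–tissue correlation, or real ortholog divergence
— so passing tests demonstrate correctness of the computations on
NB-structured data, not robustness to those real-data features.

## Problem sizes and numerics

Simulation-backed checks use 500 genes × 50 samples for trend recovery,
100 seeds for ordinal pattern rates, 1000 fuzzed profiles for the
entropy oracle and 20 random trend pairs for the quadrature oracle —
sizes at which Monte-Carlo error is far below the tested margins while
the whole suite stays fast. Output TSVs render floats at six
significant digits and sort by each type's natural key, so identical
runs are byte-identical. Tie-breaks: `argmax` rank checks take the
first maximum (pandas `idxmax`); profile normalization tolerance is
10⁻¹².

## Known limitations

- Tissue vocabulary is free-text exact-match; no ontology resolution,
  so spelling variants surface as unresolved selections by design.
- Orthology sources (ortholog-group dumps from different pipelines) are
  not merged; the caller picks one table per call.
- The dispersion trend is global per species; gene-wise shrinkage is
  out of scope.
- `cv_species` assumes orthology has been resolved upstream to shared
  gene ids; many-to-many groups must be expanded before the call.
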