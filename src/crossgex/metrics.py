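"""Cross-species comparison metrics: coefficient of variation and
Shannon-entropy diversity/specificity.

Instead of comparing expression magnitudes directly across species —
which is confounded by annotation depth, batch structure and
species-level shifts — these metrics summarize each gene's *pattern*
within a species and let the patterns be compared.

Variability: CV = sd / median of a gene's per-group median VST values,
either across tissues within a species (``cv_tissue``) or across species
for a tissue (``cv_species``).

Diversity of a gene over T tissues is its normalized Shannon entropy
``H(p) / log2 T`` where p is the gene's min–max-scaled median profile
renormalized to a probability vector; specificity is the normalized
divergence from the uniform profile, ``1 - diversity``, so the two are
exactly inversely related at gene level and both live in [0, 1].
Tissue-level diversity is the entropy (over genes) of the tissue's
expression profile normalized by ``log2 G``; tissue specialization is
the expression-weighted mean of the unnormalized gene specificities,
divided by ``log2 T`` — deliberately *not* ``1 - diversity``, so tissues
can sit off the anti-diagonal of a diversity/specificity scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SelectionError, ValidationError
from .expression_store import ExpressionTable, SelectionSpec, filter_expression
from .preprocessing import MedianMatrix, median_by_group, minmax_scale_rows

#: tolerance for the probability-profile normalization invariant
PROB_TOL = 1e-12

#: medians whose magnitude falls below this are treated as zero for CV
ZERO_MEDIAN_TOL = 1e-12

CV_MODES = ("cv_tissue", "cv_species")
DS_MODES = ("ds_gene", "ds_gene_all", "ds_tissue", "ds_tissue_all")


@dataclass(frozen=True)
class ProbabilityProfile:
    """A normalized expression profile (the p_i fed to the entropy).

    ``source`` records the slicing: a gene's profile over tissues or a
    tissue's profile over genes.
    """

    categories: tuple[str, ...]
    p: np.ndarray
    source: str = "gene-over-tissues"

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or len(p) != len(self.categories):
            raise ValidationError("profile length must match categories")
        if (p < 0).any() or not np.all(np.isfinite(p)):
            raise ValidationError("probabilities must be finite and >= 0")
        object.__setattr__(self, "p", p)

    @classmethod
    def from_values(cls, values: Sequence[float],
                    categories: Sequence[str],
                    source: str = "gene-over-tissues") -> "ProbabilityProfile":
        """Build a profile from nonnegative weights by renormalization."""
        arr = np.asarray(values, dtype=float)
        if (arr < 0).any() or not np.all(np.isfinite(arr)):
            raise ValidationError("profile weights must be finite and >= 0")
        total = arr.sum()
        if total <= 0:
            raise ValidationError("cannot normalize an all-zero profile")
        return cls(tuple(str(c) for c in categories), arr / total, source)


@dataclass
class CVResult:
    """Per-gene variability records for one CV mode."""

    frame: pd.DataFrame
    NATURAL_KEY = ("gene_id", "species", "mode", "group_label")

    COLUMNS = ("gene_id", "species", "mode", "group_label", "cv",
               "n_values", "reason")


@dataclass
class DSResult:
    """Per-gene or per-tissue diversity/specificity records."""

    frame: pd.DataFrame
    NATURAL_KEY = ("unit", "unit_id", "species", "mode")

    COLUMNS = ("unit", "unit_id", "species", "mode", "diversity",
               "specificity", "n_categories", "flags")


def shannon_entropy(profile: ProbabilityProfile) -> float:
    """Shannon entropy ``H = -sum p_i log2 p_i`` in bits, with
    ``0 log 0 = 0``. The profile must be normalized."""
    p = profile.p
    if abs(p.sum() - 1.0) > max(PROB_TOL, 1e-15 * len(p)):
        raise ValidationError(
            f"profile is not normalized (sum = {p.sum():.17g})"
        )
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def gene_diversity_specificity(
        profile: ProbabilityProfile) -> tuple[float, float]:
    """Diversity and specificity of one gene's profile over T >= 2
    categories.

    Diversity ``D = H(p)/log2 T`` is 1 for a uniform profile (evenly
    expressed everywhere) and 0 for a one-hot profile; specificity
    ``S = KL(p || uniform)/log2 T = 1 - D`` is the exact complement.
    """
    t = len(profile.categories)
    if t < 2:
        raise ValidationError("need >= 2 categories for diversity/specificity")
    d = shannon_entropy(profile) / np.log2(t)
    return float(d), float(1.0 - d)


def tissue_diversity_specificity(scaled: pd.DataFrame,
                                 tissue: str) -> tuple[float, float]:
    """Diversity and specialization of one tissue given a genes × tissues
    matrix of min–max-scaled median values.

    Diversity is ``H(q) / log2 G`` for the tissue's across-gene profile
    ``q_g = scaled[g, t] / sum_g scaled[g, t]``. Specialization is the
    q-weighted mean of the *unnormalized* gene specificities
    ``log2 T - H(p_g)`` (bits), divided by ``log2 T``: high when the
    tissue's expression is dominated by tissue-restricted genes.
    Constant gene rows contribute a uniform profile (zero specificity).
    """
    if scaled.shape[0] < 2 or scaled.shape[1] < 2:
        raise ValidationError("need >= 2 genes and >= 2 tissues")
    if tissue not in scaled.columns:
        raise SelectionError(f"tissue {tissue!r} not in matrix")
    n_genes, n_tissues = scaled.shape
    col = scaled[tissue].fillna(0.0).to_numpy()
    if col.sum() <= 0:
        raise ValidationError(f"tissue {tissue!r} has an all-zero column")
    q = ProbabilityProfile.from_values(col, scaled.index.astype(str),
                                       source="tissue-over-genes")
    diversity = shannon_entropy(q) / np.log2(n_genes)

    log2_t = np.log2(n_tissues)
    gene_spec_bits = np.empty(n_genes)
    for i in range(n_genes):
        row = scaled.iloc[i].fillna(0.0).to_numpy()
        if row.sum() <= 0:
            # constant row scaled to zeros: treat as uniform, zero bits
            gene_spec_bits[i] = 0.0
            continue
        p = ProbabilityProfile.from_values(row, scaled.columns.astype(str))
        gene_spec_bits[i] = log2_t - shannon_entropy(p)
    specificity = float(np.dot(q.p, gene_spec_bits) / log2_t)
    return float(diversity), specificity


def compute_cv(values) -> tuple[float | None, str]:
    """Coefficient of variation of a vector of VST values: sample
    standard deviation (n-1 denominator) over the median.

    Returns ``(cv, reason)``; cv is None with reason
    ``insufficient_values`` for < 2 finite values, or ``zero_median``
    when the median's magnitude is below 1e-12.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return None, "insufficient_values"
    med = float(np.median(arr))
    if abs(med) < ZERO_MEDIAN_TOL:
        return None, "zero_median"
    sd = float(np.std(arr, ddof=1))
    return sd / med, "ok"


def cv_analysis(table: ExpressionTable, spec: SelectionSpec,
                mode: str, on: str = "medians") -> CVResult:
    """Run a CV analysis over a VST expression table.

    ``cv_tissue``: one row per (gene, species) — CV over that gene's
    per-tissue median VST values in the selected tissues. ``cv_species``:
    one row per (gene, tissue) — CV over the per-species medians of the
    gene across the selected species, with the species-set recorded in
    the species column (orthology is resolved upstream, so the same gene
    id indexes all species).

    ``on="samples"`` switches the CV to pooled sample-level VST values
    instead of per-group medians.
    """
    if mode not in CV_MODES:
        raise ValidationError(f"mode must be one of {CV_MODES}, got {mode!r}")
    if on not in ("medians", "samples"):
        raise ValidationError(f"cv.on must be 'medians' or 'samples', got {on!r}")
    if table.scale != "vst":
        raise ValidationError("cv_analysis expects a vst-scale table")
    sub = filter_expression(table, spec)

    rows = []
    if mode == "cv_tissue":
        label = ",".join(sorted(sub.tissues))
        for (gene, sp), grp in sub.data.groupby(["gene_id", "species"]):
            if on == "medians":
                vals = grp.groupby("tissue")["value"].median().to_numpy()
            else:
                vals = grp["value"].to_numpy()
            cv, reason = compute_cv(vals)
            rows.append((gene, sp, mode, label, cv, len(vals), reason))
    else:
        species_set = ",".join(sorted(sub.species_present))
        if sub.data["species"].nunique() < 2:
            raise SelectionError(
                "cv_species needs >= 2 species in the selection"
            )
        for (gene, tissue), grp in sub.data.groupby(["gene_id", "tissue"]):
            if on == "medians":
                vals = grp.groupby("species")["value"].median().to_numpy()
            else:
                vals = grp["value"].to_numpy()
            cv, reason = compute_cv(vals)
            rows.append((gene, species_set, mode, tissue, cv, len(vals),
                         reason))
    frame = pd.DataFrame(rows, columns=list(CVResult.COLUMNS))
    return CVResult(frame.sort_values(list(CVResult.NATURAL_KEY))
                    .reset_index(drop=True))


def _slice_for_mode(matrix: pd.DataFrame, spec: SelectionSpec,
                    mode: str) -> pd.DataFrame:
    """Apply the DS-mode slicing rules to one species' genes × tissues
    frame. The *_all modes keep every tissue (gene modes) or every gene
    (tissue modes) regardless of the selection."""
    genes = list(spec.genes) if spec.genes else list(matrix.index)
    tissues = list(spec.tissues) if spec.tissues else list(matrix.columns)
    missing_g = [g for g in genes if g not in matrix.index]
    missing_t = [t for t in tissues if t not in matrix.columns]
    if missing_g or missing_t:
        raise SelectionError(
            f"selection not present in matrix: genes {missing_g}, "
            f"tissues {missing_t}"
        )
    if mode == "ds_gene":
        return matrix.loc[genes, tissues]
    if mode == "ds_gene_all":
        return matrix.loc[genes, :]
    if mode == "ds_tissue":
        return matrix.loc[genes, tissues]
    if mode == "ds_tissue_all":
        return matrix.loc[:, tissues]
    raise ValidationError(f"unknown DS mode {mode!r}")


def ds_analysis(matrix: MedianMatrix, spec: SelectionSpec,
                mode: str) -> DSResult:
    """Diversity/specificity analysis over a tissue-axis median matrix.

    Per species: slice per the mode, min–max rescale each gene row, then
    compute gene-level metrics from each gene's profile over tissues
    (``ds_gene``/``ds_gene_all``) or tissue-level metrics from each
    tissue's profile over genes (``ds_tissue``/``ds_tissue_all``).

    Degenerate gene rows (constant nonzero before scaling) are resolved
    to a uniform profile and flagged; all-zero or all-missing rows are
    emitted with missing metrics.
    """
    if mode not in DS_MODES:
        raise ValidationError(f"mode must be one of {DS_MODES}, got {mode!r}")
    if matrix.axis != "tissue":
        raise ValidationError("ds_analysis requires a tissue-axis matrix")

    species_list = sorted(matrix.values.index.get_level_values("species")
                          .unique())
    if spec.species:
        unknown = [s for s in spec.species if s not in species_list]
        if unknown:
            raise SelectionError(f"species not in matrix: {unknown}")
        species_list = list(spec.species)

    rows = []
    for sp in species_list:
        full = matrix.for_species(sp)
        sliced = _slice_for_mode(full, spec, mode)
        if sliced.shape[0] < 2 or sliced.shape[1] < 2:
            raise ValidationError(
                f"species {sp!r}: DS needs >= 2 genes and >= 2 tissues "
                f"after slicing, got {sliced.shape}"
            )
        scaled, degenerate = minmax_scale_rows(sliced)
        n_tissues = sliced.shape[1]
        n_genes = sliced.shape[0]

        if mode in ("ds_gene", "ds_gene_all"):
            for gene in sliced.index:
                raw = sliced.loc[gene]
                flags = []
                if raw.isna().all() or (raw.fillna(0.0) == 0).all():
                    rows.append(("gene", gene, sp, mode, np.nan, np.nan,
                                 n_tissues, "missing"))
                    continue
                if degenerate[gene]:
                    # constant nonzero row: uniform profile by convention
                    p = ProbabilityProfile.from_values(
                        np.ones(n_tissues), sliced.columns.astype(str))
                    flags.append("degenerate")
                else:
                    p = ProbabilityProfile.from_values(
                        scaled.loc[gene].fillna(0.0).to_numpy(),
                        sliced.columns.astype(str))
                d, s = gene_diversity_specificity(p)
                rows.append(("gene", gene, sp, mode, d, s, n_tissues,
                             ";".join(flags) or ""))
        else:
            # tissue modes need well-defined gene rows: resolve degenerate
            # nonzero rows to uniform, drop all-zero rows from the profile
            work = scaled.copy()
            for gene in sliced.index:
                raw = sliced.loc[gene]
                if raw.isna().all() or (raw.fillna(0.0) == 0).all():
                    work.loc[gene] = 0.0
                elif degenerate[gene]:
                    work.loc[gene] = 1.0 / n_tissues
            for tissue in sliced.columns:
                col = work[tissue].fillna(0.0)
                if col.sum() <= 0:
                    rows.append(("tissue", tissue, sp, mode, np.nan, np.nan,
                                 n_genes, "all_zero_column"))
                    continue
                d, s = tissue_diversity_specificity(work.fillna(0.0), tissue)
                flag = "has_degenerate_genes" if degenerate.any() else ""
                rows.append(("tissue", tissue, sp, mode, d, s, n_genes, flag))

    frame = pd.DataFrame(rows, columns=list(DSResult.COLUMNS))
    return DSResult(frame.sort_values(list(DSResult.NATURAL_KEY))
                    .reset_index(drop=True))


def ds_from_expression(table: ExpressionTable, spec: SelectionSpec,
                       mode: str) -> DSResult:
    """Convenience: build the tissue-axis median matrix from a VST table
    and run :func:`ds_analysis`."""
    matrix = median_by_group(table, axis="tissue")
    return ds_analysis(matrix, spec, mode)
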