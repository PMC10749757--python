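"""Expression preprocessing: TPM, variance stabilization, group medians,
min–max rescaling.

The variance-stabilizing transformation assumes a negative-binomial
mean–variance relationship ``Var = mu + alpha(mu) * mu^2`` with a
parametric dispersion trend ``alpha(mu) = a0 + a1/mu`` (an asymptotic
dispersion plus an extra-Poisson term). Under that trend the stabilizer
has a closed form; ``vst_transform`` applies it elementwise. The trend is
estimated from the data by method-of-moments per-gene dispersions followed
by an unweighted least-squares fit — deliberately simple, anchored by a
quadrature oracle in the test suite.

Input to the dispersion fit and the transform may be non-integer: the
pipeline applies the stabilizer to TPM values, treating them as
count-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FitError, FormatError, ValidationError
from .expression_store import ExpressionTable

#: genes with fewer usable moment estimates than this abort the trend fit
MIN_GENES_FOR_FIT = 10


@dataclass(frozen=True)
class DispersionTrend:
    """Fitted NB dispersion trend ``alpha(mu) = a0 + a1/mu``.

    ``a0`` is the asymptotic (high-expression) dispersion, ``a1`` the
    extra-Poisson term dominating at low means; both dimensionless.
    """

    a0: float
    a1: float
    n_genes_used: int = 0

    def __post_init__(self) -> None:
        if not (self.a0 > 0):
            raise ValidationError(f"a0 must be > 0, got {self.a0}")
        if self.a1 < 0:
            raise ValidationError(f"a1 must be >= 0, got {self.a1}")

    def alpha(self, mu):
        """Dispersion at mean ``mu``."""
        mu = np.asarray(mu, dtype=float)
        return self.a0 + self.a1 / np.maximum(mu, 1e-300)


@dataclass
class MedianMatrix:
    """Per-group median VST values for one slicing of an expression table.

    ``values`` has a (gene_id, species) row MultiIndex and tissue columns
    when ``axis == "tissue"``, or a (gene_id, tissue) row MultiIndex and
    species columns when ``axis == "species"``. Cells for groups with no
    samples are NaN — explicitly missing, never zero-filled.
    """

    values: pd.DataFrame
    axis: str
    provenance: dict = field(default_factory=dict)

    def for_species(self, species: str) -> pd.DataFrame:
        """Genes × tissues frame for one species (axis must be tissue)."""
        if self.axis != "tissue":
            raise ValidationError("for_species requires a tissue-axis matrix")
        sub = self.values.xs(species, level="species")
        return sub


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read the gene-length TSV (``gene_id, length_bases``; header
    required) into a Series indexed by gene id."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length_bases"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    lengths = df.set_index("gene_id")["length_bases"].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValidationError(f"non-positive length for gene {bad!r}")
    return lengths


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a gene × sample count matrix.

    Per sample: ``rate_g = count_g / (length_g / 1000)`` then rates are
    scaled to sum to 1e6, so every column of the result sums to one
    million.
    """
    counts = counts.astype(float)
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()][:5])
        raise ValidationError(f"no length for gene(s) {missing}")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("counts must be >= 0")
    rates = counts.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"sample(s) with all-zero counts: {list(zero.index)}"
        )
    return rates.div(totals, axis=1) * 1e6


def fit_dispersion_trend(values) -> DispersionTrend:
    """Fit ``alpha(mu) = a0 + a1/mu`` from a gene × sample matrix.

    Per-gene moment dispersions ``alpha_g = max(0, (s2_g - mean_g) /
    mean_g^2)`` are computed with the n-1 variance, then the trend is fit
    by unweighted least squares on genes with ``alpha_g > 0`` and
    ``mean_g > 1``. If the unconstrained fit leaves the parameter region
    (a0 <= 0 or a1 < 0) it is refit under nonnegativity, with a0 floored
    at 1e-8 so near-Poisson data yields a valid (vanishing) asymptote.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D gene × sample matrix")
    n_genes, n_samples = arr.shape
    if n_genes < MIN_GENES_FOR_FIT or n_samples < 2:
        raise FitError(
            f"need >= {MIN_GENES_FOR_FIT} genes and >= 2 samples; "
            f"got {n_genes} × {n_samples}"
        )
    mu = arr.mean(axis=1)
    s2 = arr.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = (s2 - mu) / np.square(mu)
    usable = (mu > 1) & np.isfinite(alpha_hat) & (alpha_hat > 0)
    if usable.sum() < MIN_GENES_FOR_FIT:
        raise FitError(
            f"only {int(usable.sum())} genes have positive moment "
            f"dispersion and mean > 1; need >= {MIN_GENES_FOR_FIT}"
        )
    a = alpha_hat[usable]
    m = mu[usable]
    design = np.column_stack([np.ones_like(m), 1.0 / m])
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    if a0 <= 0 or a1 < 0:
        from scipy.optimize import nnls
        coef, _ = nnls(design, a)
        a0, a1 = float(coef[0]), float(coef[1])
    a0 = max(a0, 1e-8)
    a1 = max(a1, 0.0)
    return DispersionTrend(a0=a0, a1=a1, n_genes_used=int(usable.sum()))


def vst_transform(values, trend: DispersionTrend):
    """Closed-form variance stabilizer for the NB family with trend
    ``alpha(mu) = a0 + a1/mu``, applied elementwise:

    ``f(q) = log2( (1 + a1 + 2 a0 q + 2 sqrt(a0 q (1 + a1 + a0 q)))
    / (4 a0) )``

    Strictly increasing in ``q``, with a ``log2 q`` tail at high
    expression. Accepts arrays, DataFrames or scalars of nonnegative
    finite values.
    """
    is_frame = isinstance(values, pd.DataFrame)
    arr = np.asarray(values.to_numpy() if is_frame else values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite input to vst_transform")
    if (arr < 0).any():
        raise ValidationError("vst_transform requires nonnegative input")
    a0, a1 = trend.a0, trend.a1
    q = arr
    out = np.log2(
        (1.0 + a1 + 2.0 * a0 * q
         + 2.0 * np.sqrt(a0 * q * (1.0 + a1 + a0 * q))) / (4.0 * a0)
    )
    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def log2p1_transform(values):
    """``log2(x + 1)`` fallback for tables too small to fit a trend.

    Opt-in only — never the default stabilizer.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)) or (arr < 0).any():
        raise ValidationError("log2p1_transform requires finite nonnegative input")
    return np.log2(arr + 1.0)


def vst_expression(table: ExpressionTable,
                   trend: DispersionTrend | None = None,
                   fallback_log2: bool = False) -> ExpressionTable:
    """Stabilize an expression table's values, returning a scale=vst copy.

    With no ``trend`` given, one trend is fitted per species from that
    species' gene × sample matrix (samples keyed by tissue+sample id) and
    applied to its records; the fitted parameters are recorded in the
    table's provenance. With ``fallback_log2`` and too few genes to fit,
    ``log2(x+1)`` is used instead and flagged in provenance.
    """
    if table.scale == "vst":
        raise ValidationError("table is already on the vst scale")
    df = table.data
    out = np.empty(len(df), dtype=float)
    trends: dict[str, tuple] = {}
    for sp, idx in df.groupby("species").groups.items():
        sub = df.loc[idx]
        if trend is not None:
            sp_trend = trend
        else:
            wide = sub.pivot_table(
                index="gene_id", columns=["tissue", "sample_id"],
                values="value",
            )
            try:
                sp_trend = fit_dispersion_trend(wide.to_numpy())
            except FitError:
                if not fallback_log2:
                    raise
                out[df.index.get_indexer(idx)] = log2p1_transform(
                    sub["value"].to_numpy())
                trends[sp] = ("log2p1",)
                continue
        out[df.index.get_indexer(idx)] = vst_transform(
            sub["value"].to_numpy(), sp_trend)
        trends[sp] = (sp_trend.a0, sp_trend.a1, sp_trend.n_genes_used)
    return table.with_values(out, scale="vst", vst_trends=trends)


def median_by_group(table: ExpressionTable, axis: str) -> MedianMatrix:
    """Median expression per (gene, group) cell of a VST table.

    ``axis="tissue"``: rows are (gene, species), columns tissues, each
    cell the median over that tissue's samples. ``axis="species"``: rows
    are (gene, tissue), columns species. Even sample counts take the
    midpoint of the two central values; cells without samples stay NaN.
    """
    if axis not in ("tissue", "species"):
        raise ValidationError(f"axis must be 'tissue' or 'species', got {axis!r}")
    if len(table) == 0:
        raise ValidationError("empty expression table")
    if table.scale != "vst":
        raise ValidationError(
            f"median_by_group expects a vst-scale table, got {table.scale!r}"
        )
    other = "species" if axis == "tissue" else "tissue"
    wide = table.data.pivot_table(
        index=["gene_id", other], columns=axis, values="value",
        aggfunc="median",
    )
    wide.columns.name = axis
    return MedianMatrix(values=wide, axis=axis,
                        provenance={"scale": table.scale})


def minmax_scale(values):
    """Rescale a vector to [0, 1] by ``(x - min) / (max - min)``.

    Returns ``(scaled, degenerate)``. A constant vector maps to all
    zeros with ``degenerate=True``; NaN entries propagate; an all-missing
    vector is an error.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValidationError("minmax_scale: no finite values")
    lo = np.nanmin(arr[finite])
    hi = np.nanmax(arr[finite])
    if hi == lo:
        out = np.where(finite, 0.0, np.nan)
        return out, True
    out = (arr - lo) / (hi - lo)
    return out, False


def minmax_scale_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Min–max scale each row of a genes × groups frame independently.

    Returns the scaled frame and a boolean Series flagging degenerate
    (constant) rows. Scaling per gene row keeps each gene's profile in
    [0, 1] regardless of its absolute expression level.
    """
    scaled = np.empty(matrix.shape, dtype=float)
    flags = []
    for i, (_, row) in enumerate(matrix.iterrows()):
        s, degenerate = minmax_scale(row.to_numpy())
        scaled[i] = s
        flags.append(degenerate)
    return (pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns),
            pd.Series(flags, index=matrix.index, name="degenerate"))
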