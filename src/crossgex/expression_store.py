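"""Canonical in-memory expression container, validation, filtering and I/O.

Long format is canonical: one record per (gene, species, tissue, sample)
with a single value column and a declared scale (``counts``, ``tpm`` or
``vst``). Wide matrices used by the metrics are derived views, never the
stored representation, because the different analysis modes slice the same
records along different axes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SelectionError, ValidationError
from .species import normalize_species

EXPRESSION_COLUMNS = ("gene_id", "species", "tissue", "sample_id", "value")

VALID_SCALES = ("counts", "tpm", "vst")

#: deterministic output ordering per tabular type, keyed by a frozenset of
#: identifying columns present in the frame
_NATURAL_KEYS = (
    ("gene_id", "species", "tissue", "sample_id"),           # expression
    ("gene_id", "species", "mode", "group_label"),           # CV results
    ("unit", "unit_id", "species", "mode"),                  # DS results
    ("input_id", "from_species", "to_species", "ortholog_entrez"),
    ("input_id", "mapped_id"),                               # id conversion
)


@dataclass
class SelectionSpec:
    """A user selection of genes, tissues and species.

    Empty lists mean "everything". Non-empty entries must resolve against
    the table they are applied to; unresolved names raise rather than
    silently vanishing.
    """

    genes: tuple[str, ...] = ()
    tissues: tuple[str, ...] = ()
    species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.tissues = tuple(self.tissues)
        self.species = tuple(normalize_species(s) for s in self.species)

    def is_empty(self) -> bool:
        return not (self.genes or self.tissues or self.species)


@dataclass
class ExpressionTable:
    """Validated long-format expression records with a declared scale.

    Parameters
    ----------
    data
        Frame with columns ``gene_id, species, tissue, sample_id, value``.
        Species entries may be short names or taxon ids; they are
        normalized to short names.
    scale
        One of ``counts``, ``tpm``, ``vst``. Values must be nonnegative
        for counts and TPM (VST output may be negative at low counts).
    provenance
        Free-form metadata recording how the table was produced.
    """

    data: pd.DataFrame
    scale: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValidationError(
                f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}"
            )
        missing = [c for c in EXPRESSION_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"expression table missing column(s): {missing}")
        df = self.data.loc[:, list(EXPRESSION_COLUMNS)].copy()
        for col in ("gene_id", "tissue", "sample_id"):
            df[col] = df[col].astype(str)
        df["species"] = [normalize_species(s) for s in df["species"]]
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)

        values = df["value"].to_numpy()
        bad = ~np.isfinite(values)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"non-finite value at row {idx}")
        if self.scale in ("counts", "tpm"):
            neg = values < 0
            if neg.any():
                idx = int(np.flatnonzero(neg)[0])
                raise ValidationError(
                    f"negative value {values[idx]} at row {idx} "
                    f"(scale={self.scale} requires values >= 0)"
                )

        key_cols = ["gene_id", "species", "tissue", "sample_id"]
        dup = df.duplicated(subset=key_cols, keep=False)
        if dup.any():
            first = df.loc[dup, key_cols].iloc[0]
            raise ValidationError(
                "duplicate record for "
                f"(gene_id={first['gene_id']!r}, species={first['species']!r}, "
                f"tissue={first['tissue']!r}, sample_id={first['sample_id']!r})"
            )
        self.data = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["gene_id"].unique()))

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["tissue"].unique()))

    @property
    def species_present(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["species"].unique()))

    def with_values(self, values: np.ndarray, scale: str,
                    **provenance) -> "ExpressionTable":
        """Return a copy with the value column replaced (e.g. after a
        transform) and the scale re-declared."""
        df = self.data.copy()
        df["value"] = np.asarray(values, dtype=float)
        prov = dict(self.provenance)
        prov.update(provenance)
        return ExpressionTable(df, scale=scale, provenance=prov)


def read_expression(path: str | Path, scale: str) -> ExpressionTable:
    """Read an expression TSV/CSV with the five canonical columns.

    The delimiter is taken from the extension (``.csv`` -> comma,
    otherwise tab). Header is mandatory; column order is not significant.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    table = ExpressionTable(df, scale=scale,
                            provenance={"source": str(path), "scale": scale})
    return table


def filter_expression(table: ExpressionTable,
                      spec: SelectionSpec) -> ExpressionTable:
    """Return the sub-table matching a selection.

    An all-empty spec returns the table unchanged. Requested names absent
    from the table, or a selection matching zero records, raise
    :class:`SelectionError` — an empty result is never a silent success.
    The result's provenance records how many records were retained.
    """
    if spec.is_empty():
        return table

    df = table.data
    unresolved: list[str] = []
    for attr, col in (("genes", "gene_id"), ("tissues", "tissue"),
                      ("species", "species")):
        wanted = getattr(spec, attr)
        if wanted:
            present = set(df[col].unique())
            unresolved.extend(f"{col}={w!r}" for w in wanted
                              if w not in present)
    if unresolved:
        raise SelectionError(
            "selection names not present in table: " + ", ".join(unresolved)
        )

    mask = pd.Series(True, index=df.index)
    if spec.genes:
        mask &= df["gene_id"].isin(spec.genes)
    if spec.tissues:
        mask &= df["tissue"].isin(spec.tissues)
    if spec.species:
        mask &= df["species"].isin(spec.species)
    kept = df[mask]
    if kept.empty:
        raise SelectionError(
            f"selection {spec} matched no records "
            f"(table has {len(df)} records)"
        )
    prov = dict(table.provenance)
    prov["filter"] = {
        "spec": dataclasses.asdict(spec),
        "retained": int(mask.sum()),
        "removed": int((~mask).sum()),
    }
    return ExpressionTable(kept, scale=table.scale, provenance=prov)


def _natural_key_for(df: pd.DataFrame) -> list[str]:
    cols = set(df.columns)
    for key in _NATURAL_KEYS:
        if set(key) <= cols:
            return list(key)
    # fall back to every non-numeric column, left to right
    return [c for c in df.columns if df[c].dtype == object]


def write_table(result, path: str | Path) -> None:
    """Write a tabular result as TSV with header.

    Rows are sorted by the type's natural key so repeated writes of the
    same result are byte-identical; floats are rendered with six
    significant digits.
    """
    if isinstance(result, ExpressionTable):
        df = result.data
    elif isinstance(result, pd.DataFrame):
        df = result
    elif hasattr(result, "frame"):
        df = result.frame
    else:
        raise ValidationError(
            f"cannot write object of type {type(result).__name__}"
        )
    key = _natural_key_for(df)
    if key:
        df = df.sort_values(key, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g",
              lineterminator="\n")
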