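"""Gene identifier conversion and cross-species ortholog mapping.

Both operations are driven entirely by local tables: a per-species
identifier cross-reference (Ensembl id / Entrez id / symbol) and ortholog
group tables in the NCBI ``homologene.data`` dialect (six tab-separated
columns, no header). Genes sharing a group id are treated as orthologs.

One-to-many resolutions (shared symbols, paralog-expanded groups) are
returned exhaustively and flagged, never collapsed to a first match —
a silent collapse would corrupt downstream cross-species joins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .species import SPECIES_TAXA, SUPPORTED_TAXA, TAXON_TO_SPECIES, normalize_species

ID_TYPES = ("ensembl", "entrez", "symbol")

_ID_COLUMNS = {"ensembl": "ensembl_id", "entrez": "entrez_id",
               "symbol": "symbol"}

#: marker written for ids with no mapping
MISSING = "NA"

IDMAP_COLUMNS = ("species", "ensembl_id", "entrez_id", "symbol")

HOMOLOGENE_COLUMNS = ("group_id", "taxon_id", "entrez_id", "symbol",
                      "protein_gi", "protein_accession")


@dataclass
class IdMap:
    """Per-species identifier cross-reference.

    Any field may be absent for a gene (stored as NaN). Within one
    species, Ensembl ids and Entrez ids are unique when present; symbols
    need not be.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in IDMAP_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"IdMap missing column(s): {missing}")
        df = self.data.loc[:, list(IDMAP_COLUMNS)].copy()
        df["species"] = [normalize_species(s) for s in df["species"]]
        for col in ("ensembl_id", "entrez_id", "symbol"):
            df[col] = df[col].astype("string").str.strip()
            df.loc[df[col].isin(["", "NA"]), col] = pd.NA
        for col in ("ensembl_id", "entrez_id"):
            present = df.dropna(subset=[col])
            dup = present.duplicated(subset=["species", col], keep=False)
            if dup.any():
                row = present.loc[dup].iloc[0]
                raise ValidationError(
                    f"duplicate {col} {row[col]!r} within species "
                    f"{row['species']!r}"
                )
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMap":
        """Load the cross-reference TSV (header required; empty string
        means absent)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in IDMAP_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        return cls(df)


@dataclass
class OrthologTable:
    """Parsed ortholog groups in the ``homologene.data`` dialect.

    Records from taxa outside the supported six are dropped on load; the
    drop count is retained so callers can report it.
    """

    data: pd.DataFrame
    n_dropped_taxa: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.loc[:, list(HOMOLOGENE_COLUMNS)].copy()
        df["group_id"] = df["group_id"].astype(int)
        df["taxon_id"] = df["taxon_id"].astype(int)
        for col in ("entrez_id", "symbol", "protein_gi", "protein_accession"):
            df[col] = df[col].astype(str)
        bad_taxa = ~df["taxon_id"].isin(SUPPORTED_TAXA)
        if bad_taxa.any():
            raise ValidationError(
                f"unsupported taxon ids present: "
                f"{sorted(df.loc[bad_taxa, 'taxon_id'].unique())}"
            )
        dup = df.duplicated(subset=["group_id", "taxon_id", "entrez_id"],
                            keep=False)
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicate ortholog record (group {row['group_id']}, "
                f"taxon {row['taxon_id']}, entrez {row['entrez_id']!r})"
            )
        df["species"] = df["taxon_id"].map(TAXON_TO_SPECIES)
        self.data = df.reset_index(drop=True)

    @property
    def n_groups(self) -> int:
        return int(self.data["group_id"].nunique())

    def genes_per_species(self) -> dict[str, int]:
        return self.data.groupby("species")["entrez_id"].nunique().to_dict()


def load_homologene(path: str | Path) -> OrthologTable:
    """Parse a ``homologene.data``-dialect file.

    Six tab-separated columns per line, no header:
    ``group_id, taxon_id, entrez_id, symbol, protein_gi, protein_accession``.
    Lines for unsupported taxa are dropped (real dumps span ~21 taxa);
    the drop count is reported on the returned table. A line with the
    wrong field count is a parse error naming the line number.
    """
    path = Path(path)
    rows: list[tuple] = []
    n_dropped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected 6 tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                group_id = int(fields[0])
                taxon_id = int(fields[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer group/taxon id"
                ) from exc
            if taxon_id not in SUPPORTED_TAXA:
                n_dropped += 1
                continue
            rows.append((group_id, taxon_id, *fields[2:]))
    df = pd.DataFrame(rows, columns=list(HOMOLOGENE_COLUMNS))
    return OrthologTable(df, n_dropped_taxa=n_dropped,
                         provenance={"source": str(path)})


def convert_ids(ids: list[str], from_type: str, to_type: str,
                species: str, idmap: IdMap) -> pd.DataFrame:
    """Convert gene identifiers within one species.

    Returns one row per input id (more when a resolution is one-to-many):
    columns ``input_id, mapped_id, status`` with status in
    ``ok | missing | ambiguous``. Unmapped ids carry the explicit
    ``NA`` marker; ambiguous resolutions are expanded to all matches.
    """
    if from_type not in ID_TYPES or to_type not in ID_TYPES:
        raise ValidationError(
            f"id types must be in {ID_TYPES}; got {from_type!r}->{to_type!r}"
        )
    if from_type == to_type:
        raise ValidationError("from_type and to_type must differ")
    if not ids:
        raise ValidationError("empty id list")
    species = normalize_species(species)

    sub = idmap.data[idmap.data["species"] == species]
    src, dst = _ID_COLUMNS[from_type], _ID_COLUMNS[to_type]

    rows = []
    for input_id in ids:
        matches = sub[sub[src] == input_id].dropna(subset=[dst])
        targets = sorted(matches[dst].unique())
        if not targets:
            rows.append((input_id, MISSING, "missing"))
        elif len(targets) == 1:
            rows.append((input_id, targets[0], "ok"))
        else:
            rows.extend((input_id, t, "ambiguous") for t in targets)
    return pd.DataFrame(rows, columns=["input_id", "mapped_id", "status"])


def map_orthologs(genes: list[str], from_species: str,
                  to_species: list[str],
                  orth: OrthologTable) -> pd.DataFrame:
    """Map genes to their orthologs in target species via shared groups.

    Input genes may be Entrez ids or symbols. For each (gene, target
    species) pair the result holds every group member in that species,
    flagged ``one_to_many`` when more than one; genes with no group, or
    whose group lacks the target species, get a ``NA`` ortholog and a
    reason code (``no_group`` / ``group_lacks_species``).
    """
    if not genes:
        raise ValidationError("empty gene list")
    from_species = normalize_species(from_species)
    targets = [normalize_species(s) for s in to_species]
    if not targets:
        raise ValidationError("empty target species list")
    if from_species in targets:
        raise ValidationError(
            f"from_species {from_species!r} cannot appear in to_species"
        )

    df = orth.data
    from_taxon = SPECIES_TAXA[from_species]
    src = df[df["taxon_id"] == from_taxon]

    rows = []
    for gene in genes:
        hit = src[(src["entrez_id"] == gene) | (src["symbol"] == gene)]
        groups = sorted(hit["group_id"].unique())
        if not groups:
            for sp in targets:
                rows.append((gene, from_species, sp, MISSING, MISSING,
                             "no_group", False))
            continue
        for sp in targets:
            taxon = SPECIES_TAXA[sp]
            members = df[(df["group_id"].isin(groups))
                         & (df["taxon_id"] == taxon)]
            if members.empty:
                rows.append((gene, from_species, sp, MISSING, MISSING,
                             "group_lacks_species", False))
            else:
                many = len(members) > 1 or len(groups) > 1
                for _, m in members.sort_values("entrez_id").iterrows():
                    rows.append((gene, from_species, sp, m["entrez_id"],
                                 m["symbol"], "ok", many))
    return pd.DataFrame(
        rows,
        columns=["input_id", "from_species", "to_species", "ortholog_entrez",
                 "ortholog_symbol", "reason", "one_to_many"],
    )
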