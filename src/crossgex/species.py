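"""Supported species registry.

Six species commonly used in biomedical transcriptomics are supported,
keyed by lowercase short names. NCBI taxon ids are accepted as input
aliases because ortholog group tables are keyed by taxon id.
"""

from __future__ import annotations

from .errors import ValidationError

#: short name -> NCBI taxon id
SPECIES_TAXA: dict[str, int] = {
    "human": 9606,       # Homo sapiens
    "mouse": 10090,      # Mus musculus
    "rat": 10116,        # Rattus norvegicus
    "zebrafish": 7955,   # Danio rerio
    "fly": 7227,         # Drosophila melanogaster
    "worm": 6239,        # Caenorhabditis elegans
}

TAXON_TO_SPECIES: dict[int, str] = {v: k for k, v in SPECIES_TAXA.items()}

SUPPORTED_SPECIES = frozenset(SPECIES_TAXA)
SUPPORTED_TAXA = frozenset(TAXON_TO_SPECIES)


def normalize_species(value: str | int) -> str:
    """Resolve a species short name or NCBI taxon id to the canonical
    lowercase short name.

    Raises
    ------
    ValidationError
        If the value names no supported species.
    """
    if isinstance(value, str):
        name = value.strip().lower()
        if name in SPECIES_TAXA:
            return name
        if name.isdigit():
            value = int(name)
        else:
            raise ValidationError(
                f"unsupported species {value!r}; expected one of "
                f"{sorted(SPECIES_TAXA)} or a taxon id {sorted(TAXON_TO_SPECIES)}"
            )
    if isinstance(value, (int,)):
        try:
            return TAXON_TO_SPECIES[int(value)]
        except KeyError:
            raise ValidationError(
                f"unsupported taxon id {value}; expected one of "
                f"{sorted(TAXON_TO_SPECIES)}"
            ) from None
    raise ValidationError(f"cannot interpret species {value!r}")
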