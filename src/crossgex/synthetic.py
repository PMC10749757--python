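"""Seeded synthetic expression data.

Generates negative-binomial count tables with configurable per-gene
effects across tissues and species, plus the truth table of designed
means, so the preprocessing and metrics layers can be validated against
known structure. The bundled demo dataset reproduces the qualitative
design of a five-gene, two-species, five-tissue example: one gene with
high expression variability across tissues in both species, three flat
genes, and one gene whose tissue-restricted expression appears in only
one of the two species.

The generator emulates structure, not a particular real dataset: library
sizes are homogeneous, tissues are uncorrelated, and there is no batch
effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_store import ExpressionTable
from .preprocessing import DispersionTrend, vst_transform


# ---------------------------------------------------------------------------
# effect catalog

@dataclass(frozen=True)
class Flat:
    """No tissue or species effect: mean = baseline everywhere."""


@dataclass(frozen=True)
class TissueSpecific:
    """Fold-elevated mean in one tissue; optionally only in some species.

    ``species=None`` applies the effect in every species — otherwise the
    gene is flat outside the listed species, which is how species-specific
    variability is encoded.
    """

    tissue: str
    fold: float
    species: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SpeciesVariable:
    """Explicit per-species, per-tissue fold profile."""

    fold_profile: Mapping[str, Mapping[str, float]]


@dataclass(frozen=True)
class HighVar:
    """Strong tissue-to-tissue spread of the mean in every species.

    Per-tissue log-fold offsets are an evenly spaced, centred ramp scaled
    by ``sd_multiplier``; at the default multiplier the extreme tissues
    sit at e^{±2.5} ≈ 12-fold from the middle one.
    """

    sd_multiplier: float = 1.0


Effect = Union[Flat, TissueSpecific, SpeciesVariable, HighVar]


@dataclass
class SimSpec:
    """Design of a synthetic experiment.

    The NB variance follows the same dispersion trend the stabilizer
    assumes: ``Var = mu + (a0 + a1/mu) mu^2``.
    """

    n_genes: int
    n_species: int
    n_tissues: int
    n_samples_per_cell: int
    baseline_mean: float = 100.0
    dispersion: tuple[float, float] = (0.05, 2.0)
    effects: dict[str, Effect] = field(default_factory=dict)
    seed: int | None = None
    species_names: tuple[str, ...] = ("human", "mouse", "rat", "zebrafish",
                                      "fly", "worm")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimSpec.seed is mandatory")
        if min(self.n_genes, self.n_species, self.n_tissues,
               self.n_samples_per_cell) < 1:
            raise ValidationError("all design sizes must be >= 1")
        if self.n_species > len(self.species_names):
            raise ValidationError(
                f"at most {len(self.species_names)} species supported"
            )
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be > 0")
        a0, a1 = self.dispersion
        if a0 < 0 or a1 < 0:
            raise ValidationError("dispersion components must be >= 0")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(f"gene{i + 1}" for i in range(self.n_genes))

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(f"tissue{i + 1}" for i in range(self.n_tissues))

    @property
    def species(self) -> tuple[str, ...]:
        return self.species_names[: self.n_species]


def _fold(effect: Effect, species: str, tissue: str,
          tissues: Sequence[str]) -> float:
    if isinstance(effect, Flat):
        return 1.0
    if isinstance(effect, TissueSpecific):
        if effect.species is not None and species not in effect.species:
            return 1.0
        return effect.fold if tissue == effect.tissue else 1.0
    if isinstance(effect, SpeciesVariable):
        return float(effect.fold_profile.get(species, {}).get(tissue, 1.0))
    if isinstance(effect, HighVar):
        n = len(tissues)
        i = list(tissues).index(tissue)
        # centred ramp in log space; ±2.5 at the extremes for multiplier 1
        z = (i - (n - 1) / 2) * (5.0 / max(n - 1, 1))
        return float(np.exp(z * effect.sd_multiplier))
    raise ValidationError(f"unknown effect {effect!r}")


def _validate_effects(spec: SimSpec) -> None:
    for gene, eff in spec.effects.items():
        if gene not in spec.genes:
            raise ValidationError(f"effect for unknown gene {gene!r}")
        if isinstance(eff, TissueSpecific):
            if eff.tissue not in spec.tissues:
                raise ValidationError(
                    f"effect for {gene!r} names unknown tissue {eff.tissue!r}"
                )
            if eff.fold <= 0:
                raise ValidationError("fold must be > 0")
            if eff.species is not None:
                unknown = [s for s in eff.species if s not in spec.species]
                if unknown:
                    raise ValidationError(
                        f"effect for {gene!r} names unknown species {unknown}"
                    )
        if isinstance(eff, SpeciesVariable):
            for sp, prof in eff.fold_profile.items():
                if sp not in spec.species:
                    raise ValidationError(f"unknown species {sp!r} in profile")
                for t, f in prof.items():
                    if t not in spec.tissues:
                        raise ValidationError(f"unknown tissue {t!r} in profile")
                    if f <= 0:
                        raise ValidationError("folds must be > 0")


def _nb_sample(rng: np.random.Generator, mu: float,
               a0: float, a1: float, size: int) -> np.ndarray:
    """Draw NB counts with mean mu and variance mu + alpha(mu) mu^2."""
    alpha = a0 + (a1 / mu if mu > 0 else 0.0)
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    n = 1.0 / alpha                      # NB size parameter
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


def simulate_counts(spec: SimSpec) -> tuple[ExpressionTable, pd.DataFrame]:
    """Simulate a long-format NB count table plus its truth table.

    The truth table holds the designed mean for every
    (gene, species, tissue) cell. Identical spec + seed gives identical
    output.
    """
    _validate_effects(spec)
    rng = np.random.default_rng(spec.seed)
    a0, a1 = spec.dispersion

    records = []
    truth = []
    for gene in spec.genes:
        eff = spec.effects.get(gene, Flat())
        for sp in spec.species:
            for tissue in spec.tissues:
                mu = spec.baseline_mean * _fold(eff, sp, tissue, spec.tissues)
                truth.append((gene, sp, tissue, mu))
                draws = _nb_sample(rng, mu, a0, a1, spec.n_samples_per_cell)
                for j, c in enumerate(draws):
                    records.append((gene, sp, tissue, f"s{j + 1}", float(c)))
    table = ExpressionTable(
        pd.DataFrame(records, columns=["gene_id", "species", "tissue",
                                       "sample_id", "value"]),
        scale="counts",
        provenance={"simulated": True, "seed": spec.seed,
                    "dispersion": spec.dispersion,
                    "baseline_mean": spec.baseline_mean},
    )
    truth_df = pd.DataFrame(truth, columns=["gene_id", "species", "tissue",
                                            "mu"])
    return table, truth_df


# ---------------------------------------------------------------------------
# the bundled five-gene demonstration design

DEMO_DISPERSION = (0.05, 2.0)
DEMO_BASELINE = 100.0


def demo_spec(seed: int) -> SimSpec:
    """Design of the bundled demonstration dataset: five genes, two
    species (human, mouse), five tissues, four samples per cell.

    gene1/gene3/gene4 are flat; gene5 has strongly tissue-variable means
    in both species (high variability everywhere); gene2 is 16-fold
    enriched in tissue1 in human only (species-specific variability, and
    tissue-restricted in one species but diverse in the other).
    """
    return SimSpec(
        n_genes=5, n_species=2, n_tissues=5, n_samples_per_cell=4,
        baseline_mean=DEMO_BASELINE, dispersion=DEMO_DISPERSION,
        effects={
            "gene2": TissueSpecific(tissue="tissue1", fold=16.0,
                                    species=("human",)),
            "gene5": HighVar(sd_multiplier=1.0),
        },
        seed=seed,
    )


def make_demo_dataset(seed: int) -> ExpressionTable:
    """Simulate the demonstration count table (200 records)."""
    table, _ = simulate_counts(demo_spec(seed))
    return table


def make_demo_vst(seed: int) -> ExpressionTable:
    """Demo counts stabilized with the design's own dispersion trend.

    Five genes are too few to refit the trend from data, so the known
    simulation dispersion is used directly — the point of the demo is
    the downstream metrics, not trend estimation.
    """
    table = make_demo_dataset(seed)
    trend = DispersionTrend(a0=DEMO_DISPERSION[0], a1=DEMO_DISPERSION[1])
    vst = vst_transform(table.data["value"].to_numpy(), trend)
    return table.with_values(vst, scale="vst",
                             vst_trend=(trend.a0, trend.a1))
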