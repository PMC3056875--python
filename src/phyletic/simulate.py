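"""Synthetic presence/absence matrices and essentiality tables.

Real inputs to these analyses are per-genome domain assignments and
knockout-essentiality screens.  This generator emulates their
statistical structure so every stage is testable end to end:

* *Presence.* Families come in classes; each class has a per-clade
  retention probability and a viral carriage rate.  Every
  (family, genome) cell is an independent Bernoulli draw with the
  class's clade-specific probability — clade-structured retention with
  no phylogenetic autocorrelation, which is also the exchangeability
  the downstream statistics implicitly assume.  A class with high
  archaeal and eukaryotic retention and low bacterial retention plants
  LAECA-pattern families; the truth table records each family's class.
* *Essentiality.* Per species, ``n_ribosomal`` ribosomal proteins;
  essentiality is Bernoulli(p_s) outside the designated subset and
  Bernoulli(min(1, p_s * delta)) inside.  ``delta`` < 1 plants the
  "subset is more dispensable" effect the flexibility test looks for;
  ``delta`` = 1 is the null.

A single seed governs all draws through a spawned-stream scheme (one
independent child stream per family class and per species), so adding a
class or species does not perturb draws made by earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CladeLabel,
    EssentialityRecord,
    GenomeRecord,
    PresenceMatrix,
    SchemaError,
)

__all__ = [
    "FamilyClass",
    "SpeciesSpec",
    "SyntheticConfig",
    "generate_presence",
    "generate_essentiality",
]


@dataclass(frozen=True)
class FamilyClass:
    """A block of families sharing retention behaviour.

    ``retention`` maps each cellular clade to the per-genome presence
    probability; ``viral_rate`` is the probability any given viral
    genome carries the family.
    """

    label: str
    n_families: int
    retention: dict[CladeLabel, float]
    viral_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_families < 0:
            raise SchemaError(f"class {self.label!r}: n_families < 0")
        probs = [*self.retention.values(), self.viral_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SchemaError(f"class {self.label!r}: probability outside [0, 1]")

    def presence_probability(self, clade: CladeLabel) -> float:
        if clade is CladeLabel.VIRUS:
            return self.viral_rate
        return self.retention.get(clade, 0.0)


@dataclass(frozen=True)
class SpeciesSpec:
    """One species of the synthetic essentiality block."""

    name: str
    base_essentiality: float
    subset_effect: float = 1.0  # multiplier on essentiality inside the subset

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_essentiality <= 1.0:
            raise SchemaError(f"species {self.name!r}: base_essentiality outside [0, 1]")
        if self.subset_effect < 0.0:
            raise SchemaError(f"species {self.name!r}: subset_effect < 0")


def _default_genomes_per_clade() -> dict[CladeLabel, int]:
    # Clade sizes of the genome collection the coverage rules were framed
    # against: 46 archaea, 35 eukaryotes; the bacterial collection (939
    # historically) is scaled to 100 to keep simulated matrices small,
    # with 60 viral genomes.
    return {
        CladeLabel.ARCHAEA: 46,
        CladeLabel.EUKARYOTA: 35,
        CladeLabel.BACTERIA: 100,
        CladeLabel.VIRUS: 60,
    }


@dataclass
class SyntheticConfig:
    """Everything the generator needs; all draws derive from ``seed``."""

    genomes_per_clade: dict[CladeLabel, int] = field(
        default_factory=_default_genomes_per_clade
    )
    family_classes: list[FamilyClass] = field(default_factory=list)
    species: list[SpeciesSpec] = field(default_factory=list)
    n_ribosomal: int = 55
    subset_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.genomes_per_clade.values()):
            raise SchemaError("genome counts must be >= 0")
        if not 0 <= self.subset_size <= self.n_ribosomal:
            raise SchemaError("require 0 <= subset_size <= n_ribosomal")


#: stream-splitting keys: presence draws and essentiality draws never share
#: a child stream, and each class/species gets its own spawn position.
_PRESENCE_STREAM = 0
_ESSENTIALITY_STREAM = 1


def _genome_records(config: SyntheticConfig) -> list[GenomeRecord]:
    clade_tag = {
        CladeLabel.ARCHAEA: "arc",
        CladeLabel.BACTERIA: "bac",
        CladeLabel.EUKARYOTA: "euk",
        CladeLabel.VIRUS: "vir",
    }
    records = []
    for clade in CladeLabel:
        for i in range(config.genomes_per_clade.get(clade, 0)):
            records.append(GenomeRecord(f"{clade_tag[clade]}{i:04d}", clade))
    return records


def generate_presence(
    config: SyntheticConfig,
) -> tuple[PresenceMatrix, list[GenomeRecord], pd.DataFrame]:
    """Draw a presence matrix plus its genome set and truth table.

    The truth table has columns ``family_id`` and ``class_label`` and
    one row per family, in matrix order.  Reproducible from the seed.
    """
    genomes = _genome_records(config)
    genome_ids = [g.genome_id for g in genomes]
    clades = np.array([g.clade.value for g in genomes])

    root = np.random.SeedSequence(config.seed)
    presence_seed = root.spawn(2)[_PRESENCE_STREAM]
    class_streams = presence_seed.spawn(len(config.family_classes))

    blocks: list[np.ndarray] = []
    family_ids: list[str] = []
    class_labels: list[str] = []
    for cls, stream in zip(config.family_classes, class_streams):
        rng = np.random.default_rng(stream)
        probs = np.empty(len(genomes))
        for clade in CladeLabel:
            probs[clades == clade.value] = cls.presence_probability(clade)
        block = (rng.random((cls.n_families, len(genomes))) < probs).astype(np.int8)
        blocks.append(block)
        start = len(family_ids)
        family_ids.extend(
            f"{cls.label}_{start + i:05d}" for i in range(cls.n_families)
        )
        class_labels.extend([cls.label] * cls.n_families)

    data = (
        np.vstack(blocks)
        if blocks
        else np.empty((0, len(genomes)), dtype=np.int8)
    )
    frame = pd.DataFrame(
        data, index=pd.Index(family_ids, dtype=object), columns=genome_ids
    )
    truth = pd.DataFrame({"family_id": family_ids, "class_label": class_labels})
    return PresenceMatrix(frame), genomes, truth


def generate_essentiality(config: SyntheticConfig) -> list[EssentialityRecord]:
    """Draw the per-species essentiality table.

    The first ``subset_size`` proteins of each species carry the
    target-subset flag; all proteins are ribosomal.  Reproducible from
    the seed.
    """
    root = np.random.SeedSequence(config.seed)
    ess_seed = root.spawn(2)[_ESSENTIALITY_STREAM]
    species_streams = ess_seed.spawn(len(config.species))

    records: list[EssentialityRecord] = []
    for spec, stream in zip(config.species, species_streams):
        rng = np.random.default_rng(stream)
        p_in = min(1.0, spec.base_essentiality * spec.subset_effect)
        n, s = config.n_ribosomal, config.subset_size
        probs = np.full(n, spec.base_essentiality)
        probs[:s] = p_in
        essential = rng.random(n) < probs
        for i in range(n):
            records.append(
                EssentialityRecord(
                    species=spec.name,
                    protein_id=f"{spec.name}_rp{i:03d}",
                    is_ribosomal=True,
                    is_essential=bool(essential[i]),
                    in_target_subset=i < s,
                )
            )
    return records
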