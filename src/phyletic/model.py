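"""Core domain types shared by every analysis stage.

The analyses operate on three kinds of data:

* a genome collection, each genome labelled with one of four clades
  (archaea, bacteria, eukaryota, virus) — the clade sizes are the fixed
  denominators for all coverage fractions;
* a binary family-by-genome presence/absence matrix (a phyletic pattern
  per family), where presence means "at least one occurrence of the
  family in that genome";
* per-species protein essentiality records for the ribosomal
  flexibility test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CladeLabel",
    "GenomeRecord",
    "PresenceMatrix",
    "EssentialityRecord",
    "AnalysisConfig",
    "PhyleticError",
    "SchemaError",
    "InvariantError",
    "clade_counts",
]


class PhyleticError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PhyleticError):
    """Malformed or invalid input data (bad file, bad value, bad reference)."""


class InvariantError(PhyleticError):
    """An internal consistency condition was violated."""


class CladeLabel(enum.Enum):
    """The four top-level clades genomes are assigned to.

    Exactly these four labels exist; any other clade string in input is
    an error and is never silently coerced.
    """

    ARCHAEA = "archaea"
    BACTERIA = "bacteria"
    EUKARYOTA = "eukaryota"
    VIRUS = "virus"

    @classmethod
    def parse(cls, value: str) -> "CladeLabel":
        try:
            return cls(value.strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise SchemaError(
                f"unknown clade {value!r}; valid clades are: {valid}"
            ) from None


#: Clades whose genomes are cellular organisms (everything but viruses).
CELLULAR_CLADES = (CladeLabel.ARCHAEA, CladeLabel.BACTERIA, CladeLabel.EUKARYOTA)


@dataclass(frozen=True)
class GenomeRecord:
    """A single genome with its clade assignment."""

    genome_id: str
    clade: CladeLabel
    display_name: str | None = None


def clade_counts(genomes: list[GenomeRecord]) -> dict[CladeLabel, int]:
    """Number of genomes per clade — the coverage denominators.

    Denominators always come from the genome metadata (the full surveyed
    collection), never from whichever genomes happen to carry families.
    """
    counts = {c: 0 for c in CladeLabel}
    for g in genomes:
        counts[g.clade] += 1
    return counts


@dataclass(frozen=True)
class EssentialityRecord:
    """One protein in one species, with knockout-essentiality flags.

    ``in_target_subset`` marks membership in the designated ribosomal
    subset under test (e.g. the bacterial ribosomal proteins never found
    in archaea); it implies ``is_ribosomal``.
    """

    species: str
    protein_id: str
    is_ribosomal: bool
    is_essential: bool
    in_target_subset: bool

    def __post_init__(self) -> None:
        if self.in_target_subset and not self.is_ribosomal:
            raise SchemaError(
                f"protein {self.protein_id!r} of species {self.species!r}: "
                "in_target_subset requires is_ribosomal"
            )


class PresenceMatrix:
    """Binary family-by-genome presence/absence matrix.

    Wraps a pandas DataFrame with family ids as the index and genome ids
    as the columns; every cell is 0 or 1.  Family and genome ids are each
    unique.  Construction validates; the frame is treated as immutable
    afterwards.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate family_id(s): {dups}")
        if frame.columns.has_duplicates:
            dups = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate genome_id(s): {dups}")
        values = frame.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise SchemaError(
                f"non-binary presence value {values[tuple(bad)]!r} at "
                f"family {frame.index[bad[0]]!r}, genome {frame.columns[bad[1]]!r}"
            )
        self._frame = frame.astype(np.int8)

    @classmethod
    def from_long(
        cls, pairs: list[tuple[str, str]], genome_ids: list[str]
    ) -> "PresenceMatrix":
        """Build from (family_id, genome_id) pairs over a full genome set.

        Repeated pairs collapse to a single presence; genomes with no
        families still appear as all-zero columns (they dilute coverage).
        """
        genome_index = pd.Index(genome_ids, dtype=object)
        if genome_index.has_duplicates:
            raise SchemaError("duplicate genome ids in genome set")
        known = set(genome_ids)
        families: list[str] = []
        seen: set[str] = set()
        for fam, gen in pairs:
            if gen not in known:
                raise SchemaError(
                    f"genome_id {gen!r} (family {fam!r}) absent from metadata"
                )
            if fam not in seen:
                seen.add(fam)
                families.append(fam)
        frame = pd.DataFrame(
            0, index=pd.Index(families, dtype=object), columns=genome_index,
            dtype=np.int8,
        )
        for fam, gen in pairs:
            frame.at[fam, gen] = 1
        return cls(frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def family_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def genome_ids(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def require_families(self, family_ids: list[str]) -> None:
        missing = [f for f in family_ids if f not in self._frame.index]
        if missing:
            raise SchemaError(f"unknown family id(s): {missing}")

    def check_genomes(self, genomes: list[GenomeRecord]) -> None:
        """Every matrix genome must resolve to a metadata record."""
        known = {g.genome_id for g in genomes}
        missing = [g for g in self.genome_ids if g not in known]
        if missing:
            raise SchemaError(
                f"matrix genome id(s) absent from metadata: {missing}"
            )

    def genomes_with_family(
        self, family_id: str, genome_ids: list[str]
    ) -> int:
        """Count of the given genomes carrying the family (0 if none listed)."""
        self.require_families([family_id])
        present = [g for g in genome_ids if g in self._frame.columns]
        if not present:
            return 0
        return int(self._frame.loc[family_id, present].sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        nf, ng = self.shape
        return f"PresenceMatrix({nf} families x {ng} genomes)"


@dataclass
class AnalysisConfig:
    """Run-level knobs shared across stages.

    ``resample_count`` is the number of random family sets drawn for the
    enrichment null (10000 by default).  ``exclusion_families`` are
    dropped from the occupancy mean when requested (e.g. the two
    PolB-related families).  ``rounding_digits`` controls display
    rounding in TSV reports only; internal values keep full precision.
    """

    resample_count: int = 10_000
    exclusion_families: list[str] = field(default_factory=list)
    random_seed: int = 0
    rounding_digits: int = 4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.resample_count < 1:
            raise SchemaError("resample_count must be >= 1")
        if self.rounding_digits < 0:
            raise SchemaError("rounding_digits must be >= 0")
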