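"""Clade-coverage profiling and threshold classification of family origins.

A family's *coverage* in a clade is the fraction of that clade's genomes
carrying it, with the denominator taken from the genome metadata (the
full surveyed collection).  An :class:`OriginRule` assigns an
ancestral-origin label when coverage is at least a minimum in every
"include" clade and strictly below a maximum in every "exclude" clade.

The two canonical rules mirror the ancestral-content definitions used in
comparative-genomics surveys of the superkingdoms:

* ``LAECA_ORIGIN`` — at least 90% of archaeal and 90% of eukaryotic
  genomes, under 50% of bacterial genomes: the family traces to the last
  archaeal-eukaryotic common ancestor.  The 90% cutoff is strict enough
  to imply ancestral presence; the 50% cutoff tolerates recent
  horizontal transfers into bacteria.
* ``LBCA_ORIGIN`` — the symmetric rule (bacteria >= 90%, archaea and
  eukaryotes < 50%) for the last bacterial common ancestor.

Viral coverage is profiled and reported but never thresholded: viruses
carry cellular families by exchange, not descent from these ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .model import (
    CELLULAR_CLADES,
    CladeLabel,
    GenomeRecord,
    InvariantError,
    PresenceMatrix,
    SchemaError,
    clade_counts,
)

__all__ = [
    "OriginRule",
    "CoverageProfile",
    "OriginCall",
    "LAECA_RULE",
    "LBCA_RULE",
    "DEFAULT_RULES",
    "compute_coverage",
    "classify_family",
    "classify_all",
]

NO_CALL = "NONE"


def _as_fraction(threshold: float | int | Fraction) -> Fraction:
    """Read a threshold as the decimal it was written as.

    A float literal like 0.9 means the rational 9/10, not the nearest
    binary double (which is a hair above it); going through the shortest
    decimal repr keeps boundary comparisons exact, so coverage of
    exactly 90% satisfies "at least 90%" and exactly 50% fails
    "less than 50%".
    """
    if isinstance(threshold, Fraction):
        return threshold
    return Fraction(str(threshold))


@dataclass(frozen=True)
class OriginRule:
    """Threshold rule assigning one ancestral-origin label.

    ``include_clades`` maps a clade to its minimum coverage ("at least",
    inclusive >=); ``exclude_clades`` maps a clade to its maximum
    coverage ("less than", strict <).  The two clade sets must be
    disjoint and all thresholds lie in [0, 1].
    """

    label: str
    include_clades: dict[CladeLabel, float] = field(default_factory=dict)
    exclude_clades: dict[CladeLabel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.include_clades) & set(self.exclude_clades)
        if overlap:
            raise SchemaError(
                f"rule {self.label!r}: clades {sorted(c.value for c in overlap)} "
                "appear in both include and exclude sets"
            )
        for threshold in (*self.include_clades.values(), *self.exclude_clades.values()):
            if not 0.0 <= threshold <= 1.0:
                raise SchemaError(
                    f"rule {self.label!r}: threshold {threshold} outside [0, 1]"
                )

    def matches(self, profile: "CoverageProfile") -> bool:
        for clade, minimum in self.include_clades.items():
            if not profile.coverage(clade) >= _as_fraction(minimum):
                return False
        for clade, maximum in self.exclude_clades.items():
            if not profile.coverage(clade) < _as_fraction(maximum):
                return False
        return True


LAECA_RULE = OriginRule(
    label="LAECA_ORIGIN",
    include_clades={CladeLabel.ARCHAEA: 0.90, CladeLabel.EUKARYOTA: 0.90},
    exclude_clades={CladeLabel.BACTERIA: 0.50},
)

LBCA_RULE = OriginRule(
    label="LBCA_ORIGIN",
    include_clades={CladeLabel.BACTERIA: 0.90},
    exclude_clades={CladeLabel.ARCHAEA: 0.50, CladeLabel.EUKARYOTA: 0.50},
)

DEFAULT_RULES = [LAECA_RULE, LBCA_RULE]


@dataclass(frozen=True)
class CoverageProfile:
    """Per-clade presence counts and coverage fractions for one family.

    Coverage is stored as the exact rational present/total so threshold
    comparisons are free of floating-point surprises at the boundaries
    (e.g. 0.50 is never "less than 50%").
    """

    family_id: str
    genomes_present: dict[CladeLabel, int]
    genomes_total: dict[CladeLabel, int]

    def __post_init__(self) -> None:
        for clade in self.genomes_present:
            if self.genomes_present[clade] > self.genomes_total[clade]:
                raise InvariantError(
                    f"family {self.family_id!r}: present > total in {clade.value}"
                )

    def coverage(self, clade: CladeLabel) -> Fraction:
        total = self.genomes_total[clade]
        if total == 0:
            raise SchemaError(
                f"clade {clade.value!r} has zero genomes; coverage is undefined "
                "and cannot be thresholded"
            )
        return Fraction(self.genomes_present[clade], total)

    def as_row(self) -> dict:
        row: dict = {"family_id": self.family_id}
        for clade in CladeLabel:
            row[f"{clade.value}_present"] = self.genomes_present[clade]
            row[f"{clade.value}_total"] = self.genomes_total[clade]
            total = self.genomes_total[clade]
            row[f"{clade.value}_coverage"] = (
                self.genomes_present[clade] / total if total else float("nan")
            )
        return row


@dataclass(frozen=True)
class OriginCall:
    """A family's origin label (or NONE) with its coverage profile."""

    family_id: str
    label: str
    profile: CoverageProfile


def compute_coverage(
    matrix: PresenceMatrix,
    genomes: list[GenomeRecord],
    family_id: str,
) -> CoverageProfile:
    """Coverage profile of one family over the full genome collection."""
    matrix.require_families([family_id])
    matrix.check_genomes(genomes)
    totals = clade_counts(genomes)
    by_clade: dict[CladeLabel, list[str]] = {c: [] for c in CladeLabel}
    for g in genomes:
        by_clade[g.clade].append(g.genome_id)
    present = {
        clade: matrix.genomes_with_family(family_id, ids)
        for clade, ids in by_clade.items()
    }
    return CoverageProfile(family_id, present, totals)


def classify_family(
    profile: CoverageProfile, rules: list[OriginRule]
) -> OriginCall:
    """Apply the rules to one coverage profile.

    Exactly one rule may match; two matching rules indicate
    misconfigured (non-exclusive) thresholds and raise.  No match yields
    the NONE label.
    """
    matched = [rule for rule in rules if rule.matches(profile)]
    if len(matched) > 1:
        labels = [r.label for r in matched]
        raise SchemaError(
            f"family {profile.family_id!r}: rules {labels} all match; "
            "rules must be mutually exclusive on the data"
        )
    label = matched[0].label if matched else NO_CALL
    return OriginCall(profile.family_id, label, profile)


def classify_all(
    matrix: PresenceMatrix,
    genomes: list[GenomeRecord],
    rules: list[OriginRule],
) -> list[OriginCall]:
    """Classify every family in the matrix, preserving family order.

    Only clades referenced by some rule need genomes; a clade with zero
    genomes that a rule thresholds raises on the first family.
    """
    matrix.check_genomes(genomes)
    totals = clade_counts(genomes)
    by_clade: dict[CladeLabel, list[str]] = {c: [] for c in CladeLabel}
    for g in genomes:
        by_clade[g.clade].append(g.genome_id)
    # one matrix-slice sum per clade instead of one per (family, clade)
    in_matrix = set(matrix.genome_ids)
    present_per_clade = {}
    for clade, ids in by_clade.items():
        ids = [g for g in ids if g in in_matrix]
        present_per_clade[clade] = (
            matrix.frame[ids].to_numpy().sum(axis=1)
            if ids
            else [0] * len(matrix.family_ids)
        )
    calls = []
    for i, fam in enumerate(matrix.family_ids):
        profile = CoverageProfile(
            fam,
            {clade: int(present_per_clade[clade][i]) for clade in CladeLabel},
            totals,
        )
        calls.append(classify_family(profile, rules))
    return calls


def call_summary(calls: list[OriginCall]) -> dict[str, int]:
    """Number of families per assigned label (including NONE)."""
    summary: dict[str, int] = {}
    for call in calls:
        summary[call.label] = summary.get(call.label, 0) + 1
    return summary
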