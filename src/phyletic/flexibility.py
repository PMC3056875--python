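"""Per-species binomial test of ribosomal-subset flexibility.

The question: is a designated subset of ribosomal proteins (e.g. the
bacterial ribosomal proteins never found in archaea) *less essential*
than ribosomal proteins in general in that species?

For each species the base rate p̂ is the proportion of all assayed
ribosomal proteins found essential there — estimated per species rather
than pooled, because knockout screens differ in thoroughness and a
pooled rate would import those biases.  With n subset proteins of which
k are essential, the reported p-value is the exact lower binomial tail

    P(X <= k),  X ~ Binomial(n, p̂)

— the probability that a random draw of n ribosomal proteins would
contain at most k essential ones.  A small p-value means the subset is
unusually dispensable.  No normal approximation and no multiple-testing
correction are applied; the report flags species below a configurable
alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .model import EssentialityRecord, SchemaError

__all__ = [
    "FlexibilityResult",
    "estimate_base_rate",
    "binomial_tail_p",
    "flexibility_test",
    "flexibility_table",
]


@dataclass(frozen=True)
class FlexibilityResult:
    """One species' row of the flexibility report."""

    species: str
    n_ribosomal_assayed: int
    n_ribosomal_essential: int
    base_rate: float
    subset_size: int
    subset_essential: int
    p_value: float

    def as_row(self) -> dict:
        return {
            "species": self.species,
            "essential_ribosomal": self.n_ribosomal_essential,
            "base_rate": self.base_rate,
            "subset_essential": self.subset_essential,
            "p_value": self.p_value,
        }


def estimate_base_rate(
    records: list[EssentialityRecord], species: str
) -> tuple[int, int, float]:
    """(assayed, essential, p̂) over the species' ribosomal proteins.

    Non-ribosomal records are ignored in both counts; p̂ is the exact
    ratio essential/assayed.
    """
    ribo = [r for r in records if r.species == species and r.is_ribosomal]
    if not ribo:
        raise SchemaError(f"no ribosomal records for species {species!r}")
    n_assayed = len(ribo)
    n_essential = sum(r.is_essential for r in ribo)
    return n_assayed, n_essential, n_essential / n_assayed


def binomial_tail_p(n: int, k: int, p: float) -> float:
    """Exact lower tail P(X <= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise SchemaError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise SchemaError(f"probability p={p} outside [0, 1]")
    return float(stats.binom.cdf(k, n, p))


def flexibility_test(
    records: list[EssentialityRecord], species: str
) -> FlexibilityResult:
    """Run the flexibility test for one species.

    The subset is defined by the ``in_target_subset`` flag of the input
    records; the species must have at least one flagged protein.
    """
    n_assayed, n_essential, p_hat = estimate_base_rate(records, species)
    subset = [
        r for r in records if r.species == species and r.in_target_subset
    ]
    if not subset:
        raise SchemaError(f"species {species!r} has no target-subset proteins")
    n = len(subset)
    k = sum(r.is_essential for r in subset)
    return FlexibilityResult(
        species=species,
        n_ribosomal_assayed=n_assayed,
        n_ribosomal_essential=n_essential,
        base_rate=p_hat,
        subset_size=n,
        subset_essential=k,
        p_value=binomial_tail_p(n, k, p_hat),
    )


def flexibility_table(
    records: list[EssentialityRecord],
) -> list[FlexibilityResult]:
    """Flexibility test for every species, in first-appearance order."""
    groups: dict[str, list[EssentialityRecord]] = {}
    for r in records:
        groups.setdefault(r.species, []).append(r)
    return [flexibility_test(group, sp) for sp, group in groups.items()]
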