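"""Viral-sharing statistics for a classified family set.

Given a set of families (typically the LAECA-origin calls), this module
measures how strongly the set overlaps the viral world:

* the number of set families present in at least one viral genome;
* the mean *viral occupancy* — the average number of viral genomes
  carrying each family — optionally with an exclusion list (dominant
  families such as the PolB polymerase pair swamp the mean);
* a significance estimate against a resampling null: draw many random
  same-sized sets from the universe of families present in at least one
  cellular (non-virus) genome and count how often the random set has at
  least as many viral-present families as observed.

Sampling is without replacement (a set of distinct families cannot
repeat a member), which makes the null exactly hypergeometric; the
closed-form upper tail is reported alongside the Monte-Carlo estimate
and serves as its cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import (
    CELLULAR_CLADES,
    CladeLabel,
    GenomeRecord,
    PresenceMatrix,
    SchemaError,
)

__all__ = [
    "ViralEnrichmentResult",
    "viral_presence_count",
    "viral_occupancies",
    "mean_viral_occupancy",
    "cellular_universe",
    "hypergeometric_tail",
    "resample_null",
    "viral_enrichment",
]


@dataclass(frozen=True)
class ViralEnrichmentResult:
    """Full output of the enrichment analysis for one family set.

    ``empirical_p_raw`` is exceed_count/R and may be exactly 0 when no
    resample reaches the observed count; ``empirical_p_add_one`` is the
    standard (exceed_count+1)/(R+1) Monte-Carlo estimator that never
    claims p = 0.  ``exact_p`` is the hypergeometric upper tail of the
    same null.
    """

    set_label: str
    set_size: int
    universe_size: int
    universe_viral_present: int
    observed_viral_present: int
    mean_viral_occupancy: float
    mean_viral_occupancy_excluded: float | None
    resample_count: int
    exceed_count: int
    empirical_p_raw: float
    empirical_p_add_one: float
    exact_p: float
    seed: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.observed_viral_present <= self.set_size <= self.universe_size
            and 0 <= self.universe_viral_present <= self.universe_size
            and 0 <= self.exceed_count <= self.resample_count
        )
        if not ok:
            raise SchemaError("inconsistent enrichment counts")


def _viral_genome_ids(genomes: list[GenomeRecord]) -> list[str]:
    return [g.genome_id for g in genomes if g.clade is CladeLabel.VIRUS]


def viral_occupancies(
    matrix: PresenceMatrix,
    genomes: list[GenomeRecord],
    family_set: list[str],
) -> dict[str, int]:
    """Number of viral genomes carrying each family of the set."""
    matrix.require_families(family_set)
    viral = _viral_genome_ids(genomes)
    return {
        fam: matrix.genomes_with_family(fam, viral) for fam in family_set
    }


def viral_presence_count(
    matrix: PresenceMatrix,
    genomes: list[GenomeRecord],
    family_set: list[str],
) -> int:
    """Families in the set present in at least one viral genome."""
    occ = viral_occupancies(matrix, genomes, family_set)
    return sum(1 for n in occ.values() if n > 0)


def mean_viral_occupancy(
    matrix: PresenceMatrix,
    genomes: list[GenomeRecord],
    family_set: list[str],
    exclude: list[str] | None = None,
) -> float:
    """Mean number of viral genomes per family, after exclusions."""
    exclude_set = set(exclude or ())
    kept = [f for f in family_set if f not in exclude_set]
    if not kept:
        raise SchemaError("family set is empty after applying exclusions")
    occ = viral_occupancies(matrix, genomes, kept)
    return float(np.mean([occ[f] for f in kept]))


def cellular_universe(
    matrix: PresenceMatrix, genomes: list[GenomeRecord]
) -> list[str]:
    """Families present in at least one cellular (non-virus) genome.

    This is the population the resampling null draws from; a family
    carried only by viruses never enters it.
    """
    matrix.check_genomes(genomes)
    cellular_ids = [
        g.genome_id
        for g in genomes
        if g.clade in CELLULAR_CLADES and g.genome_id in set(matrix.genome_ids)
    ]
    if not cellular_ids:
        return []
    counts = matrix.frame[cellular_ids].to_numpy().sum(axis=1)
    return [fam for fam, n in zip(matrix.family_ids, counts) if n > 0]


def hypergeometric_tail(M: int, V: int, m: int, v_obs: int) -> float:
    """P(X >= v_obs) for X ~ Hypergeometric(M, V, m).

    M is the universe size, V the number of viral-present families in
    it, m the drawn set size.  Upper tail is inclusive.
    """
    if not (0 <= V <= M and 0 <= v_obs <= m <= M):
        raise SchemaError(
            f"invalid hypergeometric arguments M={M}, V={V}, m={m}, v_obs={v_obs}"
        )
    if v_obs == 0:
        return 1.0
    return float(stats.hypergeom.sf(v_obs - 1, M, V, m))


def resample_null(
    matrix: PresenceMatrix,
    genomes: list[GenomeRecord],
    universe: list[str],
    m: int,
    v_obs: int,
    R: int = 10_000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo null: R uniform draws of m families without replacement.

    Returns exceed_count (resamples with viral-present count >= v_obs),
    both empirical p estimators, and the exact hypergeometric tail of
    the same null.  Fully reproducible from ``seed``.
    """
    if m > len(universe):
        raise SchemaError(
            f"cannot draw {m} families from a universe of {len(universe)}"
        )
    matrix.require_families(universe)
    viral = _viral_genome_ids(genomes)
    present = [g for g in viral if g in set(matrix.genome_ids)]
    if present:
        viral_counts = matrix.frame.loc[universe, present].to_numpy().sum(axis=1)
    else:
        viral_counts = np.zeros(len(universe), dtype=int)
    is_viral = (viral_counts > 0).astype(np.int64)
    V = int(is_viral.sum())
    M = len(universe)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(R):
        draw = rng.choice(M, size=m, replace=False)
        if int(is_viral[draw].sum()) >= v_obs:
            exceed += 1
    return {
        "universe_size": M,
        "universe_viral_present": V,
        "resample_count": R,
        "exceed_count": exceed,
        "empirical_p_raw": exceed / R,
        "empirical_p_add_one": (exceed + 1) / (R + 1),
        "exact_p": hypergeometric_tail(M, V, m, v_obs),
        "seed": seed,
    }


def viral_enrichment(
    matrix: PresenceMatrix,
    genomes: list[GenomeRecord],
    family_set: list[str],
    set_label: str = "SET",
    exclude: list[str] | None = None,
    resample_count: int = 10_000,
    seed: int = 0,
) -> ViralEnrichmentResult:
    """Run the full enrichment analysis for one family set."""
    if not family_set:
        raise SchemaError("family set is empty")
    matrix.require_families(family_set)
    universe = cellular_universe(matrix, genomes)
    outside = [f for f in family_set if f not in set(universe)]
    if outside:
        raise SchemaError(
            "family set members absent from the cellular universe "
            f"(virus-only or absent everywhere): {outside}"
        )
    v_obs = viral_presence_count(matrix, genomes, family_set)
    null = resample_null(
        matrix, genomes, universe, len(family_set), v_obs, resample_count, seed
    )
    mean_occ = mean_viral_occupancy(matrix, genomes, family_set)
    mean_excl = None
    if exclude:
        mean_excl = mean_viral_occupancy(matrix, genomes, family_set, exclude)
    return ViralEnrichmentResult(
        set_label=set_label,
        set_size=len(family_set),
        universe_size=null["universe_size"],
        universe_viral_present=null["universe_viral_present"],
        observed_viral_present=v_obs,
        mean_viral_occupancy=mean_occ,
        mean_viral_occupancy_excluded=mean_excl,
        resample_count=null["resample_count"],
        exceed_count=null["exceed_count"],
        empirical_p_raw=null["empirical_p_raw"],
        empirical_p_add_one=null["empirical_p_add_one"],
        exact_p=null["exact_p"],
        seed=seed,
    )
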