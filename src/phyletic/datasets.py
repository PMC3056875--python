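"""Bundled reference inputs for the two worked analyses.

Two small published data tables ship with the package:

* A survey of ribosomal-protein essentiality in eleven bacterial
  species.  Each species had 55 ribosomal proteins assayed by knockout;
  the table records how many were essential, and how many of the 16
  ribosomal proteins that are universal in bacteria but absent from
  archaea were essential.  This is the worked input for the
  flexibility test.
* The 24 protein families (Pfam accessions) classified as originating
  in the last archaeal-eukaryotic common ancestor (LAECA) that are
  found in at least one viral genome, with the number of archaeal,
  bacterial, eukaryotic and viral genomes carrying each.  This is the
  worked input for the viral-occupancy statistics.  The two
  DNA-polymerase-family-B entries dominate the viral counts, hence the
  conventional exclusion list.

Helpers expand these count tables into the package's own record and
matrix types.  The expansions are synthetic reconstructions: they
reproduce the published counts exactly but invent protein/genome
identities, which the downstream statistics never use.
"""

from __future__ import annotations

import pandas as pd

from .model import CladeLabel, EssentialityRecord, GenomeRecord, PresenceMatrix

__all__ = [
    "ribosomal_essentiality_survey",
    "ribosomal_essentiality_records",
    "laeca_viral_families",
    "POLB_FAMILIES",
    "viral_family_matrix",
]

N_RIBOSOMAL_ASSAYED = 55
SUBSET_SIZE = 16

_ESSENTIALITY_ROWS = [
    # species, essential ribosomal (of 55), essential in the archaea-absent subset (of 16)
    ("Pseudomonas aeruginosa UCBPP-PA14", 32, 8),
    ("Escherichia coli MG1655", 45, 10),
    ("Bacillus subtilis 168", 51, 14),
    ("Mycoplasma pulmonis UAB CTIP", 47, 10),
    ("Francisella novicida U112", 49, 13),
    ("Helicobacter pylori 26695", 29, 10),
    ("Mycoplasma genitalium G37", 51, 14),
    ("Acinetobacter baylyi ADP1", 48, 11),
    ("Mycobacterium tuberculosis H37Rv", 34, 4),
    ("Staphylococcus aureus N315", 51, 14),
    ("Haemophilus influenzae Rd KW20", 39, 9),
]

_VIRAL_FAMILY_ROWS = [
    # pfam accession, description, archaea, bacteria, eukaryote, virus genome counts
    ("PF00136", "DNA polymerase family B", 45, 195, 31, 384),
    ("PF03104", "DNA polymerase family B, exonuclease domain", 45, 210, 31, 173),
    ("PF01068", "ATP dependent DNA ligase domain", 45, 372, 31, 50),
    ("PF01096", "Transcription factor S-II (TFIIS)", 45, 1, 31, 44),
    ("PF00867", "XPG I-region", 43, 0, 31, 37),
    ("PF04566", "RNA polymerase Rpb2, domain 4", 45, 0, 32, 31),
    ("PF04567", "RNA polymerase Rpb2, domain 5", 45, 0, 32, 31),
    ("PF01896", "Eukaryotic and archaeal DNA primase small subunit", 44, 159, 31, 30),
    ("PF04675", "DNA ligase N terminus", 44, 167, 31, 20),
    ("PF04679", "ATP dependent DNA ligase C terminal region", 44, 248, 31, 20),
    ("PF00752", "XPG N-terminal domain", 43, 0, 31, 16),
    ("PF00705", "Proliferating cell nuclear antigen, N-terminal domain", 45, 0, 33, 10),
    ("PF01191", "RNA polymerase Rpb5, C-terminal domain", 44, 0, 32, 5),
    ("PF00352", "Transcription factor TFIID (or TATA-binding protein, TBP)", 45, 0, 33, 4),
    ("PF01194", "RNA polymerases N/8 kDa subunit", 45, 0, 30, 3),
    ("PF01981", "Peptidyl-tRNA hydrolase PTH2", 45, 26, 30, 3),
    ("PF00382", "Transcription factor TFIIB repeat", 45, 0, 32, 3),
    ("PF03876", "RNA polymerase Rpb7-like, N-terminal domain", 42, 0, 31, 2),
    ("PF08542", "Replication factor C", 44, 0, 31, 2),
    ("PF02933", "Cell division protein 48 (CDC48), domain 2", 45, 18, 31, 1),
    ("PF01599", "Ribosomal protein S27a", 41, 0, 32, 1),
    ("PF02359", "Cell division protein 48 (CDC48), N-terminal domain", 45, 44, 32, 1),
    ("PF01873", "Domain found in IF2B/IF5", 45, 0, 33, 1),
    ("PF01253", "Translation initiation factor SUI1", 45, 287, 33, 1),
]

#: the two DNA-polymerase-family-B entries, conventionally excluded from
#: the occupancy mean because they dominate it
POLB_FAMILIES = ["PF00136", "PF03104"]


def ribosomal_essentiality_survey() -> pd.DataFrame:
    """The eleven-species essentiality count table."""
    return pd.DataFrame(
        _ESSENTIALITY_ROWS,
        columns=["species", "essential_ribosomal", "subset_essential"],
    )


def ribosomal_essentiality_records() -> list[EssentialityRecord]:
    """Expand the survey counts into per-protein records.

    Synthetic reconstruction: per species, 55 ribosomal proteins with
    invented ids, of which the first 16 form the archaea-absent subset;
    essentiality flags are distributed to match the published counts
    exactly (which proteins carry them is arbitrary and does not affect
    any statistic computed downstream).
    """
    records: list[EssentialityRecord] = []
    for species, n_essential, k_subset in _ESSENTIALITY_ROWS:
        n_outside = n_essential - k_subset
        for i in range(N_RIBOSOMAL_ASSAYED):
            in_subset = i < SUBSET_SIZE
            if in_subset:
                essential = i < k_subset
            else:
                essential = (i - SUBSET_SIZE) < n_outside
            records.append(
                EssentialityRecord(
                    species=species,
                    protein_id=f"rp{i:03d}",
                    is_ribosomal=True,
                    is_essential=essential,
                    in_target_subset=in_subset,
                )
            )
    return records


def laeca_viral_families() -> pd.DataFrame:
    """The 24 LAECA-origin families found in viruses, with genome counts."""
    return pd.DataFrame(
        _VIRAL_FAMILY_ROWS,
        columns=["family_id", "description", "archaea", "bacteria", "eukaryota", "virus"],
    )


def viral_family_matrix() -> tuple[PresenceMatrix, list[GenomeRecord]]:
    """Expand the genome-count table into a presence matrix.

    Synthetic reconstruction: genome identities are invented; each
    family is marked present in exactly as many genomes per clade as
    the published counts state, with clade sizes matching the surveyed
    collections (46 archaea, 939 bacteria, 35 eukaryotes; 390 viruses
    accommodates the largest viral count).  All per-clade counting and
    occupancy statistics computed from this matrix equal those computed
    from the original data.  Re-running the origin classifier on it is
    not meaningful: several published per-clade counts sit just below
    90% of the full clade sizes, because the survey's denominators at
    classification time predate its final genome collection.
    """
    sizes = {
        CladeLabel.ARCHAEA: ("arc", 46),
        CladeLabel.BACTERIA: ("bac", 939),
        CladeLabel.EUKARYOTA: ("euk", 35),
        CladeLabel.VIRUS: ("vir", 390),
    }
    genomes: list[GenomeRecord] = []
    ids_by_clade: dict[CladeLabel, list[str]] = {}
    for clade, (tag, n) in sizes.items():
        ids = [f"{tag}{i:04d}" for i in range(n)]
        ids_by_clade[clade] = ids
        genomes.extend(GenomeRecord(g, clade) for g in ids)

    frame = pd.DataFrame(
        0,
        index=pd.Index([r[0] for r in _VIRAL_FAMILY_ROWS], dtype=object),
        columns=[g.genome_id for g in genomes],
        dtype="int8",
    )
    count_cols = {
        CladeLabel.ARCHAEA: 2,
        CladeLabel.BACTERIA: 3,
        CladeLabel.EUKARYOTA: 4,
        CladeLabel.VIRUS: 5,
    }
    for row in _VIRAL_FAMILY_ROWS:
        fam = row[0]
        for clade, col in count_cols.items():
            frame.loc[fam, ids_by_clade[clade][: row[col]]] = 1
    return PresenceMatrix(frame), genomes
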