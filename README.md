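# phyletic

Phyletic-pattern analyses of protein-family origins across the tree of
life: classify families to ancestral origins from clade coverage, test
whether a classified set is unusually shared with viruses, and test
per-species whether a designated subset of ribosomal proteins is
unusually nonessential.

## Who this is for

Comparative genomicists working with family-by-genome presence/absence
data (phyletic patterns) — e.g. per-genome domain assignments — who want
the counting and significance machinery behind ancestral-gene-content
arguments as reusable, tested code rather than one-off scripts.

## The statistics

**Origin classification.** For family *f* and clade *c* with *N_c*
surveyed genomes of which *k_{f,c}* carry the family, coverage is
*cov(f, c) = k_{f,c} / N_c* (denominators always come from the genome
metadata, never from the matrix). A family is assigned to the last
archaeal-eukaryotic common ancestor (LAECA) when

    cov(archaea) ≥ 0.90  and  cov(eukaryota) ≥ 0.90  and  cov(bacteria) < 0.50

and to the last bacterial common ancestor (LBCA) under the mirrored
rule (bacteria ≥ 0.90; archaea and eukaryota < 0.50). The 90% bound is
strict enough to imply ancestral presence; the 50% bound tolerates
recent horizontal transfers. "At least" is inclusive, "less than" is
strict, and coverages are kept as exact rationals so a family at
exactly 50% bacterial coverage is never called LAECA. Viral coverage is
reported but never thresholded.

**Viral enrichment.** For a classified set of *m* families, of which
*v* are present in ≥1 viral genome, significance is assessed against a
resampling null: draw *R* random *m*-subsets (without replacement) of
the universe of *M* families present in ≥1 cellular genome, *V* of
which are viral-present, and count draws with ≥ *v* viral-present
members. Both the raw estimator `exceed/R` and the add-one estimator
`(exceed+1)/(R+1)` are reported, alongside the exact null — the
hypergeometric upper tail P(X ≥ v), X ~ Hypergeom(M, V, m) — which the
sampler must agree with. The set's mean viral occupancy (average number
of viral genomes per family) is reported with and without an exclusion
list, since single dominant families (classically the two DNA
polymerase B entries) can swamp the mean.

**Ribosomal flexibility.** Per species, with *N* assayed ribosomal
proteins of which *e* are essential, the base rate is p̂ = e/N
(estimated per species to control for unequal knockout thoroughness).
For a designated subset of *n* ribosomal proteins with *k* essential,
the reported p-value is the exact lower binomial tail

    P(X ≤ k),   X ~ Binomial(n, p̂)

— small values mean the subset is significantly more dispensable than
ribosomal proteins in general.

## Worked example

The package bundles two published reference inputs: an eleven-species
bacterial survey of ribosomal-protein essentiality (55 proteins assayed
per species; 16 of them form the archaea-absent subset) and the
24-family table of LAECA-origin families found in viruses, with
per-clade genome counts.

```sh
python - <<'EOF'
from phyletic.io import write_essentiality, write_genome_metadata, write_presence
from phyletic.datasets import ribosomal_essentiality_records, viral_family_matrix
matrix, genomes = viral_family_matrix()
write_genome_metadata(genomes, "meta.tsv")
write_presence(matrix, "presence.tsv", layout="matrix")
write_essentiality(ribosomal_essentiality_records(), "ess.tsv")
import pandas as pd
pd.DataFrame({"family_id": matrix.family_ids, "label": "LAECA_ORIGIN"}
             ).to_csv("calls.tsv", sep="\t", index=False)
EOF
phyletic flex --essentiality ess.tsv --out flex.tsv
phyletic enrich --metadata meta.tsv --presence presence.tsv \
    --calls calls.tsv --label LAECA_ORIGIN --resamples 10000 --seed 17 \
    --exclude PF00136,PF03104 --out enrich.json
phyletic report --flex flex.tsv --enrich enrich.json
```

prints (abridged):

```
                          species  essential_ribosomal  base_rate  subset_essential  p_value  significant
     Mycoplasma pulmonis UAB CTIP                   47     0.8545                10   0.0204            1
        Acinetobacter baylyi ADP1                   48     0.8727                11   0.0435            1
 Mycobacterium tuberculosis H37Rv                   34     0.6182                 4   0.0031            1
       Staphylococcus aureus N315                   51     0.9273                14   0.3263            0

Viral enrichment:
  set LAECA_ORIGIN: 24 of 24 families viral-present
  mean viral occupancy 36.38 (14.36 after exclusions)
```

Three species fall below α = 0.05; *M. tuberculosis* is by far the most
significant (p = 0.0031): only 4 of its 16 archaea-absent ribosomal
proteins are essential, against a base essentiality of 34/55. The
24-family set averages 36.38 viral genomes per family, dropping to
14.36 once the two dominant polymerase families are excluded. (The
enrichment p-values in this toy run are 1.0 by construction — every
family in the bundled matrix is viral-present, so every resample
matches; meaningful nulls require a full family universe, as in the
synthetic end-to-end tests.)

`phyletic simulate` generates clade-structured synthetic presence
matrices and essentiality tables with known planted truth; see
`docs/methods.md`.

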