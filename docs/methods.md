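# Methods

## Scope and data model

The package implements two related comparative-genomics analyses over a
binary family-by-genome presence/absence matrix with clade-labelled
genomes (archaea, bacteria, eukaryota, virus — exactly these four;
anything else in input is rejected):

1. threshold classification of families to ancestral origins, followed
   by a viral-sharing enrichment test of the classified set;
2. a per-species exact binomial test of whether a designated ribosomal
   subset is unusually nonessential.

Presence is boolean per (family, genome): at least one occurrence.
Domain copy numbers are deliberately not modelled — all downstream
statistics count genomes, not copies. Coverage denominators are always
the clade sizes of the genome metadata, so genomes carrying no families
legitimately dilute coverage; a clade with zero genomes cannot be
thresholded and raises rather than yielding 0/0.

## Origin classification

Coverage is stored as an exact rational (`fractions.Fraction`), and
rule thresholds written as decimals are interpreted as decimals
(`0.9` means 9/10, not the nearest binary double). This makes the
boundary semantics exact: "at least 90%" is `>=`, "less than 50%" is
strict `<`, and a family present in exactly half the bacterial genomes
fails the LAECA rule. Rules must be mutually exclusive on the data;
two rules matching one family is treated as misconfiguration and
raises, rather than being resolved by precedence. Families matching no
rule are labelled `NONE`. Viral coverage is profiled in every output
but never participates in a rule: viruses acquire cellular families by
exchange, so their coverage says nothing about ancestral cellular
content.

The historical clade sizes these rules were framed against were 46
archaea, 35 eukaryotes and 939 bacteria; all of them are configuration,
not constants.

## Viral enrichment

Given a classified set of size m with v viral-present members, the null
asks: does a uniformly random m-subset of the eligible universe — the
M families present in at least one *cellular* genome (virus-only
families never enter) — contain ≥ v viral-present members as often?
Sampling is without replacement (a set of distinct families cannot
repeat a member), which makes the null exactly hypergeometric; the
implementation draws R seeded resamples and also reports the exact
upper tail P(X ≥ v), X ~ Hypergeom(M, V, m), which doubles as the
correctness oracle for the sampler in the test suite. R defaults to
10,000. Two empirical estimators are reported: the raw exceed/R (which
may be 0) and the add-one (exceed+1)/(R+1), the standard Monte-Carlo
p-value that never claims exact zero. All sampling uses an explicit
`numpy.random.Generator` seeded from the recorded seed; there is no
global random state, and identical seeds give bit-identical counts.

Mean viral occupancy is the arithmetic mean, over the set, of the
number of viral genomes carrying each family. Because one or two
families can dominate (in the bundled reference set the two DNA
polymerase B entries account for 557 of 873 viral genome occurrences),
the mean is also reported under a configurable exclusion list; the
shipped default excludes both polymerase entries (PF00136, PF03104).

## Ribosomal flexibility

Per species: p̂ = (essential ribosomal proteins) / (assayed ribosomal
proteins), an exact ratio over that species' own assay — never pooled
across species, because knockout screens differ in thoroughness and a
pooled rate would confound the comparison. The subset under test is an
input flag on the records (`in_target_subset`, which must imply
`is_ribosomal`), not a built-in protein list. With n subset members and
k essential, the p-value is the exact inclusive lower tail
P(X ≤ k) under Binomial(n, p̂) — no normal approximation. No
multiple-testing correction is applied across species; the report
flags species below a configurable α (default 0.05).

Internally p̂ is carried at full precision; reports round half-even to
a configurable number of digits (default 4) for display only. This
matters: recomputing the tails from 4-decimal rounded base rates
changes fourth-decimal p-values (e.g. 51/55 vs 0.9273 flips 0.3263 to
0.3262).

## Synthetic data

The generator emulates the statistical structure the analyses assume,
so every stage is testable end to end with known truth:

* **Presence.** Families come in classes; class c has per-clade
  retention probabilities and a viral carriage rate, and each
  (family, genome) cell is an independent Bernoulli draw. Defaults for
  the clade sizes are 46 archaea, 35 eukaryotes, 100 bacteria and 60
  viruses — archaea and eukaryotes at the historical collection sizes,
  bacteria scaled down (the full 939 is configuration) and a viral
  collection large enough that carriage-rate contrasts (e.g. 0.3 vs
  0.02 per genome) separate cleanly. A planted LAECA-like class uses
  retention 0.98 in archaea and eukaryotes and 0.05 in bacteria;
  background families mirror it.
* **Essentiality.** Per species, 55 ribosomal proteins (matching the
  reference survey's assay size), the first 16 flagged as the target
  subset; essentiality is Bernoulli(p_s) outside the subset and
  Bernoulli(min(1, p_s·δ)) inside. δ = 1 is the null; δ < 1 plants the
  dispensability effect.

A single seed drives everything through `numpy.random.SeedSequence`
spawning: presence and essentiality use disjoint child streams, and
each family class and each species gets its own grandchild stream, so
adding a class or species never perturbs draws made by earlier ones.

What the generator does **not** emulate: phylogenetic autocorrelation
(genomes within a clade are exchangeable and independent), correlated
retention between families (operons, pathways), genome-size or
sampling-bias structure, and copy-number variation. Passing tests
therefore demonstrate correctness of the statistics under
exchangeability — the same implicit assumption the analyses make — not
robustness of the science to real phylogenetic structure.

## Verification strategy and problem sizes

* The eleven-species flexibility table and the 24-family occupancy
  statistics are reproduced at printed precision from the bundled
  reference inputs (exact checks).
* The resampler is checked against the closed-form hypergeometric tail
  at five parameter settings with R = 10,000 within 3 Monte-Carlo
  standard errors; the binomial tail against 200,000 seeded Bernoulli
  replicates at five settings, likewise within 3 SE.
* Parameter recovery: the classifier's planted-class recovery rate is
  compared with the closed-form product of binomial threshold tails
  (five pooled runs of 50 planted + 100 background families at clade
  sizes 46/35/100); flexibility-test power at p_s = 0.8, n = 16 is
  checked to be monotone in δ over {1.0, 0.75, 0.5, 0.25} with 2,000
  replicates per setting; under δ = 1 the p-value's empirical CDF over
  1,000 replicates is compared with its exact null CDF (joint
  enumeration over subset/non-subset essential counts — the p-value is
  discrete, so a plain uniformity test would be wrong).
* End to end, a planted viral-associated LAECA-like class among
  background families must be flagged enriched (add-one empirical
  p < 0.01) while the same run's LBCA-pattern call set — drawn at the
  universe's bulk carriage rate — must not.

These simulation sizes keep the whole suite fast while leaving
Monte-Carlo standard errors far smaller than the effects being checked.

## Known limitations and deliberate gaps

* The bundled 24-family reference table reproduces published per-clade
  genome *counts*; re-running the classifier on it is not meaningful
  because the original survey's denominators at classification time
  differ from its final clade sizes (several counts sit just below 90%
  of 46 or 35). The table's role here is the occupancy and
  viral-presence statistics, which depend only on the counts.
* Absolute historical quantities — how many families classify as
  LAECA- or LBCA-origin in a given family-database release, and the
  enrichment p-values against that universe — depend on the snapshot
  and are not reproducible from the bundled inputs; the synthetic
  end-to-end checks stand in for them.
* No probabilistic ancestral-content reconstruction (gain/loss models,
  Dollo parsimony): the classifier is a pure threshold rule by design.
* No inference about the direction of virus–cell transfer, and no
  identification of which specific subset proteins are dispensable.
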