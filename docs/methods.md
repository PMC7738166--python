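# Methods

This note records the models, statistics, and conventions implemented in
deltacf, in enough detail to re-derive every number the package prints.

## 1. Branch contexts and gene-tree classification

The species tree is rooted and binary. Every internal branch that is
informative about topology (all branches except those incident to the root
pair and to leaves; a tree with n taxa has n − 3 of them) induces a
**branch context**: the two child clades A and B below the branch, and a
partition of the remaining taxa into C and D given by the far side of the
split at the branch's parent. Within each pair the group containing the
lexicographically smallest taxon label is listed first, which makes the
naming of the two discordant arrangements deterministic:

- **CONCORDANT** — the gene tree displays the split (A∪B) | (C∪D);
- **ALT1** — it displays (A∪C) | (B∪D);
- **ALT2** — it displays (A∪D) | (B∪C);
- **PARAPHYLETIC** — all four groups are present but no one split of the
  gene tree separates any of the three arrangements;
- **NOT_DECISIVE** — after restriction to the taxa present at the locus,
  one of the four groups is empty (or fewer than four taxa remain).

"Displays" is evaluated on the gene tree restricted to the taxa it actually
contains: a split (S, S̄) of the gene tree displays an arrangement (P, Q)
iff P∩L ⊆ S and Q∩L ⊆ S̄ (or vice versa), where L is the gene tree's leaf
set. At most one of the three arrangements can be displayed. Branch
identifiers are short stable hashes of the branch's leaf-set bipartition,
so they survive tree rotations and relabelling of internal nodes.

## 2. Concordance factors

For each branch, the **gene concordance factor** gCF is the percentage of
*decisive* gene trees that are concordant; gDF1, gDF2, and gDFP are the
percentages in ALT1, ALT2, and PARAPHYLETIC. By construction
gCF + gDF1 + gDF2 + gDFP = 100 whenever at least one tree is decisive;
branches with no decisive tree report undefined (NA) percentages.

The **site concordance factor** sCF samples quartets around a branch (one
taxon from each of A, B, C, D, uniformly at random, default 300 quartets)
and, pooling all alignment columns across loci, counts decisive sites —
sites where the four sampled sequences carry exactly two states, two taxa
each, with no gaps or ambiguity codes. Each decisive site supports exactly
one of the three quartet topologies; sCF is the mean over quartets of the
percentage supporting the species-tree pairing. Its ILS-free floor is
33.3 %, so values near 33.3 indicate a branch whose sites are effectively
unresolved.

The **polytomy test** asks whether the three resolutions around a branch
are equally frequent: a chi-square goodness-of-fit of (n_conc, n_alt1,
n_alt2) against uniform expectation, 2 degrees of freedom. For example
(442, 437, 413) gives χ² = 1.116, p = 0.572.

## 3. The Δ introgression test

Under the neutral MSC the two discordant classes around a branch are
exchangeable, so E[DF1 − DF2] = 0. The test statistic is

Δ = (DF1 − DF2) / (DF1 + DF2),

reported as a non-negative number (the larger class in the numerator); it
is undefined when DF1 + DF2 = 0.

**Screening.** Only branches whose discordant fraction of decisive trees
strictly exceeds 5 % are tested; nearly clean branches carry too few
discordant trees for the ratio to be meaningful.

**Calibration.** The null distribution of Δ comes from a gene-tree
bootstrap: resample the gene trees with replacement B times (default
2,000), recompute Δ with the *identities* of DF1 and DF2 frozen at their
observed assignment (so bootstrap Δ values can be negative), and take the
standard deviation. The observed Δ is converted to z = Δ/sd and to a tail
probability p = min(1, 2·Φ̄(z)) — a half-normal tail, reflecting that Δ is
folded to be non-negative. A `tail="normal"` option gives the plain
two-sided normal tail (exactly half the half-normal p); both are monotone
transformations of z, so significance rankings agree and only cutoff
placement differs.

**Multiplicity.** With m branches tested, the Dunn–Šidák per-comparison
cutoff is 1 − (1 − α)^(1/m). At α = 0.05, m = 17: 0.00301. The CLI
defaults m to the number of screened branches in the current run.

**Quartet follow-up.** For a significant branch, `quartet_followup`
re-runs the test on a single named quartet (one taxon per group), dropping
loci missing any of the four taxa — a check that the signal is not an
artefact of taxon-sampling heterogeneity. On four-taxon data it reproduces
the full test exactly.

## 4. MSC simulator

Gene trees are simulated locus-by-locus under the multispecies coalescent
on the species tree's topology and branch lengths, interpreted in
**haploid coalescent units** (one unit = 2N generations for diploids; the
probability that two lineages entering a branch of length T fail to
coalesce is e^(−T)). The probability that the gene tree is concordant at a
branch of length T with a single lineage entering from each child is the
closed form

P(concordant) = 1 − ⅔·e^(−T),

which the simulator matches to within binomial error at 10,000 loci across
T from 0.01 to 2 (acceptance test 2).

**Introgression pulses.** A pulse (donor, recipient, time t, γ) moves each
sampled lineage of the recipient population that is present at time t into
the donor population independently with probability γ. γ = 0 is simulated
identically to no pulse (same random stream); γ = 1 reroutes every lineage.
The truth log records, per locus, which pulses rerouted lineages and the
topology class at every branch.

**Determinism.** Each locus draws from its own child stream of the
configured seed (`numpy` `SeedSequence.spawn`), so results are bit-identical
for a fixed seed and the first k loci of an n-locus run equal a k-locus run.

**Sequences.** `simulate_alignment` evolves i.i.d. sites under JC69 along
the gene tree, with a scale factor converting branch-length units to
substitutions per site. Missing data is modelled by dropping each taxon
from a locus independently with probability `missing_prob` (floor of three
taxa per locus).

## 5. Wright–Fisher selection null

Could purifying selection bias topology frequencies and mimic Δ's signal?
The forward model:

- Haploid Wright–Fisher populations of size N (default 500). The
  population history mirrors the MSC setup: an ancestral population splits
  into p1 and (p2,p3)'s ancestor; after an internal interval of 0.01·N
  generations (T = 0.01 coalescent units) the ancestor splits into p2 and
  a small p3 of size 0.04·N; tip branches run 8·N generations.
- Each individual carries a count of deleterious mutations per locus
  (L = 50 unlinked loci); fitness is multiplicative, (1 + s)^k with
  Ns = −7.5. New mutations arrive at per-locus rate U (3·10⁻⁷ and 3·10⁻⁵
  per individual per generation in the two tested regimes). Parents are
  drawn fitness-proportionally by exact rejection sampling, so the
  offspring distribution is exactly multinomial with fitness weights.
- The pedigree (parent indices) is recorded through every epoch that a
  sampled lineage can traverse. One individual per population is sampled
  per locus and its ancestry is traced backwards through the recorded
  pedigree — coalescence is an event in the realised pedigree, not a
  coalescent approximation. Tracing through the root continues for a 3·N
  generation window; the topology of each locus is the first pairwise
  merge among the three lineages (ties in a triple merge broken uniformly
  at random), and loci not fully resolved inside the window are reported
  as unresolved and excluded from frequencies (with N = 500 and a 3·N
  window, about 5 % of loci; e^(−3) ≈ 0.05 of pairs survive the window).
- 100 replicates of 50 loci per condition; a neutral run uses the same
  machinery with s = 0, U = 0. With U = 0 the selected and neutral runs
  consume identical random streams and give identical results — a built-in
  self-check.

The **topology bias test** compares pooled (concordant, p1p2, p1p3) counts
between two conditions with a 3×2 chi-square test of independence (no
continuity correction); when any expected cell is below 5 it switches to a
Monte-Carlo exact test (random 3×2 tables with fixed margins). In the
acceptance run, neither mutation regime rejects the neutral null, and the
neutral topology frequencies match 1 − ⅔·e^(−0.01) within 3 binomial
standard errors — selection at these parameters does not confound the
introgression test.

A `diploid_units` flag reinterprets branch durations with 2N-generation
units for users who think in diploid time.

## 6. Conventions

- **Tables** are TSV: tab separator, `\n` line endings, header row, no
  quoting, `.` decimal point, `NA` for missing values.
- **Manifests**: every CLI command that writes a table also writes
  `<out>.manifest.json` recording the command, options, seed, SHA-256 of
  each input file, package version, and a UTC timestamp.
- **Seeds**: a single user-supplied seed is expanded into per-component
  substreams via `SeedSequence`; all derived seeds are kept below 2³¹.
- **Alignments**: FASTA and relaxed PHYLIP are auto-detected; labels must
  be unique and sequences equal-length within a locus.
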