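# Methods

## Coordinate and codon conventions

Alignment columns are 1-based. Coding positions are 1-based from the start
codon of the reference coding sequence; `coding_offset` (default 431) is the
coding position of column 1, so a default-offset matrix starts inside codon
144 at phase 2, mirroring an amplicon that covers the 3' two thirds of the
gene. Codon-level operations (site kinds, Ka/Ks, residue checks) use only
codons that fall entirely inside the matrix. The standard nuclear genetic
code (61 sense codons, 3 stops) is used throughout.

Gaps (`-`) inside a record are treated as deletions; leading and trailing
gap runs are treated as missing data from partial amplicons, not deletions,
so they are flagged `terminal` and never produce frameshift calls. `N` is
missing data at every site-level computation. Because the ambiguity of
reported deletion coordinates in mid-gene amplicons is real, every indel
event is reported in both coordinate systems (alignment column and coding
position).

## Site classification

A column is *variable* when it carries ≥ 2 distinct non-gap, non-N states,
*parsimony-informative* when ≥ 2 states each occur in ≥ 2 records, and a
*singleton* site when variable but not informative. Matrix-level counts use
one of two gap policies: `complete_deletion` (default) drops every
gap-containing column from the totals — the convention when indels are
excluded from the calculations — while `indel_as_one_site` additionally
counts each internal indel event as one polymorphic site. Percentages of
the matrix are rounded half-up to two decimals, matching how such tables
are conventionally printed.

Silent/replacement kinds are decided against the column's *majority codon*
(ties broken by lexicographic codon order, for determinism). At a
polymorphic column, the kind is silent if every observed variant codon
encodes the majority amino acid, replacement if every variant changes it
(stops count as replacement), mixed otherwise. At a monomorphic column, the
kind reflects the degeneracy of that position in the majority codon: silent
if all three possible point changes are synonymous and non-stop,
replacement if none is, mixed otherwise. Columns without a single complete
gap/N-free codon are `not_assessable`. Sliding-window software differs in
its exact silent-site definition; ours is declared here, configurable at
the call sites that consume it, and may diverge from other implementations
in mixed-degeneracy columns.

## Diversity and divergence estimators

- **p-distance**: proportion of differing sites among sites where neither
  sequence has gap or N.
- **π**: mean p-distance over all unordered pairs of the subset, computed
  on the *complete-deletion* site set shared by the whole subset. The
  mean-pairwise form without an n/(n−1) correction is used (equal
  haplotype weights); this matches the classical sequence-sample
  formulation and keeps site sets reproducible. A consequence worth noting:
  for two groups with identical composition, the between-group mean (which
  includes identical-haplotype cross pairs at distance 0) equals the pooled
  mean-pairwise π times (n−1)/n, not π itself.
- **D<sub>xy</sub>**: mean p-distance over all cross-group pairs
  (complete deletion over the union), Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − (4/3)·p). The correction is undefined for p ≥ 3/4 and
  such saturation raises a domain error rather than returning a number.
- **Sliding windows**: windows contain a fixed number of silent columns
  (default 25) and advance by a fixed number of silent columns (default
  10); a trailing partial window is dropped. Within a window, π is the
  mean over pairs of (differences / comparable sites) restricted to the
  window's silent columns, with per-pair gap/N exclusion.

## Nei–Gojobori Ka/Ks

Per codon, each position contributes a synonymous-site fraction equal to
the proportion of its possible point changes that preserve the amino acid,
with changes creating stop codons excluded from the denominator; the
nonsynonymous count is 3 minus the synonymous count, so S + N = 3 × codons
by construction. Observed codon differences are resolved over all minimal
substitution pathways, weighted equally, skipping pathways that pass
through a stop codon (if every minimal pathway is stop-locked — possible
only for 2- and 3-fold differences — all pathways are used and
stop-involving steps count as nonsynonymous). Codons are taken from the
complete-deletion codon set shared by the subset. Per-pair proportions
p<sub>S</sub> = s<sub>d</sub>/S and p<sub>N</sub> = n<sub>d</sub>/N are
averaged over all pairs, then Jukes–Cantor corrected into Ks and Ka; the
ratio is reported as undefined when Ks = 0. Codon-pair difference counts
and per-codon site counts are precomputed into 64×64 / 64-entry lookup
tables, so multi-sequence estimates reduce to integer-array indexing.

## Diagnostic sites and fixed differences

A column is diagnostic for a group when all its assessable (non-gap, non-N)
members share one state that no assessable non-member carries; non-members
are the records of the scheme's other groups, and a column with zero
assessable focal members contributes nothing. Gap characters are never
diagnostic states by default.

Relaxed fixed differences between two groups use strict frequency
thresholds: some state's frequency must exceed `f_high` (default 0.70) in
one group and stay below `f_low` (default 0.30) in the other, computed over
assessable members only, with at least two assessable members required per
group per column (partial sequences would otherwise dominate). The
boundary parameterization `f_high = 1`, `f_low = 0` means frequency exactly
1 vs exactly 0 — the strict fixed-difference definition. Output is
monotone in the thresholds: loosening them never removes a reported site.

## Phenotype categories and Fst

Erucic-acid percentages are classified into L, M1, M2, M3, H by fixed cut
points (defaults 10.5, 20.5, 31.11, 41.1; each cut point belongs to the
upper class). The boundaries are configuration with these defaults, not
auto-detected: they encode biologically meaningful gaps in the observed
distribution, which are not the numerically widest gaps in the data, so
automatic gap detection is deliberately excluded.

Differentiation is the pooled Hudson-style Fst = 1 − H<sub>w</sub>/H<sub>b</sub>,
where H<sub>w</sub> is the mean p-distance over all within-category pairs
pooled across categories and H<sub>b</sub> the mean over all
between-category pairs; pooling (rather than per-category averaging)
matches the "all possible pairs" convention used for between-group
diversity. The statistic can be negative on unstructured data; it is
undefined (error) when H<sub>b</sub> = 0. Significance comes from shuffling
category labels among records with sizes preserved, with the add-one
estimator p = (#{Fst<sub>perm</sub> ≥ Fst<sub>obs</sub>} + 1)/(n + 1),
which is never zero and has resolution floor 1/(n+1). The default
permutation count is 10,000 and a seed is mandatory wherever permutations
are requested.

## Synthetic-data generator

The generator provides ground truth for every analysis stage. Trees are
built by random sequential joins with exponential branch lengths; the
clade-structured variant simulates one subtree per clade and attaches each
to the root by a long stem, labelling the subtree root with the clade name.
Sequences evolve at codon granularity with an explicit accept/reject rule
rather than a full rate-matrix exponential: candidate point mutations
arrive as a Poisson process (branch lengths are expected candidate
substitutions per site), targets are weighted κ:1 for transitions vs
transversions, stop-creating mutations are rejected, synonymous changes
accepted, and nonsynonymous changes accepted with probability ω. This is
desk-scale, fully seedable, and realizes ω-controlled silent/replacement
structure; it is not a calibrated substitution model. The root sequence is
drawn uniformly from sense codons.

Default conditions emulate the study system: 60 taxa in 5 clades (sizes
22/20/6/6/6 — two large, three small), 300 codons (900 columns), ω = 0.1,
κ = 2, within-clade mean branch 0.03 and clade stems 0.25 (candidate
substitutions per site), two token indels (one 1-bp frameshifting, one 3-bp
in-frame), and truncated-normal phenotypes on [0, 100] with clade means
47/3/15/25/35% and sd 1 — every mean ≥ 3.9 sd from the nearest category
boundary, so individual values respect their category with probability
≥ 0.999. Injected clade mutations force a target codon onto every clade
member and return an edit ledger; when no target is given, a sense codon is
chosen that differs from the clade consensus at exactly one position using
a base absent from that column matrix-wide, making the edited column a
strict fixed difference by construction.

One subtlety governs fixed-difference ground truth: with genuinely
clade-structured trees, parallel substitutions on the two child branches of
a clade root occasionally create *natural* strict fixed differences, which
would contaminate an injected truth set. `generate_fixed_difference_dataset`
therefore evolves a single panmictic pool and defines groups I/II as an
alternating half-split deliberately incongruent with the tree: no branch
separates exactly that partition, so the injected edits are provably the
only strict fixed differences.

What the generator does **not** emulate — and hence what passing recovery
tests cannot show about real data: manual alignment adjustment, partial
amplicon coverage (long terminal gap runs), multiple gene copies and
heterozygous clones, recombination, rate variation among sites or lineages,
and realistic indel evolution. Results on real alignments additionally
depend on alignment quality in ways the synthetic tests do not probe.

## Numerical choices

- Percentages: decimal half-up rounding to 2 decimals; report tables round
  to 4 decimals; internal computation is full double precision.
- Majority-codon and codon-order ties: lexicographic, for determinism.
- Saturation (p ≥ 3/4) raises a correction-domain error everywhere the
  Jukes–Cantor transform is applied; Ks = 0 yields an undefined ratio, not
  an exception.
- Pipeline outputs are a pure function of (inputs, config, seed): floats
  are formatted with fixed precision, JSON keys are sorted, and repeated
  runs are byte-identical.
- Sub-seeds for tree/evolution/phenotype stages are drawn below 2^31 from
  one master generator per dataset.

## Problem sizes

The test suite and the acceptance script run simulations at the scale the
statistics are meant for while staying desk-sized: oracle equivalence on
100 random matrices up to 20×120; Ka/Ks pathway checks on 50 random codon
pairs; ω = 0.1 selection replicates at 40 taxa × 300 codons (40 replicates
in tests, 20 in the acceptance script); association recovery over 20 seeds
at 40 taxa × 300 codons with 999 permutations; determinism over 3 repeated
pipeline runs.

## Known limitations

- The silent/replacement column rule is majority-codon-based and may
  differ from other software at columns whose codons differ at multiple
  positions.
- The pooled Fst weights categories by their pair counts; an
  equal-weight-per-category variant would differ on very unbalanced
  partitions.
- Ka/Ks pathway averaging weights all minimal paths equally; maximum
  likelihood codon models (not in scope) would weight paths by rate.
- The simulator's branch lengths are candidate-substitution scale, not
  expected-accepted-substitution scale; realized divergence depends on ω
  and the silent-site fraction.
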