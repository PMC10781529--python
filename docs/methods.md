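# Methods

`lagenaria` reimplements, as a tested package, the dominant-marker
diversity analysis of a panel of ten Egyptian bottle gourd
(*Lagenaria siceraria*) cultivars labelled S1–S10, characterized with
three marker systems: SDS-PAGE seed/leaf proteins (17 bands, kDa),
two native-gel isozymes (peroxidase POD and polyphenol oxidase PPO,
5 bands each, identified by relative mobility Rm), and start-codon
targeted (SCoT) PCR fingerprints (8 primers, 44 bands, bp). The
published band matrices and reference tables are packaged as plain
CSV under `src/lagenaria/data/` and every downstream number is
recomputed from them.

## Data model

A band matrix is a loci × genotypes grid over {0, 1} with per-locus
metadata (assay, primer/enzyme group, band size in the assay's native
unit). Invariants enforced at construction: unique genotype and locus
labels, entries strictly 0/1, and no all-zero locus row — a band never
observed on any gel is not a locus. Isozyme gels additionally record
band density grades (+, ++, +++ encoded 1–3); grades are observational
metadata only and collapse to presence (grade ≥ 1) before any
statistic, since none of the coefficients used are density-aware.
The collapse is idempotent.

Pooling concatenates assays over a shared genotype panel, aligning
genotypes by label (not column position) so independently prepared
files compose safely; the genotype order of the first matrix wins.

## Locus classification

With n genotypes and band count c, the band frequency is p = c/n
(kept as an exact rational internally). Classes:

* monomorphic: p = 1;
* polymorphic: 0 < p < 1;
* unique-positive (M+): c = 1 — the band fingerprints its sole carrier;
* unique-negative (M−): c = n − 1 — the absence fingerprints the sole
  non-carrier.

Unique classes are subclasses of polymorphic for counting purposes,
so the polymorphism percentage 100·PBN/TBN includes them. At n = 2 a
singleton band is simultaneously present-in-one and absent-from-one;
positive polarity takes precedence. A band absent from two or more
(but not all) genotypes is polymorphic without being genotype-specific.

## Primer informativeness indices

Per primer/enzyme group, using the standard dominant-marker forms:

* PIC = mean over bands of 2p(1 − p). For a biallelic dominant locus
  2p(1 − p) is the heterozygosity-like information content of the
  presence/absence dichotomy; its maximum 0.5 is attained at p = 0.5,
  and a fully monomorphic primer scores exactly 0.
* EMR = PBN · (PBN/TBN), the number of polymorphic bands weighted by
  the polymorphic fraction.
* MI = PIC · EMR, computed from the unrounded factors so the identity
  holds to machine precision.
* Rp = Σ_b Ib with band informativeness Ib = 1 − 2|0.5 − p_b|; Rp = 0
  exactly when every band has p ∈ {0, 1}.

The packaged per-primer SCoT reference table carries published EMR,
Rp and MI values that are irreconcilable with these (or any standard)
definitions — e.g. a fully monomorphic primer listed with EMR 2.5 and
Rp 5, where every standard formula yields 0. The computation behind
those columns is unrecoverable, so they are treated as historical data,
not as reproduction targets; the index engine is validated instead by
its algebraic properties (MI identity, PIC bounds and maximizer, Rp
zero-set) and by hand-computed small cases. Band counts, polymorphism
percentages, unique-band counts and the PIC column's anchor value
(0 for the monomorphic primer) are reproduced.

Percentages are reported half-up-rounded to 2 decimals; internal
arithmetic is unrounded. One wrinkle: the published mean per-primer
polymorphism percentage (45.15) is the mean of per-primer percentages
*truncated* to 2 decimals (66.667 → 66.66, 63.636 → 63.63); the mean
of unrounded percentages is 45.16. The reproduction therefore averages
the published per-primer column as printed, which is also what the
original analysis did.

## Similarity

Jaccard similarity a/(a + b + c) over shared presences a and
unilateral presences b, c; shared absences carry no information about
dominant markers and are ignored. Dice 2a/(2a + b + c) and simple
matching (a + d)/(a + b + c + d) are available for comparison (Dice
dominates Jaccard off-diagonal for any matrix). A pair with empty
union is assigned similarity 0 with a warning; the case cannot arise
from a single valid matrix but can for subset views. Comparison with
published matrices uses decimal half-up rounding to 3 decimals,
matching their formatting.

Internal consistency of the packaged reference matrices was checked
cell-by-cell. The protein matrix reproduces in all 45 cells. The
pooled protein+isozyme matrix reproduces in 44 of 45; the remaining
cell, (S2, S7), prints 0.825 although S7's 27-band profile is
identical to S3/S4/S5/S10's, forcing (S2, S7) = (S2, S3) = 23/27 =
0.852 — a digit transposition in the source table. That cell is
asserted against the self-consistent value. A published isozyme-only
similarity matrix exists but cannot be derived from the published
isozyme band patterns under any binary coefficient (it scores S1 at 0
against all other cultivars although S1 shares 4 of 5 bands per
enzyme with each); it is excluded from the package.

## UPGMA clustering

Trees are built on the complement distance d = 1 − s. UPGMA proper
(size-weighted averages over all leaf pairs, not WPGMA) is implemented
directly rather than delegated, because determinism requires explicit
conventions the delegate would not provide:

* tie-break — when several cluster pairs share the minimal average
  distance, the pair whose smallest member label sorts
  lexicographically first merges (further ties on the partner's
  smallest label). The protein matrix, with six identical cultivars,
  exercises this heavily.
* Newick child order — the subtree containing the lexicographically
  smallest leaf prints first.

Merge heights are the full average pair distance; Newick branch
lengths follow the ultrametric convention (leaf depth = height/2).
Correctness is cross-checked in the test suite against two
independent routes: a brute-force oracle that recomputes every
inter-cluster average from the original leaf distances at each step,
and SciPy's average-linkage cophenetic matrices on tie-free random
inputs. Merge-height monotonicity (no inversions), exactness on
ultrametric inputs, and the ultrametric three-point condition of the
cophenetic matrix are asserted as properties. `cut(tree, k)` removes
the k − 1 highest merges.

The tree computed from the published SCoT similarity matrix merges
(S5, S7) first at d = 0.111 — the published similarity maximum — and
its deepest split separates {S2, S3} from the remaining eight
cultivars. The original study's prose does not state a topology for
this tree, and its figure is not machine-readable; the companion
specification asserts a different topology ({S1,S2,S3} vs the rest,
with {S4,S5}, {S6,S7}, {S8,S9} as sister pairs). That topology is
unreachable from the published matrix under *any* agglomerative
linkage: d(S5,S7) = 0.111 is the global minimum, strictly below
d(S4,S5) = 0.139, so S5 pairs with S7 before S4 can reach it. The
corresponding acceptance test asserts the specified topology and is
left failing by design; the true computed topology is frozen in the
clustering unit tests.

## Synthetic data generator

The generator emulates scored dominant-marker panels so every stage
can be validated against planted truth. Defaults mirror the study
panel: 10 genotypes, 44 bands in 8 primer groups sized
(7, 3, 3, 3, 11, 7, 4, 6), per-band presence probabilities uniform on
[0.3, 0.95] — roughly the frequency range a gel scorer retains, since
rarer bands are unreliable calls. Options: fixed frequency, a planted
genotype partition with per-cluster template profiles and independent
per-band Bernoulli(δ) flips per member (modelling scoring dropout and
ghost bands), and planted unique-positive/negative bands that are
exact by construction. All-zero locus rows are resampled, mirroring
the no-unobserved-locus invariant. A single integer seed drives one
generator with documented stream order (frequencies, templates,
presence entries, unique placements), so a spec + seed pair is fully
reproducible.

What the generator does not emulate: electrophoretic mobility physics,
primer-binding thermodynamics, correlated scoring errors within a gel
lane, and band-size distributions (sizes are synthetic placeholders).
Passing recovery tests therefore show the pipeline's statistical
machinery is sound under independent-noise conditions, not that real
gel data meet those conditions.

Measured with the packaged drivers (200 replicates per condition,
blocks of 5 genotypes): the k = 2 cut recovers the planted partition
in 100% of replicates at δ ≤ 0.05, degrading at δ = 0.15 and
collapsing by δ = 0.30; planted unique markers are recovered in all
replicates at δ = 0.

## Pipeline and reproduction surface

`run_analysis` consumes a config (inputs, coefficient, rounding,
optional cut level), writes per-assay locus stats, primer summaries,
marker tables, similarity matrices and Newick trees, pooled outputs
when several assays are given, and a manifest with parameters and
input checksums; identical config and inputs give byte-identical
outputs. `reproduce_study` recomputes every desk-reproducible
published number (38 checks) and reports computed vs published;
`lagenaria reproduce` exits non-zero if any check fails, and flipping
a single presence bit in a band matrix is detected.

## Problem sizes and tolerances

All study computations are exact-scale (≤ 27 loci × 10 genotypes plus
a 10 × 10 similarity matrix) and complete in well under a second.
Property suites use 500 random ≤ 7-leaf matrices for the UPGMA oracle
and 200 seeded replicates for cluster recovery — sizes at which the
brute-force oracles remain exact and fast. Float comparisons against
published 3-decimal values use decimal half-up rounding rather than a
tolerance; internal cross-route comparisons use absolute tolerances of
1e-9 to 1e-12.

## Known limitations

* The published SCoT band matrix itself is unavailable; SCoT analyses
  start from the published counts, marker list and similarity matrix.
* Published per-primer EMR/Rp/MI values cannot be reproduced (above).
* Two published similarity tables contain internal inconsistencies
  (one pooled cell; the whole isozyme-only matrix) and are handled as
  described.
* Dendrogram figures in the source are not machine-readable; only
  numerically derivable tree statements are testable.
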