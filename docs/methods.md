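# Methods

## Scope and data model

`repfrac` analyses bulk TCRβ repertoires at the clonotype level. A
*clonotype* is the set of T cells sharing one CDR3β amino-acid sequence; it
carries one assigned V and one J segment, the summed read count of all
nucleotide sequences encoding it (its *copy number*, CN), and those
nucleotide variants with their individual read counts. A *repertoire* is one
animal's clonotype set plus sample metadata.

Preprocessing mirrors standard bulk-TCR practice: tables of nucleotide
sequences (MiTCR-style, AIRR-rearrangement-style or a plain TSV dialect) are
read, optionally downsampled to a common read depth, merged to clonotypes,
and CN-1 clonotypes are removed as likely sequencing artefacts.

* **Downsampling** draws the target number of reads without replacement from
  the pooled per-sequence counts (multivariate hypergeometric), before
  merging, and is deterministic given a seed.
* **V/J assignment** after merging copies the segments of the nucleotide
  variant with the highest read count. Ties are broken by the
  lexicographically smallest nucleotide sequence — a documented convention;
  any deterministic rule would do, but the choice must be stable for
  round-trip identity.
* **CN-1 removal** is applied at the clonotype level, after merging.

## Indices

For a repertoire (or CN fraction) `X = {x_1..x_m}` and a reflexive,
symmetric similarity relation `R`:

* **RHI_R(X)** = (number of unordered pairs `i < j` with `x_i R x_j`) /
  `C(m, 2)` — the probability that a randomly drawn clonotype pair is
  similar; a generalized Simpson index. It is undefined (explicit flag, not
  zero) for `m < 2`; undefined values are excluded from group statistics so
  sparse fractions cannot silently bias rank tests.
* **D_NC(x)** = `1 − Σ_i (ν(x^(i)) / ν(x))²` over the nucleotide variants of
  one clonotype, and **CDI(X)** is the mean of `D_NC` over clonotypes —
  values near 0 mean essentially single coding, values near 1 balanced
  coding by many variants.
* **RSI_R(X, Y)** = `2·[Σ 1(x_i R y_j)/(nm)] / [Σ 1(x_i R x_j)/m² +
  Σ 1(y_i R y_j)/n²]`, the self sums running over ordered pairs including
  the diagonal. Under the identity relation RSI is the Sørensen index; it
  can exceed 1 for non-transitive relations, which is why the dissimilarity
  truncates it.
* **d_{α,R1..Rk}(X, Y)** = `1 − Σ α_i·min(RSI_{R_i}, 1)` with non-negative
  weights summing to 1. Two presets: `d_V,J` (V-identity and J-identity as
  two equally weighted criteria) and `d_NC` (the variant-count relation).

Relations provided: V/J identity (`VJ`, `V`, `J`), CDR3 Levenshtein distance
≤ 1 (`LD`), CDR3 identity, and the nucleotide-coding count relation (`NC`:
similar iff the numbers of coding variants coincide or both exceed 5). The
"exceeds 5" rule is implemented strictly (> 5, i.e. ≥ 6) with a configurable
threshold; this merges all counts above the threshold into one class, which
makes the relation an equivalence.

### Weighted variants

The copy-number-weighted RHI draws the pair with probability proportional to
the product of copy numbers over *distinct* clonotypes:
`Σ_{i<j} ν_i ν_j 1(x_i R x_j) / Σ_{i<j} ν_i ν_j`. This collapses to the
unweighted RHI under uniform copy numbers, and a dominant clonotype similar
only to itself drives the value to 0. The weighted RSI replaces the uniform
`1/m`, `1/n` weights with read proportions; under the identity relation it
equals the Morisita–Horn index, under uniform counts the unweighted RSI.
These limiting behaviours are pinned by tests against textbook oracles.

### Computation

RHI/RSI on non-transitive relations are quadratic in general. Two fast paths
keep cohort-scale analyses cheap, each gated by brute-force
double-loop equivalence tests on hundreds of random instances:

* equivalence relations (VJ, V, J, identity, NC) reduce to class-size
  combinatorics, `Σ C(g, 2)` and cross-class products;
* the LD ≤ 1 relation uses deletion signatures: two equal-length strings
  differ by one substitution iff they share a (position, deleted-string)
  key, and indel pairs are found by hashing the deletion sets, giving
  `O(n·L)` pair counting.

Levenshtein distances themselves go through `edlib` (unit-cost edit
distance), checked against a naive recursion in the tests.

## Fractioning

Three schemes over preprocessed repertoires (all CN ≥ 2):

* **tripartition** — CN_low: CN = 2; CN_med: 2 < CN ≤ 500; CN_high: CN > 500;
* **log2** — ten fractions, fraction k (k = 1..9) holding
  2^(k−1) < CN ≤ 2^k and fraction 10 holding CN > 512. Fraction 1 equals
  CN_low; clonotypes with 500 < CN ≤ 512 belong to CN_high but to fraction 9
  — the boundary asymmetry of the published definitions is kept and asserted
  in tests;
* **custom** contiguous half-open intervals via configuration.

Sub-repertoires X_top (CN > 64, i.e. log2(CN) > 6) and X_bottom (CN ≤ 4)
feed the classification analyses; a custom CN threshold (e.g. the
log2(CN) > 8 variant) is available. Empty fractions are retained so
downstream tables always have a fixed 10-column layout.

## Group statistics

Per fraction, the per-animal index values of the two groups are compared
with the Mann–Whitney U test (one-sided "less" tests a decrease in the
immunized group). The exact null distribution is used for combined n ≤ 20
without ties, otherwise the normal approximation with tie and continuity
correction. The ten p-values of one index row are corrected with Holm's
step-down method, each row independently. Fractions undefined in too many
animals are marked skipped, never imputed. Jaccard overlap is reported
descriptively only (all-pairs values with a within-group flag): the pairwise
design violates the independence assumptions of rank tests.

## Classification

A cohort of sub-repertoires yields a symmetric, zero-diagonal dissimilarity
matrix under `d_V,J` or `d_NC`; empty sub-repertoires are excluded with a
warning. K-medoids uses exhaustive medoid search whenever `C(n, k)` is small
(always true at cohort scale, giving the global optimum) and PAM BUILD+SWAP
otherwise; the seed only breaks ties. Visualization uses classical metric
MDS (principal-coordinates analysis via scikit-bio); tests compare embedded
distances, never raw coordinates, since orientation is arbitrary. Supervised
classification is leave-one-out: one medoid per label group is fitted on the
training samples (the sample minimizing summed within-group dissimilarity),
and the held-out sample takes the label of the nearer medoid; distance ties
predict "control" (conservative toward the null) and are logged. The
confusion table is evaluated with a two-sided exact Fisher test against
random labelling. As in the underlying study design, sub-repertoires and
criteria are chosen with knowledge of where effects live, so Fisher p-values
can overstate discriminatory power on real data; the package reproduces the
procedure and documents rather than corrects this.

## Synthetic cohorts

No public data accompany the analyses this package implements, so the
generator produces labeled cohorts whose structure carries the same signals.
Defaults (all configurable in `SyntheticCohortConfig`):

| parameter | default | rationale |
|---|---|---|
| n_control / n_treated | 20 / 10 | the study-scale group sizes |
| clonotypes per animal | 3000 | desk-scale stand-in for ~50k–100k |
| private CN | power law, exponent 2.5 on [2, 20000] | monotone-decaying fraction occupancy with most clonotypes at CN = 2 |
| public CN | power law, exponent 1.3 | publics span all ten fractions with far higher mean CN than privates |
| public pool | 150 prototypes + 2 LD-1 satellites each | convergent-recombination cluster structure |
| public share probability | 0.8 | publics present in most animals |
| public CDR3 length shift | −2 | publics are shorter on average |
| public VJ usage | Dirichlet concentration 0.05 over 20×14 V×J | restricted VJ usage of publics |
| public / private codings | ≥ 2 (2 + Poisson(1.5)) / mostly 1 | convergent coding of publics |
| CDR3 length | discretized normal, mode 14, sd 2, clipped to 8–20, C...F frame | plausible murine CDR3β lengths |

Satellites inherit their prototype's VJ pair and a correlated, somewhat
lower copy number (prototype CN × 2^−U(0,2)), so LD-1 cluster structure
co-occurs within CN fractions. Nucleotide variants are produced by reverse
translation with uniform synonymous codon choice, distinctness enforced by
rejection; variant read counts split the copy number with every variant
getting at least one read.

The **immunization effect** inserts animal-unique, single-coded private
clonotypes with copy numbers drawn log-uniformly inside a target range of
log2 fractions. Two presets: the early response (40 specific clones per
animal into fractions 7–10) and the late response (400 clones into fractions
1–2; the late effect involves many re-immigrating low-CN clones, hence the
larger count). Injection dilutes the public structure of the targeted
fractions — fewer VJ-restricted, multi-coded, clustered publics per pair —
which decreases RHI_VJ, RHI_LD, CDI and cross-animal Jaccard exactly where
the clones land, and nowhere else. Read-total conservation during injection
(hypergeometric thinning of the other clonotypes) is available but off by
default, since real repertoires are depth-normalized upstream.

What the generator does *not* emulate: V(D)J generation probabilities,
selection, sequencing error, clonal competition dynamics, TCRα pairing, or
realistic (skewed) V/J usage among private clones (drawn uniformly here).
Passing tests therefore show that the indices, fractioning, statistics and
classification recover displacement effects of the modelled kind at the
configured effect sizes — not that those effect sizes match any particular
biological dataset.

## Calibration and problem sizes

The test suite verifies, on top of unit oracles:

* type-I error — on ≥ 500 Holm-corrected null rows (cohorts of 6 + 6
  animals, 700 clonotypes each, no injected effect) the fraction of rows
  containing any adjusted rejection at α = 0.05 stays within 0.05 + 2·SE;
* chance-level classification — mean leave-one-out accuracy on 200 null
  cohorts is within 2·SE of 50%;
* effect recovery — the early preset yields Holm-adjusted significance for
  RHI_VJ and CDI inside fractions 7–10 and none in the untargeted fractions
  5–6; the late preset the analogous low-CN pattern; d_V,J leave-one-out
  classification of X_top beats random labelling by Fisher test;
* direction of change — both injections decrease the cohort-level medians
  of RHI_LD, RHI_VJ, CDI and cross-animal Jaccard in the targeted fractions.

Calibration cohorts are smaller than the demonstration cohorts (6 + 6
animals, 500–700 clonotypes); these are the package's chosen simulation
sizes for replicate-heavy checks, and the statistical guarantees being
tested are size-free.

## Numerical and degenerate-input choices

* Indices on fewer items than their formula supports return an explicit
  undefined flag (NaN value), never zero.
* `d` values are clipped into [0, 1] after the `min(RSI, 1)` truncation;
  dissimilarity matrices must be symmetric within 1e−12 with an exactly zero
  diagonal.
* All-zero dissimilarity matrices embed at the origin with a warning.
* The root seed fans out through named integer substreams
  (`default_rng([seed, stream, animal_index])`); identical seeds give
  bit-identical cohorts, tables and result bundles.

## Known limitations

* The NC relation's "> 5" threshold is a convention (the boundary between
  "coincides" and "both exceed" is ambiguous at exactly 5); it is
  configurable.
* Jaccard and identity comparisons use the CDR3 amino-acid sequence only; a
  strict mode additionally requiring V/J equality is available.
* The generator's effect sizes are free parameters chosen so the qualitative
  displacement directions are recoverable at desk scale; they are not fitted
  to any dataset.
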