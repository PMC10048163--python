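# Methods

This note documents the models and procedures implemented in `g4families`,
the parameter choices that matter, and what the synthetic benchmark does
and does not demonstrate.

## Detection by tract chaining

A G4 region is a maximal chain of guanine tracts (runs of ≥ `min_tract_len`
consecutive G, default 3) whose consecutive gaps all lie in
[`loop_min`, `loop_max`] = [1, 7]. Detection deliberately chains tracts
instead of applying the literal regular expression
`G{3,}([ACGT]{1,7}G{3,}){3,}`: greedy regexes are ambiguous about
overlapping matches, while chaining makes the placement arithmetic exact —
a chain of k tracts admits k − 3 windows of four consecutive tracts and
⌊k/4⌋ pairwise-disjoint windows (greedy left-to-right selection is optimal
for interval scheduling). Chained loops may themselves contain guanines
(in sub-threshold runs), so a chained region can properly contain a regex
match; the test suite asserts this containment relation rather than
equality. Two-tetrad scanning (`min_tract_len=2`) exists behind the flag
but is off by default because of its computational false-positive rate.

Coordinates are 0-based half-open on the plus strand everywhere; 1-based
browser labels are converted only at I/O. Minus-strand regions carry the
plus-strand (C-rich) interval plus the scanned G-rich sequence, which is
what flows into clustering.

## Initial clustering

**Sphere stage.** Centres are chosen longest-first (ties lexicographic) for
determinism; every unassigned sequence within Levenshtein radius 2 of the
centre joins the sphere, subject to a group filter (same tract count,
length within ±radius). The radius is a package decision (the divergence of
near-identical G4 copies is one or two edits); it is exposed in
`SphereParams`. Singleton spheres are passed to the similarity stage.
Edit distances are computed with edlib (banded early exit for radius
queries); the trie-based message-passing optimisation used by barcode
clusterers is not re-implemented because it changes only speed, not the
resulting partition.

**Similarity stage.** Leftovers get all-vs-all Smith–Waterman local
alignment (match +2, mismatch −3, gap open −5, extend −2) converted to
E-values with the Karlin–Altschul formula E = K·m·n·exp(−λS), λ = 0.625,
K = 0.41, m·n the pairwise search space. Similarity is max(0, −ln E);
distance is the off-diagonal maximum similarity minus the pair similarity,
so the most similar pair sits at distance 0. Self-similarities are
excluded from the maximum — including them would prevent any identical
pair shorter than the longest input from reaching distance zero. Running
an external alignment search tool is deliberately avoided; the closed-form
E-value preserves the −log(E) semantics without a binary dependency.

**Hierarchy and k.** Ward, complete and average linkage use standard
agglomeration; the divisive method is DIANA-style (split the
largest-diameter cluster, seeding the splinter with the point of highest
mean dissimilarity). The number of clusters is chosen by the inertia-ratio
rule: with I_m the total within-cluster sum of squared distances to each
cluster medoid at the m-cluster cut, the chosen k is m + 1 for the m
maximising I_m/I_{m+1} — the cut just after the largest relative drop.
Ratios with a zero denominator (all-singleton cuts) are skipped. Medoid
inertia is used because the input is a general dissimilarity, not points
in a vector space. The alternative consensus rule takes the mode of five
internal indices at their standard optimum directions (silhouette and Dunn
maximise, C-index and McClain minimise, Frey keeps the last k with
successive ratio ≥ 1), ties broken toward smaller k. Raw McClain is known
to keep shrinking as clusters split, so its vote often sits at the top of
the k range; the consensus mode absorbs this.

## Alignment and consensus

Progressive alignment follows a UPGMA guide tree over pairwise edit
distances, with profile–profile Needleman–Wunsch (Gotoh affine gaps;
match +1, mismatch −1, open −2, extend −0.5 — tuned for ≤ 40 nt G-rich
sequences and exposed in `AlignScoring`). A post-pass shifts gaps between
score-neutral placements: a move (swapping a gap with an adjacent residue
in one row) is accepted when the sum-of-pairs score is unchanged and the
column-homogeneity objective Σ_cols Σ_base count² strictly improves, or is
neutral and the gap moves left. Each accepted move strictly increases the
lexicographic key (objective, −Σ gap positions), so the pass terminates at
a fixed point and is idempotent. Degapped rows always reproduce the
inputs.

The gap score is the overall gap fraction, total gap characters divided by
rows × columns. The phrase "average number of gaps in each column divided
by the length" admits a per-column and a per-alignment reading; the
per-alignment fraction is used because it is bounded in [0, 1], matching
the 0.07/0.10/0.6 thresholds used as fractions. The IUPAC consensus emits,
per column, the minimal degenerate code covering all bases whose frequency
is at least 0.5 × the modal base's frequency; gap-majority columns emit
'-'. The 0.5 plurality reproduces the mixed literal/ambiguity style of
published family consensus strings.

## Plan7 profile HMMs

Columns with gap fraction ≤ 0.5 become match states; others are modelled
by inserts. The seven transition types (M→M, M→I, M→D, I→I, I→M, D→M,
D→D) plus begin/end are counted from the alignment's implied state paths
and normalised after adding a Laplace pseudocount of +1 to every emission
and transition count — the pseudocount keeps all paths finite for
four-member clusters at the cost of flattening tiny alignments, and is
configurable. Scoring is global (begin at node 0, end after node m);
local entry/exit wings are unnecessary because training sequences are
full-length minimal G4s. Log odds are natural-log, against a uniform
null by default (background frequencies estimated from a training pool
are available via `NullModel.from_sequences`); the acceptance threshold
"log odds 5" is therefore in nat units. Forward and Viterbi recursions run
in log space; Viterbi tie-breaks are M > D > I. Correctness is established
against exhaustive path enumeration on all models with m ≤ 3 and
sequences of length ≤ 4 (exact to 1e−9 in log space).

## Refinement into families

Per iteration: align each cluster, train its profile, score every
cluster's test set (its own members by default; profile-sampled sequences
via `test_set="sampled"`) against every profile, and run one-sided
Wilcoxon rank-sum tests of own-profile versus rival-profile scores
(exact distribution for samples ≤ 10 without ties, otherwise normal
approximation with tie and continuity corrections; p-values are raw —
no multiplicity correction, with Benjamini–Hochberg available off by
default). A profile is accepted when distinct against all rivals
(p < 0.05), its alignment gap score is < 0.10, and its members' mean
Akaike weight for it is ≥ 0.99 ("probability 0.99" is operationalised as
mean membership weight; a min-based reading is a config switch).
Mutually non-distinct profiles are pooled by connected components and
merged into one cluster; if the merged alignment's gap score reaches 0.6
the pool is instead re-clustered (average linkage on pairwise edit
distance, inertia-rule k). The loop stops when the partition stops
changing or after 100 iterations, and is deterministic given the seed.
Clusters below four members are dropped throughout.

Cross-method redundancy merging scores each family's members against
every other family's profile: families merge when mean cross log odds
≥ 5 and mean cross Akaike weight ≥ 0.7, computed with the family's own
profile left out of the weight normalisation — with the own profile
included, a member's twin profile is mathematically capped near weight
0.5 and the 0.7 threshold could never fire. A merge is kept only if the
re-trained family's gap score stays ≤ 0.07.

Classification computes forward log odds against every family and
normalised Akaike weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) in log space.
The model-complexity term k defaults to 0 for all families (family model
lengths are similar, so AIC reduces to likelihood weights); a
free-parameter-count mode is available. Ties in the argmax break toward
the lowest family id.

## Restricted quadruplex thermodynamics

The structure space is every placement of four equal-length G sub-tracts
(layers L ≥ 2, window anywhere inside a guanine run) joined by linkers of
1–7 nt, plus the open chain at E = 0. The energy is
E = α(L−1) + trunc(β·ln(ltot−2)) with α = −18.00 kcal/mol per stack step
and β = 12.0 kcal/mol — the established quadruplex parameterisation used
by RNA secondary-structure folders — with the linker term truncated toward
zero at the 0.01 kcal/mol resolution. Truncation, not rounding, is
required: 12·ln 2 = 8.3177 must contribute 8.31 (giving −27.69 for a
three-layer placement with four linker bases), where rounding would give
8.32/−27.68. At ltot = 3 the linker term is exactly zero, so the most
compact three-layer quadruplex scores −36.00 kcal/mol.

Boltzmann statistics use RT = 0.61633 kcal/mol (37 °C):
Z = 1 + Σ exp(−E/RT) over placements, ensemble free energy −RT·ln Z, MFE
frequency 100·exp(−E_mfe/RT)/Z, and diversity the expected pairwise
symmetric difference of tetrad-involved position sets (the open chain
contributes the empty set). MFE ties break leftmost, then most compact.
Ambiguity codes and gaps in consensus strings are loop bases. Because
canonical base-pair competition is outside the model, ensemble quantities
are faithful only where the quadruplex dominates; consensus sequences
whose published ensembles include hairpin competition will disagree, and
no claim is made for them.

## Synthetic benchmark

`simulate` builds family templates (four conserved G-tracts, distinct loop
lengths and letters per family), mutates only the loops — substitutions at
rate 0.05 and at most one 1-nt loop indel per loop at rate 0.02, with
loops kept inside the detectable 1–7 nt range and never mutated to G — and
plants members on random strands in i.i.d. background DNA of GC 0.4,
separated by ≥ 20 nt margins. The default benchmark is 5 families × 20
members on a 20 kb background; the pipeline recovers all five (ARI 1.0 at
seed 1) in well under a minute on one CPU. Loop-only mutation mirrors the
biological prior that tracts are conserved; tract erosion is available
(`tract_mutation_rate`) to stress-test robustness. The background has no
repeat structure and member counts are balanced, so passing the benchmark
demonstrates correctness of the machinery under the stated divergence
regime, not performance on genomic repeat families, unbalanced family
sizes, or two-tetrad structures.

## Numerical and degenerate-input conventions

Log-space arithmetic throughout the HMM with −1e30 as log 0; emission and
transition rows validated to sum to 1 ± 1e−9. Constant (all-zero) distance
matrices make k selection report a degenerate, undefined k rather than an
arbitrary one. Empty sequences are scoring errors; sequences without four
tracts yield empty placement lists and an open-chain ensemble (frequency
100%, diversity 0). Family bundles and profile JSON are version-stamped
and reject schema mismatches. All randomness flows through explicit seeds
(numpy Generator); identical config + inputs + seed give byte-identical
bundles.

## Known limitations

- The forward scorer is global-alignment only by default; strongly
  truncated queries are better handled by extracting minimal placements
  first (the detection module does this).
- The Karlin–Altschul parameters are ungapped-regime constants applied to
  gapped local scores; similarities are comparative quantities, not
  calibrated significance estimates.
- Akaike weights with k = 0 assume comparable model complexity across
  families; families with very different model lengths would warrant the
  free-parameter mode.
- The thermodynamic model omits canonical base pairing, loop-composition
  effects and cation dependence; energies are comparable within the model,
  not absolute measurements.
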