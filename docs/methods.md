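# Methods

`rnaswitch` discovers bi-stable RNA structural switches — cis-regulatory
elements that populate two mutually exclusive secondary-structure
conformations — from sequence alone, and carries the prediction through
to experimental design and screen analysis. This note documents the
models, the parameters that matter, the synthetic-data generators, and
the numerical choices, in enough detail to reproduce or modify any
stage.

## 1. Ensemble sampling and the backend contract

All downstream analysis consumes a Boltzmann sample of N secondary
structures (default N = 1000). Two backends implement one contract
(`sample`, `evaluate_energy`):

* **Exact toy backend** (`ExactToyBackend`). Additive energy model:
  E(S) = −1.0 kcal/mol per canonical pair (AU, GC, GU), kT = 0.6163
  kcal/mol (≈310 K), minimum hairpin loop of 3 nt, pseudoknot-free.
  The partition function is computed by the standard interval dynamic
  programme, structures are drawn i.i.d. by stochastic traceback, and
  two exact oracles are exposed: full enumeration with Boltzmann
  probabilities, and base-pair probabilities by an inside–outside
  recursion (O(n⁴), n ≤ 30 by default — the length cap exists because
  enumeration and the DP tables grow quickly, and exactness is the
  point of this backend).
* **ViennaRNA adapter** (`ViennaBackend`). Thin pass-through to the
  nearest-neighbor engine: partition function + stochastic backtracking
  (`uniq_ML`), `eval_structure` for energies, seeded deterministically.

Chemical-probing restraints enter as per-position pairing penalties
ΔG(i) = m·ln(r_i + 1) + b with defaults m = 1.8, b = −0.6 kcal/mol (the
standard probing-directed folding parameterization); missing positions
contribute nothing. Restraints modify **sampling only**; reported
energies are always unrestrained. (The alternative — also penalizing
the energies handed to the classifier — would double-count the data;
the restrained ensemble already shifts every downstream statistic.)

A caveat used throughout this note: the toy model has no stacking
cooperativity. A full helix has exactly the same energy as the sum of
its pairs, so bulged sub-states, shifted pairing registers, and
"chimeras" that split a shared arm between two competing helices are
all iso-energetic with the pure conformations. Toy ensembles are
therefore much blurrier than nearest-neighbor ensembles. This is a
feature for testing (every probability is computable in closed form)
but it shapes several operational definitions below.

## 2. Conflict detection (mutual-information base pairing)

Each base pair observed in the ensemble becomes a binary presence
vector of length N. Pairs present in almost all or almost none of the
folds are removed (defaults f_min = 0.05, f_max = 0.95; these keep only
pairs that can actually covary). Plug-in mutual information (base-2 logs, 0·log 0 ≡ 0)
is computed for every pair of presence vectors; the row sums K of the
M×M MI table score each base pair's total involvement in alternative
structure, excluding the diagonal (self-information would swamp the
sum). Pairs with K ≥ U·max(K) (U = 0.5, inclusive so the maximum always
survives) are the *conflicting base pairs*. Adjacent conflicting pairs
((a,b), (a+1,b−1)) are merged into maximal stems; stems longer than 3
pairs are kept; two stems conflict when any of their four arm-interval
overlaps exceeds 3 positions (both thresholds strict).
Conflicting stem pairs are ranked by the mean K of their constituent
pairs, ties broken lexicographically by stem coordinates for
deterministic output. The top pair is the switch prediction; an empty
ranking means "no potential switch".

The MI base matters only as a global scale: K scales uniformly, so the
U·max(K) filter and all rankings are base-invariant.

## 3. Conformations and the activation barrier

For each stem of the winning pair, the corresponding conformation is
predicted by maximum-expected-accuracy (MEA) folding over the
ensemble's pair frequencies p(i,j): maximize Σ_pairs 2γ·p(i,j) +
Σ_unpaired q(i), q(i) = 1 − Σ_j p(i,j), γ = 1.0, by a Nussinov-style
DP. The stem's pairs are forced (large score bonus) and pairs crossing
or sharing endpoints with them are forbidden. Accuracy, not free
energy, is the objective — the ensemble, not the single minimum,
defines each conformation.

The barrier of the conf1 → conf2 transition is estimated by beam search
(default width 50) over single base-pair additions/removals restricted
to the symmetric difference, so every path has exactly |conf1 Δ conf2|
steps. The barrier is max path energy − E(conf1). The estimate is an
**upper bound** on the true minimal direct-path barrier and is labeled
as such in output records; on instances small enough for exhaustive
path search the beam reproduces the exact optimum (tested), and the
identity B(1→2) − B(2→1) = E(conf2) − E(conf1) holds for reversed
paths. Indirect paths (transient pairs outside both conformations) are
out of scope.

The two classifier features are the mean of the two conformations' free
energies and the activation energy.

## 4. Classifier and transcriptome-style scanning

The switch classifier is a literal least-squares regression of the
binary label (switch vs dinucleotide-preserving shuffle) on the two
features. Scores feed only rankings and ROC curves, for which any
monotone link is equivalent, so the linear probability model is used as
stated rather than logistic regression. Fitting requires both classes
and a non-singular design.

Negatives are produced by the Altschul–Erickson dinucleotide shuffle:
a uniform-random Eulerian path over the dinucleotide multigraph, with
the arborescence of last-edges sampled by Wilson's loop-erased random
walk. Dinucleotide counts and both terminal residues are preserved
exactly.

Evaluation is leave-one-family-out: the held-out family never
influences its own model; a held-out family containing a single class
yields an undefined-AUC marker. AUC is the Mann–Whitney statistic with
half-credit ties.

Long sequences are scanned as overlapping fragments (defaults 186 nt,
93 nt overlap). Windows start at 0 with stride = length − overlap; when
the final stride leaves a remainder, one additional full-length window
anchored at the 3′ end is added so every nucleotide is covered.
Fragments with no detected stem pair are excluded from the ranking;
ties break by fragment coordinates.

## 5. Conformation-locking mutation design

Four variants per candidate: A (strengthen stem 1), B (weaken stem 2),
C (strengthen stem 2), D (weaken stem 1); A/B lock conformation 1, C/D
lock conformation 2. Strengthen rewrites the stem's 5′ arm and writes
the reverse complement into the 3′ arm; weaken rewrites one arm of the
rival stem, leaving the kept stem untouched. Filters: (i) for weaken,
the kept stem's pairing must be fully preserved (edits overlapping its
arms are rejected outright); (ii) the rival stem must not re-form more
than 0.6 of its original pairs, operationalized as the count of its
original (i,j) coordinates that are canonical pairs in the mutant;
(iii) the edit must not create an antiparallel complementary run longer
than 4 between the edited segment and any region disjoint from all
edited intervals (runs between two co-edited arms are the intended
pairing and are not penalized; GU counts as pairing). Comparisons are
strict. Survivors are ranked by L1 mononucleotide
composition distance from the reference (ties by mutant sequence), the
conventional `offset-REPLACEMENT` label is attached, and all edits are
same-length replacements so stem coordinates never shift.

Enumeration is exhaustive for edited intervals up to 7 nt (4⁷ =
16,384); longer intervals fall back to seeded random search with a
100,000-candidate budget. Candidates are evaluated lazily in rank
order.

**Verification.** Each candidate is verified by sampling its own
ensemble and measuring how the ensemble divides between the two
conformations. The default statistic (`conformation_share`) assigns
each fold to the stem whose two arm intervals it connects with more
base pairs — any register between the arms counts, because a slid
helix between the same two strands is the same gross conformation —
and reports the two conformations' shares of the assigned folds. A
variant is *shifted* when the target share is ≥ 0.8 and the rival share
is ≤ 0.2. This share-based reading was chosen because the two
thresholds are complementary (they describe a two-state balance), and
because under the non-cooperative toy model absolute ensemble fractions
saturate around 0.8 even for perfectly locked designs (iso-energetic
slides and third-party pairings always hold the remainder), which would
make an absolute-fraction verdict a coin flip. Absolute-fraction and
per-fold stem-membership statistics remain available
(`stem_fraction_mode` = `interval_contact`, `fold_membership`,
`pair_mean`). The design loop verifies candidates in rank order (up to
`max_verify_candidates` = 200 — composition-minimal edits are often too
gentle for the toy model, so the search must be allowed to go deep) and
returns the first verified candidate per class; a class with no
verified candidate raises a partial-set error naming the class.

## 6. Reactivity processing and the probing support test

Mutational-profiling counts become per-position rates (undefined below
100× coverage). Boxplot normalization: the top ceil(0.10·n) defined
positions by rate are outliers (ties broken by position index); the
scale factor is the mean of the next decile (the 80th–90th percentile
band — the common probing-normalization convention; the 1.5×IQR variant
was considered and not needed for any tested behavior); values are
divided by the scale factor and outliers are capped at the largest
non-outlier normalized value. Normalization is scale-equivariant by
construction. Region accessibility is the mean normalized reactivity
over a region's informative positions — A/C only under DMS chemistry
(default), all residues for SHAPE-class reagents.

The probing support test asks whether in-vivo data are consistent with
the two in-silico conformations: the switch prediction is re-run with
the normalized reactivities applied as sampling restraints, and the
data are *supportive* iff a stem pair matching the in-silico pair
appears among the top T = 5 ranked conflicting pairs, where matching
means per-stem base-pair Jaccard ≥ 0.5 with stem order free. Jaccard
0.5 tolerates the one-to-two-pair trimming that register blur induces
while rejecting unrelated or single-conformation outcomes; T = 5
covers the near-duplicate trimmed variants of one true pair that
typically populate the top ranks.

## 7. Screen scoring

Sort-seq counts (8 expression bins × 2 replicates) are normalized by
median-of-ratios across all 16 samples: per-variant geometric means
over samples (variants with any zero excluded from the reference set),
per-sample size factor = median count/reference ratio. A variant's
functional effect is a one-way chi-squared test of its
replicate-summed, integer-rounded bin totals against uniformity
(df = 7), with a direction sign from the read-weighted mean bin.

A candidate switch is scored from its four variants' 16-vectors of
normalized counts: score = mean(corr(A,B), corr(C,D)) −
mean(corr(A,C), corr(A,D)), exactly this asymmetric pairing (an
optional symmetrized mode adds B–C and B–D). A constant vector makes
its correlations — and the score — undefined rather than raising.
Candidates with scores strictly above mean + 1 sample (n−1) standard
deviation of the finite scores are called significant. RNA counts are
the scored material; gDNA is carried for abundance QC only.

A genuine limitation documented here because the synthetic screens
exposed it: median-of-ratios size factors absorb the *consensus* bin
profile of the library, so a variant shaped like the consensus
normalizes to a nearly flat vector whose correlations are noise. The
concordance score can only see shifts **away** from the library
consensus. This is inherent to the normalization, not to the
simulation.

## 8. Synthetic data generators

All tests and the acceptance script run on generated data; every
generator is deterministic in its seed.

* **Bistable sequences** (`make_bistable_sequence`): rc(box) +
  A-linker + box + A-linker + rc(box); the central box pairs either the
  5′ flank (stem 1) or the 3′ flank (stem 2). Defaults stem_len = 7,
  linker_len = 3 (27 nt, within the exact-backend cap). The box is a
  capped homopolymer block over {G,C} (e.g. GCCCCCG), cap letter chosen
  by seed, because block structure minimizes off-register and
  flank–flank pairing; the all-A linkers cannot pair with G/C at all.
  Construction is verified, not assumed: the exact Boltzmann fractions
  of folds siding with each stem (by enumeration) must both lie in
  [0.35, 0.65], else the parameters are rejected. Under the toy model
  the outermost designed pairs are genuinely rare (arm-split chimeras
  carry equal energy), so the pipeline recovers the *cores* of the
  designed stems; `recovers_designed` therefore defines recovery as
  each predicted stem's pairs being a subset of a distinct designed
  stem's pairs. The `probing_informative` flag forces the orientation
  with C-rich flanks: DMS reads A/C only, and only the flanks differ
  between the conformations, so the opposite orientation is invisible
  to the reagent by construction.
* **Reactivity mixtures** (`simulate_reactivity_mixture`): population-
  averaged probing of a two-conformation mixture. Expected rate =
  p·rate(conf1) + (1−p)·rate(conf2); unpaired A/C react at 0.05,
  everything else at the 0.005 baseline (a typical ~10× mutational-
  profiling dynamic range); lognormal position noise (sd 0.1) and
  binomial sampling at the configured depth (default 10,000×).
* **Screen counts** (`simulate_screen_counts`): per (variant,
  replicate), a multinomial of depth 5000 over 8 bins. Bin profiles are
  discretized Gaussians (width 1.2 bins; sorter fluorescence is roughly
  log-normal). Non-switch candidates draw one base mode ~
  Normal(3.5, 0.3) shared by their four variants — a reporter library
  dominated by members near the library median, which is also what the
  consensus-flattening limitation above requires for the score to work.
  True switches (5% of candidates, default 200 candidates) shift A/B by
  −1 bin and C/D by +1 bin (the default effect size).
* **Labeled datasets** (`make_labeled_dataset`): positives are bistable
  fixtures across five construction-geometry families (stem length ×
  linker length); negatives are their dinucleotide shuffles; both run
  through the real feature pipeline on the exact backend. Within a
  family the positive *sequences* are few (the capped-block design
  space is small); variation across examples comes from ensemble
  sampling, which is exactly the variation the classifier sees at
  prediction time.

What passing tests on these fixtures do **not** show: performance on
nearest-neighbor ensembles of natural sequences (no stacking
cooperativity, no non-canonical structure, 27-nt scale vs 186-nt
fragments), probing noise structures beyond binomial counting, or
screens whose variants drift far from the library consensus.

## 9. Problem sizes and determinism

Default analysis sizes, chosen so the full test suite and the
acceptance script each complete in a few minutes on one core: ensembles
of 1000 folds; recovery over 20 fixtures; classifier datasets of
100 + 100 across 5 families; 1000 null screen quartets and 5000
chi-squared null draws; 10 probing seeds per condition. Every random
draw flows from an explicit seed; identical (inputs, config, seed)
reproduce outputs bit-identically, and every output record embeds the
resolved configuration.

## 10. Known limitations

* The toy backend's register blur means exact designed-stem equality is
  not a meaningful recovery target; containment is (see §8).
* The barrier estimator bounds, rather than computes, the minimal
  barrier on large symmetric differences.
* The probing support test inherits DMS blindness to G/U-only regions.
* The mean + 1 s.d. significance rule is sensible only when true
  switches are a small minority of scored candidates, and the
  concordance score is blind to consensus-shaped variants (§7).
* `fit_switch_classifier` is a linear probability model; its scores are
  rankings, not probabilities.
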