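# Methods

## The splitting protocols

All three protocols partition an interaction table — de-duplicated
(peptide, CDR3-β, label) records — into train/validation/test sets whose
target sizes ("budgets") are `round(ratio × n_records)` with a default
90-5-5 ratio. Budgets count all records, positives and negatives alike.

**Random split.** A uniform permutation of record indices cut at the budget
boundaries. Realized sizes match budgets exactly (up to rounding). Peptides
and CDR3-β sequences may appear on both sides of every boundary.

**Hard split.** Peptides are drawn uniformly at random without replacement,
first into test and then into validation, each drawn peptide moving *all*
of its records, until the corresponding record budget is reached; remaining
peptides form the training set. The last drawn peptide may overshoot the
budget — peptide atomicity takes precedence over budget exactness, so a
realized test set exceeds its budget by at most one whole peptide.

**Distance split.** Identical to the hard split except that the draw pool
is restricted to *eligible* peptides: those whose aggregated distance
(below) lies within the realized band bounds [d_l, d_u] and whose record
count lies in [min_count, max_count] (defaults 5 and 5000). Validation
draws continue from the same in-band pool after test is filled. If the pool
empties before a budget is met, the split raises an infeasible-band error
naming the shortfall rather than silently relaxing the band; a refusal is
the contracted outcome for datasets too small or too concentrated for the
requested band, not a failure mode.

Negatives are assigned by their peptide field only; a negative whose
CDR3-β also occurs in training is permitted, as peptide identity is the
quantity the protocols control.

Determinism: each split call uses a single `numpy` generator seeded from
the config; the draw pool is kept sorted so identical inputs and seed give
identical assignments. A distance split with band (0, 100), min_count 1 and
unbounded max_count degenerates to the hard split exactly (same pool, same
RNG stream) — a property the test suite asserts.

## Aggregated distances and bands

For a symmetric zero-diagonal distance matrix over n unique peptides, the
per-peptide aggregate is computed over the row *excluding* the diagonal.
The default aggregator is the median, which tolerates local clusters: a
peptide close to a few neighbours but far from most still receives a large
aggregate. Min is the stringent variant (any close neighbour keeps the
aggregate low); mean is also available. For even row lengths the median is
the average of the two central values.

Band bounds are percentiles of the aggregate distribution under linear
interpolation between closest ranks (`numpy.percentile`, `method="linear"`).
The method had to be pinned for reproducibility; linear interpolation is
numpy's default and the least surprising choice. Eligibility is inclusive
at both bounds.

## Distance metrics

**Levenshtein.** Unit-cost edit distance, computed by `edlib`. An
independent brute-force recursion in the test suite confirms exact
agreement on random pairs.

**BLOSUM pseudo-distance.** Raw alignment similarities are neither zero on
the diagonal nor comparable across sequence pairs, so the score difference

    d(a, b) = S(a, a) + S(b, b) − 2 S(a, b),  clamped at 0,

is used, where S is the Needleman–Wunsch global alignment score (Biopython
`PairwiseAligner`, global mode). This guarantees d(a, a) = 0 and symmetry,
the two invariants the distance matrix requires. Defaults: BLOSUM62, gap
open −10, gap extend −1 — the most common parameterization in sequence
analysis. Gap convention (Biopython's): a gap run of length L costs
`open + (L − 1) × extend`. The clamp is a safeguard; with standard
matrices the difference is non-negative in practice.

**Cα RMSD.** Residues of the two peptides are paired by the match columns
of their optimal global *sequence* alignment (same scoring parameters as
the BLOSUM metric), then superposed by the Kabsch algorithm — closed-form
least-squares rigid superposition via SVD, with the reflection excluded by
sign-flipping the smallest singular vector. Up to 5 rejection cycles then
discard pairs deviating by more than 2.0 Å and re-superpose, mimicking
PyMOL's `align`; `refine_cycles=0` gives the plain superposition RMSD.
Cα-only RMSD is deliberate: predicted side-chain placement is unreliable
and would inflate distances.

Numerical choices worth pinning:

* *Symmetry.* Alignment tie-breaks could differ under operand swap, so the
  RMSD canonicalizes the pair by sequence order before aligning; symmetric
  matrices follow by construction (upper triangle mirrored).
* *Degenerate pairs.* For very dissimilar sequences the unique optimal
  alignment can have fewer than 3 match columns. The pairwise operation
  raises a degenerate-structure error by default; whole-matrix builds
  instead fall back to positional pairing from the N-terminus
  (`degenerate_policy="prefix"`), so one pathological pair cannot abort an
  n × n computation.
* *Tolerances.* Matrix symmetry and zero diagonal are asserted at 1e-9
  relative; rigid-motion invariance of the RMSD is asserted at 1e-6 Å.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical features of curated viral
TCR–peptide tables that the splitting protocols actually interact with:

* **Peptides**: unique random 8–11-mers over the 20-letter alphabet.
  Lengths in this range are typical of MHC class I epitopes. Random
  composition means sequence distances carry no phylogenetic structure.
* **Record counts**: Zipf(1.7) truncated at 500, giving a median count of
  ~2 with a heavy right tail — most peptides occur fewer than 10 times
  while a few dominate, as in real curated tables.
* **CDR3-β partners**: C…F-framed random strings of length 10–16 drawn per
  peptide without replacement, so counts are respected exactly and no
  (peptide, cdr3b, label) triple repeats.
* **Labels**: `random` (fair coin) for calibration studies, or
  `peptide_keyed`, where each peptide carries a latent binding propensity
  in [0.1, 0.9] (bounded away from 0/1 so per-split AUROC stays defined)
  and labels are Bernoulli draws — the peptide-level signal a memorizing
  model can exploit. Propensities are a deterministic function of
  (peptide, seed) via CRC32 mixing, so they can be recomputed without
  threading generator state.
* **Structures**: one Cα trace per peptide on an ideal α-helix (rise
  1.5 Å, 100°/residue, radius 2.3 Å; Cα–Cα chord ≈ 3.8 Å) or extended
  strand, plus an isotropic Gaussian displacement field of configurable
  marginal sd (default 0.5 Å). The field is AR(1)-correlated along the
  chain (ρ = 0.9): uncorrelated per-residue noise of realistic amplitude
  would routinely break the 2.0–4.5 Å consecutive-spacing invariant,
  whereas a smooth field deforms the backbone while keeping bonds intact.
  Draws that still violate spacing are regenerated (10 tries) before
  erroring. Because geometry depends only on length and noise — not on
  sequence — shape and sequence distances are independent by construction,
  which is precisely the regime needed to study them separately.
* **Study dataset**: `generate_study_dataset` chains the full pipeline —
  positives-only table, then balanced shuffled negatives (non-positive
  peptide × CDR3-β combinations, rejection-sampled with an exhaustive
  fallback). Negatives spread nearly uniformly over peptides, so each
  peptide's total count is its skewed positive count plus a near-constant
  share; the per-peptide positive rate then varies with the positive
  count, making the memorization signal arise from the pipeline itself
  rather than from an injected latent variable.

What the generator does **not** emulate: biological CDR3 repertoires
(V(D)J recombination statistics), peptide families and sequence clusters,
MHC restriction, or physically realistic conformations. Passing tests
therefore demonstrate the correctness and discriminative behaviour of the
*splitting machinery* — disjointness, band containment, distance control,
leakage exposure — not predictive performance on real immunological data.

## Benchmark harness

The harness ships two reference predictors behind a scorer interface
(`(peptide, cdr3b) → score`): the peptide-memorization baseline (empirical
positive rate of the pair's peptide in training, 0.5 if unseen) and a
uniform-random baseline. AUROC is computed pooled over the test partition
in the Mann–Whitney formulation (average ranks; ties count half), and is
undefined — an error, not a default — when the test partition is
single-class.

Per split label, results over seeds are summarized as mean ± a
normal-approximation 95 % CI (1.96 · sd/√k). The band-index/AUROC trend
over distance splits is a Spearman rank correlation whose p-value is an
exact two-sided permutation p for up to 8 points (40,320 permutations) and
the asymptotic approximation above that; with the standard 3 bands × 5
seeds = 15 points the asymptotic branch applies. For the memorization
baseline the trend is identically zero — every peptide-disjoint test
record scores 0.5, so its AUROC cannot depend on the band. The harness
reports the cross-split median distance alongside, which does respond to
the band; distance-sensitive trends in AUROC require plugging in a
predictor that generalizes across peptides.

## Desk-scale study conditions

Default problem sizes were chosen once to keep every stage comfortably
within a single-CPU desk budget while preserving the proportions that make
the protocols meaningful: 200 peptides (50–500 in the invariant sweeps),
heavy-tailed counts capped at 500, balanced negatives (≈ 5,000–7,000
records in total), and the 5-seed repetition protocol for benchmark means.

One parameter is deliberately scaled rather than copied: `max_count`, the
record-count cap on held-out peptides. Its default (5000) suits
collection-scale tables; at a few thousand records a single capped-out
peptide would constitute ~15 % of the dataset and could swallow the entire
5 % test budget in one draw. Study runs therefore cap held-out peptides at
7.5 % of total records (`ceil(0.075 × n_records)`), preserving the
cap-to-dataset ratio that the default implies at collection scale.

## Known limitations

* The distance split refuses (rather than degrades) when the band pool
  cannot fill the budgets; on datasets below ~100 peptides with skewed
  counts, banded splits are frequently infeasible at 90-5-5.
* Levenshtein distances between random short peptides concentrate on a few
  integer values, so Levenshtein bands separate poorly — visible in the
  near-constant cross-split medians. The continuous BLOSUM and RMSD
  metrics are the informative choices, and directional checks use them.
* RMSD is not length-normalized; comparisons across very different peptide
  lengths conflate size with shape.
* The shipped predictors are deliberately information-poor baselines;
  conclusions about real models require plugging them into the scorer
  interface.
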