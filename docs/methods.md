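# Methods

## The classification problem

Given protein sequences over the 20-letter standard amino-acid alphabet
with binary class labels (+1 positive, e.g. antioxidant; −1 negative),
the toolkit learns a sequence-only classifier. No structure, homology or
annotation information is used; every signal the model can exploit must
be expressible through residue composition, local group transitions and
positional distribution. Sequences containing ambiguity codes or
non-standard letters (B, X, Z, J, O, U, `*`, gaps) are excluded (or
stripped, under the `coerce` policy) because the descriptor's property
groups are defined only over the standard alphabet.

## The 188D descriptor

Blocks and conventions:

* **AAC (20).** count(a)/L. Emitted as fractions in [0, 1]; the
  classifier is scale-invariant after standardization, so percentages
  (`percent=True`) differ only cosmetically.
* **Group composition (24).** Eight properties × three groups. The
  secondary-structure grouping is EALMQKRH (helix) / VIYCWFT (strand) /
  GNPSD (coil). The other seven use the standard three-state CTD
  groupings of the descriptor literature (see `seqsvm/groups.py`);
  the surface-tension grouping (GQDNAHR / KTSEC / ILMFPWYV) is the
  least standardized of the eight and should be treated as a convention,
  not a measurement. The table ships as an editable YAML config; the
  partition invariant (three disjoint groups covering all 20 letters)
  is enforced at load time.
* **Transitions (24).** Unordered: a j→k and a k→j adjacency count the
  same, normalized by L − 1, the number of adjacent pairs. A length-1
  sequence has no pairs; all 24 values are 0 and the reader warns.
* **Distribution (120).** For a group with c occurrences at 1-based
  positions p₁ < … p_c, the landmarks are p₁/L and
  p⌈q·c⌉/L for q ∈ {0.25, 0.5, 0.75}, plus p_c/L (ceiling convention,
  clamped to at least the first occurrence). An absent group emits five
  zeros rather than a sentinel, keeping the vector dense and bounded.

Feature names (`AAC_A`, `COMP_charge_g1`, `TRANS_polarity_g1g3`,
`DIST_hydrophobicity_g2_p75`, …) and block order are frozen so selected
feature indices are portable across runs and machines.

## MRMD feature selection

Score: total_i = MR_i + MD_i with unit weights.

* **MR_i** is |PCC(F_i, y)| against the +1/−1 label vector. The
  absolute value is used because negative correlation is equally
  informative; a zero-variance column scores 0 by convention.
* **MD_i** is the mean over the other M − 1 columns of the average of
  Euclidean distance, cosine distance (1 − cosine similarity) and
  Tanimoto distance (1 − Tanimoto coefficient). Columns are min-max
  normalized to [0, 1] first so the unbounded Euclidean term and the
  bounded similarity terms are commensurable. The
  `md_orientation="similarity"` switch keeps the raw similarity means
  instead, for users who want the literal printed-formula reading; the
  default distance orientation is the one consistent with "maximum
  distance" as a redundancy penalty.

Ranking is a single sort by total score (descending, ties to the lower
original index), which makes it deterministic and invariant to sample
order. The retained count m is user-set (132 in the reference preset)
or chosen by stratified-CV accuracy over a grid (`choose_m_by_cv`,
ties to the smallest m).

## SMOTE balancing

Parameters: k (default 5) nearest minority neighbors by Euclidean
distance on the feature scale entering SMOTE (ties broken by lower row
index); rate, a multiple of 100 (rate/100 synthetic samples per
minority sample, drawn from distinct neighbors without replacement);
u ~ U[0, 1] per synthetic point. Non-multiple-of-100 rates are rejected
rather than probabilistically rounded. `rate="auto"` targets parity:
100·round(n_maj/n_min − 1), capped at 100·k because each sample has
only k usable neighbors. Majority undersampling (uniform, fraction in
(0, 1]) is available but off by default. Every synthetic point's
parent, neighbor and u are logged, so the convex-combination property
is auditable after the fact. Standardization (per-column zero mean,
unit variance; zero-variance columns pass through) happens after
balancing.

**Scope.** The default `smote_scope="fold"` refits selection, SMOTE and
standardization inside each training partition, so held-out samples
never influence preprocessing. `"global"` applies them once to the full
dataset before splitting — the protocol of studies that balance first
and cross-validate after. Global scope is optimistically biased: the
evaluation pool then contains synthetic points that interpolate real
minority samples, some of which fall in other folds.

## Classifier and evaluation

RBF-kernel SVM. Defaults C = 8, γ = "scale" (1/(m·Var)); these are
fixed defaults, not tuned values — `grid_search` implements the
standard geometric grids (C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, steps of 2²) with
stratified inner CV and smaller-C/smaller-γ tie-breaking, but the
evaluation loops do not nest a grid search inside every jackknife fold;
tuning, when wanted, is done once up front. Decisions are the sign of
the decision function; no probability calibration.

Jackknife = leave-one-out; with the seed fixed the result is unique for
a given dataset and configuration (the only stochastic stages — SMOTE
and fold shuffling — draw from seeds derived deterministically from the
master seed). Stratified k-fold with folds = n reduces bitwise to the
jackknife. Metrics are computed from pooled out-of-fold predictions in
the TP/TN/FP/FN form and cross-checked against the class-total form
(Sn = 1 − N₋⁺/N⁺ etc., with N⁺, N⁻ the actual class sizes — the
convention under which the two forms are identities of each other) to
1e−12 on every call.

## Synthetic study data

The generator draws negative-class residues i.i.d. from a uniform 1/20
background (uniform keeps analytic expectations trivial: a group with g
members has baseline composition g/20) and positive-class residues from
the background with Δ probability mass moved onto a chosen property
group, renormalized off-group. Lengths are uniform on [50, 150] —
short-protein scale, long enough that composition features concentrate.
Fixed study conditions used by the tests and the acceptance script:

* strong shift: Δ = +0.30 on the charge group 1 (K, R) — the matching
  composition feature separates class means by ≈0.30, making the
  classes nearly separable; used for recovery checks;
* moderate shift: Δ = +0.12 — enough signal to classify better than
  chance but weak enough that the classifier errs, which is the regime
  where a class-balance intervention can visibly move sensitivity;
* imbalance 30 positives : 180 negatives (1:6) for pipeline runs;
  60 balanced samples with Δ = 0 for the chance-level control;
* optional `NOISE_*` columns: i.i.d. U[0, 1] appended at the matrix
  level, giving ground-truth uninformative features for selector tests.

What the generator does *not* emulate: motifs, domains, length-class
confounds, phylogenetic relatedness, or any real antioxidant biology.
Passing tests therefore demonstrate that the pipeline recovers planted
compositional signal under controlled conditions — not that it attains
any particular accuracy on real UniProt-derived data.

## Numerical choices

* Composition/AAC sums are exact up to floating addition; invariants
  are asserted at 1e−9.
* MRMD oracle agreement is asserted at 1e−10 (the vectorized Gram-based
  computation vs a double loop accumulates different rounding).
* Metric-form identity at 1e−12; SMOTE convexity at 1e−9.
* Zero-norm columns in the distance computation get similarity 0 (and
  hence distance 1) with a warning; zero-variance columns standardize
  to themselves (std recorded as 1).
* All tie-breaks (ranking, neighbor choice, grid search, m choice) go
  to the lower index / smaller value, making every stage deterministic
  given its seed.

## Known limitations

* **SMOTE in 188 dimensions.** On the high-dimensional descriptor,
  leak-free per-fold SMOTE does not reliably raise sensitivity and can
  lower it slightly: interpolated synthetics contract toward the
  minority centroid, tightening the RBF decision region (a documented
  behavior of SMOTE in high-dimensional settings, cf. Blagus & Lusa,
  BMC Bioinformatics 2013). On low-dimensional feature sets the
  expected sensitivity gain reappears. The sensitivity improvement
  reported by balance-first studies is reproduced under
  `smote_scope="global"`, where it is partly an artifact of evaluating
  on the balanced pool.
* The jackknife refits the full preprocessing n times; cost grows as
  n² per feature and the toolkit is sized for datasets of hundreds to
  a few thousand sequences, not tens of thousands.
* Redundancy reduction of the input sequences (e.g. CD-HIT clustering
  at 60% identity) is expected to be done externally before encoding;
  the toolkit does not reimplement it, and cross-validation on
  redundant sequence sets will overestimate performance.
* m = 132 in the reference preset is a convention carried from the
  antioxidant study; on other data, use `choose_m_by_cv` or the CLI's
  `--m auto`.
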