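# Methods

## Problem and scope

Lysine crotonylation (Kcr) is a post-translational modification; predicting
which lysines in a protein carry it is a binary classification problem over
candidate sites. Classical site predictors encode only the *linear* sequence
neighborhood — a window of `2n + 1` residues centered on the candidate
lysine. `kcrsite` additionally folds in *spatial* neighborhood information
taken from predicted residue–residue contact maps: residues that are far
away in sequence but predicted to be in contact with the window (Cβ–Cβ
within 8 Å in the folded structure, as contact predictors define it). The
package consumes predictor output; it never computes contacts from 3-D
structures or runs a contact predictor itself.

## Feature encoders

All composition-style encoders use the fixed alphabetical residue order
`ACDEFGHIKLMNPQRSTVWY` for column identity. Window pad slots (`-`, used when
the window extends past a terminus) and unknown residues (`X`) are excluded
from every composition count — numerator *and* denominator — so each
composition block is a proper probability distribution over what is actually
observed, or an all-zero block when nothing real is observed. This is a
deliberate normalization choice: the classic AAC definition divides by the
window size, which is ambiguous under terminal padding; dividing by the real
residue count is self-consistent and identical to the classic rule for
interior sites.

* **AAC** (20 dims): frequency of each residue type in the window.
* **AAPC** (400 dims): frequency of ordered residue pairs over all ordered
  pairs of distinct window positions. The denominator `D(D−1)` is exactly
  that pair count, which is why the all-ordered-pairs reading (rather than
  adjacent dipeptides) is used.
* **binary** ((2n+1)×20 dims): per-position one-hot; pads and `X` are zero
  blocks.
* **CKSAAP** (400 dims per gap `k`, default gaps {1, 2, 3}): counts of
  residue pairs at positions `(p, p+k+1)`, each gap's block normalized by
  the number of pairs whose two positions both hold real residues. Gap 0
  (adjacent pairs) is not in the default set but is accepted.
* **EAAC / EGAAC**: AAC (or composition over five physicochemical groups —
  aliphatic GAVLMI, aromatic FYW, positive KRH, negative DE, uncharged
  STCPNQ) in every sliding sub-window, default size 5, concatenated left to
  right. The sub-window size is a convention, not a derived quantity;
  it is configurable.
* **PSSM** ((2n+1)×20 dims): profile rows of a PSI-BLAST position-specific
  scoring matrix at the window's positions; pads contribute zero rows.

## Contact-aware encoders

A contact map is a set of `(i, j, probability)` records, canonicalized
undirected with `i < j` and symmetric duplicates merged keeping the maximum
probability. Thresholding keeps records with probability **strictly greater
than** the threshold (default 0.80). A thresholded contact *qualifies* for a
site when at least one endpoint lies inside the site's window.

* **RRC** (20 dims): the window is expanded by appending, at the tail, the
  residue of each qualifying contact's *outside* endpoint — deduplicated by
  position, ascending; contacts with both endpoints inside append nothing
  (their residues are already counted). AAC is then computed over window
  plus appendix. With no qualifying contacts RRC equals AAC exactly.
* **RRPC** (400 dims): each qualifying contact contributes the ordered pair
  `(residue(i), residue(j))`, lower sequence index first. Counts are
  normalized by the number of counted contacts, so the vector sums to 1
  when at least one contact qualifies and is all-zero otherwise; contacts
  with an `X` endpoint fall outside the 400 pair types and are skipped.
  The normalization constant is a design choice (a raw-count variant would
  confound contact *density* with contact *composition*); the zero vector
  keeps the dimensionality fixed at 400 for every sample. Both-inside
  contacts do count for RRPC — they are genuine contacts within the
  neighborhood — even though they add nothing to RRC.

## Feature selection

Selection is fitted on the balanced training matrix only; the result is a
frozen score-plus-mask object applied to any other matrix by column
projection, never by recomputation, so test information cannot leak.

* **Chi-square**: for nonnegative features, observed counts are the
  per-class value sums, expected counts the class priors times the feature
  total, `χ² = Σ (O−E)²/E` with one degree of freedom for two classes, and
  dimensions with upper-tail `p > 0.05` (configurable) are removed. An
  identically-zero dimension carries no evidence and is assigned `χ² = 0`,
  `p = 1`. This class-sum construction is the standard generalization of the
  goodness-of-fit statistic to continuous nonnegative features.
* **Information gain**: each dimension is discretized (default: two
  equal-frequency bins split at the training median, values equal to the
  split going to the upper bin), and the gain is `H(class) − H(class|bin)`
  in bits. Dimensions with zero gain are removed; a top-k override keeps the
  k highest-gain dimensions instead. With the default median split, a
  non-constant dimension almost always has nominally positive finite-sample
  gain, so top-k is the practically useful filter.

## Training protocol

Candidate sites are split 80/20 stratified by class (per-class rounding,
both sides non-empty). The training side only is randomly undersampled to an
exact 1:1 ratio — every minority (positive) sample is kept, majority samples
are drawn without replacement — while the test side keeps its natural
imbalance, where ranking metrics like AUC are most informative. This rule is
implemented as stated even though real corpora sometimes report split counts
that deviate slightly from exact per-class rounding.

Hyperparameters are chosen by exhaustive grid search with 5-fold
cross-validation on the balanced training matrix, objective mean validation
AUC (accuracy available). Folds partition the indices exactly, sizes
differing by at most one. Ties break toward the first grid point in
documented order (each axis ascending). Grids: SVM-RBF `C ∈ {2^0..2^10}`,
`γ ∈ {2^−10..2^0}`; random forest tree count `{1400, 1600, …, 2400}`;
logistic regression has a single default configuration (SGD on the
cross-entropy loss, tolerance 1e-4, at most 1000 epochs) with decision
cutoff 0.5 (score ≥ cutoff predicts positive; the boundary is inclusive).

Two numerical choices deserve note:

* **No feature standardization.** Every encoder emits features on a common
  bounded scale (compositions in [0, 1], one-hot indicators, integer
  profile scores). On sparse pair-composition features, per-column z-scaling
  inflates near-constant rare-pair dimensions into high-variance noise axes
  and measurably degrades both the RBF-SVM and SGD classifiers, so no
  scaling is applied to any classifier.
* **SVM scores** are the decision-function margins squashed through a
  logistic sigmoid rather than Platt-scaled probabilities. The map is
  strictly monotone, so ROC/AUC are identical, the 0.5 cutoff corresponds
  exactly to the margin sign, and the internal cross-validation randomness
  of Platt scaling is avoided — scores are bit-reproducible given the seed.

Every stochastic step (split, undersampling, folding, forest and SGD
initialization) takes an explicit seed; fixed seeds give byte-identical
reports across runs.

## Evaluation

Confusion counts at the cutoff feed the seven report metrics in their
protocol forms, including the complement forms of precision
(`1 − FP/(TP+FP)`) and F1 (`1 − (FP+FN)/(2TP+FP+FN)`), which are
algebraically identical to `TP/(TP+FP)` and `2TP/(2TP+FP+FN)` and are
verified as such in the test suite. A metric whose denominator is zero is
reported as 0 and listed in the report's `undefined` flags rather than
raising, keeping reports total. ROC points come from a descending threshold
sweep and AUC is the tie-aware Mann–Whitney statistic (probability that a
random positive outscores a random negative, ties counting one half).

## Synthetic data generator

The generator emulates the structure of a Kcr study corpus without
reproducing any real proteome: by default 200 proteins of length 80–200
drawn from approximate vertebrate residue frequencies, every lysine a
candidate site, each labeled positive with probability 0.1 (the ~1:10
imbalance typical of PTM corpora), one 6-column contact table and one
PSI-BLAST-style profile per protein. Two independent, controllable signals
distinguish positive sites:

* a **motif tilt** (off by default): flank residues of positive sites are
  resampled toward a preferred residue set with configurable probability;
* a **planted contact enrichment** (on by default): each positive site
  receives `1 + Poisson(enrichment − 1)` planted contacts (default mean 5)
  between a window position and a distant partner whose residue is set to a
  designated type (default `W`, rare in background), with probabilities
  drawn from U(0.85, 1.0) — above the 0.80 threshold. Partner positions are
  restricted to lie more than the half-width from *every* lysine, and
  anchors prefer positions covered by no other candidate's window, so the
  planted signal is visible only to contact-aware encoders and only at the
  intended site. This is what makes the generator a controlled experiment:
  with the tilt off, sequence-only encoders are provably blind to the class.

Background contacts are drawn per pair `(i, j)` with `j − i ≥ 3` at rate
`0.01 · exp(−(d−3)/20)` in the sequence separation `d`, with emitted
probabilities U(0.5, 1.0) plus Gaussian noise (σ = 0.02); each table is
padded with roughly one sub-0.5 noise row per residue, mimicking how real
predictor output is dominated by non-contacts. PSSM files are synthetic
stand-ins: integer log-odds of windowed residue frequencies against the
background, plus noise — they have the right format and local-composition
structure but none of the evolutionary information of a real profile.

What passing tests on this data do and do not show: they demonstrate that
the pipeline is leakage-free, deterministic, and able to recover a purely
contact-borne class signal that sequence encoders cannot see (planted-signal
RRPC test AUC ≥ 0.9, AAC at chance; on null data all pipelines sit at
chance). They do not certify performance on real Kcr corpora, where signal
strength, contact-prediction quality, and sequence/structure confounding
are all outside the generator's model.

## Problem sizes

The planted-signal study runs at 220 proteins (~1,800 sites, ~360-site
imbalanced test split) with a single-point reduced random-forest grid of 300
trees — forest quality saturates well below the protocol's 1400–2400 range
at this sample size, and the reduced grid keeps the study desk-sized. The
full grids remain the defaults for real use.

## Known limitations

* The BLAST alignment step that maps fixed-length peptide fragments back to
  full sequences in real corpus construction is out of scope; full sequences
  are consumed directly.
* Contact-file discovery assumes one file per protein named
  `<protein_id>.contacts`; predictors that emit other layouts need renaming.
* Chi-square selection requires nonnegative features (compositions,
  one-hots); profile scores can be negative and should use information gain.
* The generator's contact model is geometric, not biophysical: no secondary
  structure, no transitivity, no contact clustering beyond distance decay.
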