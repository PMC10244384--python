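# Methods

This note records the models implemented in `tcravidity`, their assumptions,
the parameter defaults and the reasoning behind the open design choices. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Structural avidity and its thresholds

Structural avidity is the dissociation half-life *T*<sub>1/2</sub> (s) of
monomeric pMHC off the TCR. Two thresholds are used throughout and are
configurable everywhere they appear:

* **60 s** separates the high-avidity class (*T*<sub>1/2</sub> > 60 s) from
  low avidity for classification. The class definitions are strict
  inequalities on either side, leaving exactly 60 s unassigned; the package
  resolves the boundary downward (60 s → low).
* **10 s** separates intermediate/high from low avidity in the clustering
  hotspot analysis.

## 4-mer biophysicochemical encoding and TCR distance

A CDR3β of length L contributes max(0, L − 10) sliding 4-mers after
excluding the first 4 and last 3 residues, which rarely contact the
presented peptide. Each 4-mer maps to a 20-vector: the five Atchley factors
of each position, position-major. The Atchley five-factor solution is
embedded verbatim (`atchley.ATCHLEY_FACTORS`) and treated as frozen
constants.

Two 4-mers are compared by Manhattan distance divided by d_max, the largest
Manhattan distance attainable by any 4-mer pair. Because positions
contribute independently, that maximum is 4 × max over amino-acid pairs of
the five-factor Manhattan distance (≈ 4 × 15.26); the maximising residue
pair repeated at all four positions attains a normalised score of exactly 1.
An alternative normalisation — the sum over the 20 vector dimensions of the
per-dimension range across the 20 amino acids (≈ 97.9) — upper-bounds every
distance but is attained by no pair, so scores stay strictly below 1; it is
available as `normalization="dim_range"`. The attainable-pair constant is
the default because the score is defined to reach 1 for maximally dissimilar
subunits.

The TCR-pair distance is the **minimum** normalised distance over the n × m
4-mer pairs. A minimum over pairs is deliberately not a metric (it violates
the triangle inequality), which is acceptable for average-linkage
clustering but means the matrix must not be fed to methods that assume
metricity. CDR3β shorter than 11 residues have no 4-mer: such pairs get
distance 1.0 with a warning rather than an error, because real repertoires
contain short CDR3s and the pipeline must not abort on them.

## UPGMA and the hotspot analysis

UPGMA (average linkage) is implemented directly so that two conventions are
exact rather than approximated: merge height is half the inter-cluster
average distance (leaf-to-leaf path height then equals the average
distance, and cophenetic distance = 2 × LCA height), and ties in the
minimal distance are broken toward the pair whose smallest member ids sort
first lexicographically, making trees reproducible run-to-run. The
implementation is cross-checked in the test suite against
scipy's average-linkage cophenetic distances on random matrices.

The hotspot is the clade (≥ `min_size` scored members) maximising the
fraction of members with *T*<sub>1/2</sub> above threshold; ties go to the
larger clade, then the lower merge height. Leaves without a half-life
neither qualify a clade nor dilute it. The report carries three numbers:
the maximised within-clade fraction (*purity*), the fraction of all
above-threshold TCRs captured inside the clade, and the fraction of
outside TCRs below threshold.

Because the best clade is *selected*, its enrichment is judged by a
**max-statistic permutation null**: half-life labels are permuted across
leaves (the tree is fixed — permuting the tree itself is not a defined
operation) and the maximal clade purity is recomputed each time;
p = (1 + #{replicate max ≥ observed}) / (b + 1), the add-one convention, so
p ∈ [1/(b+1), 1] and never 0. Default b = 1000.

`min_size` (default 5) is a genuinely free parameter: the hotspot of
interest was originally delineated visually, so clade size is surfaced in
configuration. Note a statistical consequence quantified during design: the
purity statistic saturates at 1.0, and with a small `min_size` random
permutations occasionally produce a tiny all-high clade, putting a floor of
roughly P(any small clade goes all-high) on the attainable p-value
regardless of signal strength. When testing a large planted clade,
`min_size` should be set commensurate with the expected clade size (the
acceptance checks use 10 for a 17-member clade).

The null calibration of this p-value is checked empirically (200
independent panels with labels drawn independently of sequence): the
add-one p-values are valid (the low tail is not anti-conservative) and
approximately uniform, with a Kolmogorov–Smirnov distance band of 0.2 that
accommodates the discreteness and tie mass of a max statistic estimated
from b = 199 permutations.

## Contact-count half-life model

`ContactHalfLifeModel` fits T½ = K + γ·n_apolar + δ·n_polar by ordinary
least squares (statsmodels under the hood) — no intercept suppression, no
weights, no regularisation. K (s) absorbs contributions independent of
contact counts; γ and δ (s per contact) weight apolar and polar contacts.
At least 3 measured complexes and a full-rank design are required; a
constant contact column is rejected by name. Predictions are linear
evaluations and may be negative — they are returned as-is with a warning,
since clamping would bias downstream comparisons. Contact *definition*
(distance cutoffs, atom typing) is upstream of this package; counts are
taken at face value.

## Logistic avidity classifier

Features summarise one amino-acid letter over the CDR3β under three
encodings: `presence` (letter occurs), `exposed_presence` (letter occurs at
a position with relative solvent exposure strictly > 0.30 — exposure is a
fraction in [0, 1] of the residue's surface area in a reference state),
and `frequency` (count / CDR3β length). Exposure gating can only turn
indicators off, so exposed-presence features are pointwise ≤ presence
features. The canonical feature set is {R, N, D, G, I, L, F} with
exposed-presence encoding.

The fit maximises the Bernoulli likelihood by Newton–Raphson with a fixed
tiny L2 penalty on the weights (1e-6, none on the bias). On panels where
the classes are separable — the regime of interest, where the classifier
makes only one or two errors — the unpenalised MLE diverges; the ridge
keeps estimates finite while agreeing with the MLE wherever it exists, and
separability is flagged in the results. Standard errors come from the
inverse penalised Hessian. Calls are high iff p strictly exceeds 0.5.

**Exhaustive feature search.** All residue subsets of sizes 5–8
(15,504 + 38,760 + 77,520 + 125,970 = 257,754 per encoding) are scored by
the R² of a linear regression of the binary label on the features —
5–8 variables keep roughly 5–9 training TCRs per explanatory variable on a
48-TCR panel, limiting overfitting. The top subsets are refit as logistic
models and ranked by ROC AUC, then accuracy. The search works from the
21×21 Gram matrix with one small batched solve per subset size (a 1e-10
diagonal jitter stabilises subsets containing letters absent from the
panel); a full three-encoding sweep takes seconds on one CPU. A historical
enumeration figure of 277,746 regressions circulates for this protocol; it
matches neither 257,754 per encoding nor any obvious multiple across the
three encodings, and the enumeration producing it is not recoverable, so
the package documents the binomial identity and asserts that.

**Evaluation and cross-validation.** AUC is computed as the tie-corrected
rank statistic (equivalently the concordant-pair fraction, cross-checked
against an exhaustive pair oracle in the tests); sensitivity/specificity
are taken at the 0.5 threshold. Cross-validation "success" is overall
held-out accuracy at that threshold. Three schemes: random 5-fold
(~leave-20 %-out), class-stratified 5-fold, and leave-one-epitope-out,
which holds out every TCR of one cognate pMHC at a time — the hardest
setting, since the model sees no example of the held-out specificity.
Degenerate single-class training folds fall back to a majority-class
constant predictor.

**Composition enrichment.** Pooled per-letter residue counts of the high
vs low panels are compared letter-by-letter with a two-sided Fisher exact
test on the 2×2 table (letter vs rest × high vs low); the test is not
dictated by the protocol being reproduced, and Fisher's exact test is the
standard choice for pooled count tables. Raw and Bonferroni-corrected
p-values are both reported.

## Repertoire %HA enrichment test

Classifier labels are matched into bulk β-chain repertoires by exact CDR3β
amino-acid identity (upper-cased, whitespace-stripped); unmatched rows are
"unknown" and excluded; clonotypes with a single read are dropped by
default as unreliable. Matched clonotypes are partitioned into the *n*
**infiltrating** (present in the tumor repertoire) and *m*
**non-infiltrating** (present in blood only) — disjoint groups, a
clonotype found in both compartments counting once as infiltrating. This
partition is what makes the relabeling null coherent: each clonotype
carries exactly one label, and F, the *count* of high-avidity clonotypes
among the n + m, yields the pooled fraction F/(n+m) used as the
per-clonotype relabeling probability. The statistic is
%HA<sub>Inf</sub> − %HA<sub>No</sub> over unique clonotypes (a
read-weighted variant is available and agrees when all counts are equal);
p is add-one over b = 1000 replicates, one-sided for tumor enrichment.
A multi-patient version keeps each patient's own pooled fraction and pools
the statistic.

## Synthetic data: what is planted and what is not

The generator emulates the study conditions under which each stage is
validated:

* **Panels** (default 48 TCRs, 11 high = the curated training dimensions;
  CDR3β lengths 11–20, uniform — the source panel's length distribution is
  unreported, so this is a modeling choice; 12 cognate pMHCs). High-avidity
  sequences draw central-region letters from a mixture with weight 0.35
  toward {N, E, I, K, T, Y, V} and low-avidity sequences toward
  {A, R, D, L, M, P}: a detectable but imperfect signal, because the real
  effect is an enrichment, not a rule. Half-lives are uniform within class
  intervals (2–55 s low, 65–180 s high); the low interval deliberately
  spans the 10 s boundary so the hotspot analysis sees all three avidity
  bands, and neither interval straddles 60 s. An optional shared central
  4-mer motif plants a clade among high-avidity clonotypes for
  hotspot-recovery tests.
* **Exposure profiles**: i.i.d. Bernoulli exposed/buried per position
  (rate 0.5), exposed positions drawing fractions in (0.30, 1], buried in
  [0, 0.30). An optional coupled mode exposes enrichment-set letters at
  rate 0.85 — the regime where exposure-gated features carry recoverable
  signal.
* **Feature-coupled panels** (`generate_feature_coupled_panel`): avidity
  labels derive from a planted linear model on the exposed-presence
  features of the canonical residue set, with two boundary label flips —
  emulating the near-separable curated panel on which the best classifier
  still makes about one false positive and one false negative.
* **Contact tables**: exact linear law at the published coefficients
  (K = −62.89 s, γ = 2.647 s, δ = 8.747 s) plus optional Gaussian noise;
  negative half-lives are kept unless clipping is requested, because the
  fit is unconstrained.
* **Repertoires**: both compartments share a lognormal(0, 1) base
  abundance per clonotype; the tumor multiplies high-avidity weights by an
  odds factor (1 = exchangeable compartments); reads are multinomial at
  the requested depth. Demo depths are kept shallow (~150–300 reads) so
  that the infiltrating / blood-only partition is nondegenerate.

Identical spec + seed reproduces byte-identical output. The pipeline
expands one global seed into fixed per-stage streams so that toggling a
stage never shifts another stage's randomness.

What the generator does **not** model: V(D)J recombination and germline
gene usage, real CDR3 length and clone-size distributions, sequencing
error, epitope-specific sequence convergence, or any physical relation
between sequence and true binding kinetics. Passing the parameter-recovery
and calibration tests therefore establishes that the *procedures* are
implemented correctly and are well calibrated under their own assumptions —
not that the trained models transfer to real repertoires, which requires
the original measured panels.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely on synthetic data at
these scales, chosen to give each check adequate power while completing in
minutes on one CPU: 48–58-TCR panels for protocol checks; 1000 random
panels for matrix invariants; 500 replicates for OLS unbiasedness (bias
within 3 SE of the replicate mean); n = 2000 for logistic parameter
recovery (3 SE band); 50 seeds for planted-feature-set recovery (≥ 90 %
required); 200 seeds × 199 permutations for null-calibration checks;
b = 1000 permutations for reported p-values. Numerical specifics: Newton
iterations cap at 200 with step tolerance 1e-10; probabilities are clipped
at 1e-12 inside the Hessian; the normalised 4-mer distance clips rounding
overshoot above 1 by at most 1e-9; exposure fractions are validated into
[0, 1]; distances must be symmetric to 1e-12 before clustering.

## Known limitations

* Solvent exposure and contact counts are inputs; nothing here computes
  them from 3D coordinates, and no criterion for polar/apolar contact
  typing is defined in-package.
* Only the β chain and only 4-mers are considered; no CDR1/CDR2/CDR3α
  features and no k ≠ 4.
* The TCR-pair distance is non-metric by construction; only
  average-linkage clustering is supported.
* The max-purity hotspot statistic saturates (see above); very small
  `min_size` values limit the resolution of its permutation p-value.
* The relabeling null treats clonotype labels as independent; clonal
  lineage structure or shared specificity groups would violate that
  assumption.
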