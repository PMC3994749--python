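# Methods

## Model

`locnet` predicts the location-indicator vector of a protein with q
per-location Bayesian network classifiers.  Classifier Cᵢ is a directed
acyclic graph Gᵢ over the discretized feature variables F₁…F_d and the
location variables L₁…L_q, plus one conditional probability table (CPT)
θ_v per node, so the joint distribution factorizes node-wise.  Two
structural assumptions are built in:

* **No feature–feature edges.**  Features are treated as independent or
  conditionally independent given locations.  This shrinks the search
  space; location–location and feature–location edges, which carry the
  dependency information of interest, remain unrestricted.
* **One unobserved variable per query.**  When Cᵢ is evaluated, every
  variable except Lᵢ is instantiated: features from the discretizer, the
  other locations from hard SVM estimates l̂ⱼ.  Inference is therefore a
  two-term ratio, not general marginalization:
  Pr(Lᵢ=1 | rest) = J(1)/(J(0)+J(1)) with J(z) the joint at Lᵢ=z.  The
  implementation evaluates only the factors containing Lᵢ (its CPT and
  its children's); equality with the full-joint ratio is enforced by a
  randomized test against explicit enumeration, not assumed.

Locations are binary; feature arities come from the discretizer.  The
all-zero prediction is legal output (no minimum of one location is
forced), and the metrics give such predictions zero credit.

## Discretization

Each feature is cut recursively at the boundary minimizing the class
entropy of the location variable (candidates: midpoints between
consecutive distinct values; ties resolve to the smallest boundary, with
a 1e-12 comparison tolerance so floating-point noise cannot flip a tie).
A cut is kept only if its information gain clears the
minimum-description-length threshold

    Gain > [log₂(n−1) + log₂(3^k − 2) − (k·H − k₁·H₁ − k₂·H₂)] / n,

after which both sides are partitioned recursively and independently.
Because a protein may carry several locations, every protein is expanded
into one (instance, location) pair per positive label and all
proportions — including the side weights Pr(f ≤ T) — are computed over
pairs, making the class distribution a proper distribution.  (Whether
multi-localized proteins should be expanded, dropped, or counted once is
genuinely open; expansion is the minimal choice that keeps the printed
estimators normalized, and it reduces exactly to the classical
single-label procedure on single-localized data.)

Values at a boundary map left (f ≤ T); query values outside the training
range clamp to the extreme codes, so prediction never invents unseen
codes.  The discretizer is fitted once per training fold and shared by
all q classifiers; features with no accepted cut get a single code and
thus can never enter a network informatively.

## Indicator estimators

One support-vector classifier per location (RBF kernel, C = 1,
scikit-learn's `gamma='scale'`, no class weighting; all configurable,
linear kernel available) is trained one-vs-rest on the standardized
*continuous* features.  Margin classifiers gain nothing from
discretization, which exists to make the network variables discrete; a
config switch (`estimator.features = "discrete"`) feeds the integer codes
instead.  Outputs are hard 0/1 values (sign of the decision function),
treated downstream as observed values of the other-location variables.
A location with a single training class degenerates to a constant
estimator with a warning.

Training-set estimates used during structure learning are produced
in-sample (a one-time estimate by estimators fitted on the full training
fold); an optional cross-fitting mode produces them out-of-fold instead
(internal 5-fold), off by default.

The fitted decision rule is stored explicitly (support vectors, dual
coefficients, intercept, scaler constants), and prediction always
evaluates that stored rule, so a model round-tripped through its
plain-text serialization predicts bit-identically.

## Parameter learning

CPTs are maximum-likelihood frequency counts over the training records
with a pseudo-count α added to every cell:

    θ_v(x | y…) = (n_joint + α) / (n_marginal + α·arity(v)),  α = 1.

Adding α to every cell rather than only to zero cells is the standard
smoothing variation and keeps every entry strictly positive.  Location
counts use the *true* labels; the conditional likelihood below mixes the
true target value with estimated values for the other locations, exactly
as the two quantities appear in the objective.  A config flag
(`search.location_cpts_from = "estimated"`) switches the counts to the
SVM estimates for users who prefer the matched-input reading; the
target's own column always uses true labels.  With α = 0, unseen parent
configurations produce uniform rows with a warning, and zero-probability
CLL terms are floored at log(1e-300).

## Structure search

Each classifier's graph is learned by steepest-ascent hill climbing from
the empty graph.  A move adds, deletes, or reverses one edge; moves that
would create a cycle or a feature–feature edge are excluded; enumeration
order (move kind, then node pair) is fixed, and ties go to the earliest
move, so the search is deterministic.  Every intermediate structure is
re-validated (acyclicity, edge constraints) as it is adopted.

The objective is the conditional log likelihood of the target indicator

    CLL(Cᵢ | D) = Σⱼ log Pr(Lᵢ = lᵢ^{Pⱼ} | f^{Pⱼ}, l̂ of other locations)

**minus a BIC complexity penalty** (log m / 2) · k, where k is the number
of free parameters in the factors that enter this conditional (the
target's CPT and its children's CPTs).  The penalty is not cosmetic: the
in-sample CLL of ML-fitted CPTs increases almost surely whenever any
parent is added (≈ χ²/2 per spurious edge), so an unpenalized climb with
a tiny improvement threshold connects the target to noise — on data where
the target is independent of everything, it decorates the target with
arbitrary parents, and held-out performance suffers visibly.  With the
penalty, an edge is accepted only when its fit gain exceeds the chance
level for the parameters it introduces; on independent data the target
stays unconnected.  `search.penalty = "none"` restores the raw-CLL climb.
The improvement tolerance ε = 1e-9 remains as a pure numerical guard, and
an iteration cap (default 500) bounds runtime.

Because the conditional depends only on the target's factors, candidate
moves that touch no such factor provably leave the score unchanged; the
scorer skips them and refits only the families whose parent sets change,
caching per-family terms.  A full-refit scoring mode recomputes every
candidate from the complete factorization; tests assert both modes choose
identical move sequences.  Note that greedy ascent on the *unpenalized*
CLL can stall in local optima (observed on 4-node instances); under the
penalized objective the search reaches the exhaustively enumerated global
optimum on all tested toy instances.

## Prediction

Single pass, no iteration: estimate all indicators with the SVMs, then
let each Cᵢ compute its posterior and threshold at 0.5 (strictly greater
predicts 1; exactly 0.5 predicts 0).  The target's own SVM estimate is
computed but never used by Cᵢ.  Network outputs do not feed back into
other classifiers.

## Evaluation

Example-based: Acc = mean |M∩M̂|/|M∪M̂| (Jaccard) and F1 = mean
2|M∩M̂|/(|M|+|M̂|) (Dice); an empty predicted set contributes 0 to both.
Location-based: adapted multilabel precision (mean overlap ratio over
proteins *predicted* at the location) and recall (over proteins *truly*
there), undefined — reported as NaN — when the conditioning set is empty;
F1-label macro-averages their harmonic mean over the locations present in
the evaluated data, with undefined or zero-sum locations contributing 0;
and standard binary precision/recall from TP/FP/FN counts.  F1 ≥ Acc
holds per term (|A|+|B| ≤ 2|A∪B|) and is property-tested.

Cross-validation runs R complete rounds of k-fold CV (defaults 5×5-fold
in the config; the dependency experiment uses 10 rounds).  Splits are
stratified by the *exact label combination* — the natural reading of
"stratified" for multi-label data whose corpus is described by
combination counts — with per-combination counts across folds differing
by at most 1 and overall fold sizes by at most 1.  Each round derives its
own sub-seed; held-out predictions are pooled per round; means and sample
standard deviations are reported across rounds.  The same splits also
evaluate the indicator SVMs used alone, which is the dependency-blind
baseline every claim is measured against.

## Synthetic corpora

No adequate public corpus of single- and multi-localized proteins with
precomputed feature tables is available, so the package generates its
own, and the generator is first-class, tested code.  Labels are drawn by
ancestral sampling from a DAG over the label variables; all-zero label
vectors are rejection-resampled (real corpora contain none); features are
Gaussian with label-dependent means.  Features flagged *bimodal* put a
random sign on their label contribution, giving a symmetric two-band
signature — the shape of a sorting-signal score that is extreme in either
direction for targeted proteins.  Generator self-consistency (empirical
conditional frequencies converge to the specified CPTs at the Monte-Carlo
rate) is tested.

**Dependency fixture** (q = 5, d = 10, n = 2000): drivers cyt, ex, nuc
are independent roots with priors 0.55/0.50/0.45, each signalled by one
two-band signature feature (±3.2, SD 0.58) that both the SVMs and the
discretized networks resolve at ≈ 99%, so driver prediction cannot
separate the two systems.  The dependent compartments carry *no* feature
signal: mem holds proteins found in exactly two of the three driver
compartments, mi co-occurs with ex∧nuc.  `dependency_strength` (default
0.95) interpolates these rules against a 0.75 base marginal.  The design
rationale, in order of what failed without it: the dependent labels'
signal must be unreachable for a per-label learner *in practice* — with
monotone single-margin features, an RBF SVM at this sample size learns
any two-way boolean composite about as well as the network does, so the
composite regions here are unions of many feature-space islands that the
kernel cannot tile from 1600 examples while a CPT over estimated parent
indicators reads them off directly; the base marginal sits above 0.5 so
that at strength 0 both systems collapse to the same constant majority
prediction (with rarer dependent labels, the ≥1-positive rejection itself
induces exploitable dependencies at strength 0, contaminating the
control); and the signature features are crisp so the discretizer confers
no driver-level advantage.  Measured on 10-round CV: the network
collection exceeds the SVM baseline by ≈ 0.09–0.10 example-based F1; on
the strength-0 control the gap is ≈ 0.01.

**Corpus-shape fixture**: q = 9 compartments, d = 30 features, n = 1500,
label combinations drawn from a fixed template (9 singles, 7 specific
pairs) with realistic imbalance — ~64% single- and ~36% double-localized.
Qualitative shape only.

**Tiny oracle network**: a fixed, hand-specified 4-node binary network
with printed CPTs used as ground truth for inference and
parameter-recovery tests.

What passing on these corpora does *not* show: real feature extractors
(signal scores, amino-acid composition, annotation features) are
correlated, non-Gaussian and high-dimensional; real location
dependencies are weaker and noisier than the near-deterministic rules
here; and the SVM baseline's difficulty on the composite regions is a
property of this geometry.  The synthetic results demonstrate that the
machinery extracts dependency structure when it is present and invents
none when absent — not a performance forecast for any real proteome.

## Numerical and engineering choices

* All inference in log space; posteriors materialize only at the API
  boundary; logistic transforms use `logaddexp` for stability.
* Model serialization is deterministic JSON (sorted keys, repr-exact
  floats): training twice with one seed yields byte-identical files, and
  load(save(m)) predicts identically to m.
* CV sub-seeds are derived as (seed·100003 + 7919·r + 1) mod 2³¹−1.
* Problem sizes in the test suite (n ≤ 2000, networks ≤ 12 nodes,
  20000-sample recovery runs) keep the full suite around two minutes
  while leaving every estimate's Monte-Carlo error far inside the
  asserted tolerances.

## Known limitations

* Indicator estimates are hard 0/1 values; no probability calibration,
  and estimation error in l̂ propagates uncorrected into every network
  (the natural extension — EM over hidden indicators — is out of scope).
* Exactly one variable is unobserved per query; there is no general BN
  inference, so the model cannot answer joint queries over several
  unknown locations.
* Steepest-ascent search finds local optima of its objective; global
  optimality is verified only at toy scale.
* CPT size grows exponentially in parent count; the optional
  `max_parents` guard (default unlimited) is the only protection beyond
  the BIC penalty's natural reluctance.
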