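# Methods

This note records the modelling assumptions, parameter choices, numerical
conventions and known limitations behind `rankpanel`. It documents what the
code computes and why the defaults are what they are; every empirical claim
below is one the test suite or `scripts/acceptance.py` computes itself.

## The classifier

### Rank-reversal features

The atomic feature is the strict within-profile comparison
Z<sub>ij</sub>(x) = 1[x<sub>i</sub> > x<sub>j</sub>]. Ties resolve to 0.
This makes every downstream decision invariant to strictly increasing
per-profile transforms, which is the whole appeal of the approach: profiles
preprocessed by different pipelines can be classified by the same panel as
long as within-profile orderings are preserved. The tie convention matters
only for discrete or constant data (continuous expression values tie with
probability zero); it is asserted in the tests so integer-valued inputs
behave predictably. One consequence: the antisymmetry
Δ(i,j) = −Δ(j,i) is exact only in the absence of ties.

Pairs are scored by the classic TSP statistic
Δ = P̂(Z=1 | positive) − P̂(Z=1 | negative). The score ordering must be
total for reproducibility, so ties in Δ break by a secondary statistic —
the mean within-profile rank gap |rank(i) − rank(j)| over the scored samples
(larger gaps are more robust to perturbation, as in published TSP
refinements) — and remaining ties break lexicographically on (gene_i,
gene_j). The secondary statistic and the lexicographic fallback are this
package's conventions; only the Δ score itself is intrinsic to the method.

### Candidate-pair pre-filter

All-pairs scoring is quadratic in the number of features. Above
`prefilter_f` features (default 1,000) the candidate universe is restricted
to the top features by across-sample variance of within-profile rank;
features whose rank never moves cannot participate in an informative
reversal. Datasets at or below 1,000 features are scored exhaustively.

### Hierarchy construction

The diagnostic hierarchy is built agglomeratively on training data: the two
current groups with the lowest separability merge first, where separability
is the best single pair's |Δ| between the pooled groups (the aggregation
over the sorted |Δ| values is injectable; the default uses the single best
pair). Pooling the samples of a group, rather than weighting classes,
is the simplest reading of "group"; both choices coincide for balanced data.
Merge ties break on smaller combined sample count, then on the
lexicographically smallest sorted class-name tuple, making the tree a pure
function of the dataset. Node ids are assigned breadth-first from the root
(id 1), left child = lexicographically smaller class set, so serialized
hierarchies are diff-stable. The packaged brain hierarchy is transcribed
with its published numbering rather than re-derived.

A degenerate regime worth knowing about: when the data are perfectly
separable everywhere (e.g. noiseless synthetic data), every pairwise
separability saturates at 1.0 and the topology is decided entirely by
tie-breaks. Separability carries topology information only when some
distinctions are genuinely harder than others.

### Node panels

A node's positive training data are all samples of its class set, negatives
are **all** remaining samples — a one-vs-rest test, deliberately not a
sibling-vs-sibling test, so that a positive response means "this profile
looks like L<sub>t</sub>" absolutely. Panel assembly is greedy in score
order, skipping any pair that reuses a feature already in the panel
(feature-disjointness is enforced within a node; across nodes genes may
recur). After each addition the threshold k is set to the **largest** value
whose training sensitivity still meets `sensitivity_target` (default 1.0,
falling back to the maximum attainable sensitivity when the target is out of
reach). Largest-k is the operative choice: sensitivity is non-increasing in
k, so the sensitivity constraint pins an upper bound for k and every spare
vote below that bound is wasted specificity. A rejected positive can never
be recovered downstream, which is why sensitivity is prioritized; the
specificity lost at one node is recouped by the conjunction of tests along
the chain.

Growth stops when (a) the sensitivity target is reachable and the next pair
buys less than `min_specificity_gain` (default 0.01) of training
specificity, or (b) `max_pairs` (default 7) is reached, or (c) training
sensitivity and specificity both hit 1. The stopping rule is a surrogate for
an unspecified original criterion; with these defaults learned panels span
the 1–7 pair range observed in the packaged panel. Sensitivity/specificity
comparisons are made in exact rational arithmetic on counts (`fractions`),
never on floating-point thresholds.

### Edges and prediction

Edge classifiers are single top-scoring pairs trained only on samples under
their parent node, oriented so Z=1 routes to the positive child; the
positive child is fixed as the lexicographically smaller class set, so the
learned object does not depend on declaration order. Edges train on all
samples under the parent — not only on ambiguous ones — the same way an
ordinary decision tree would.

Screening executes node classifiers breadth-first with ancestor gating;
pruning is exact (verified against a naive evaluator that runs every node).
Zero candidates ⇒ `Unclassified`; one ⇒ that label without consulting any
edge; several ⇒ a full decision-tree descent **from the root**. The descent
is deliberately not restricted to candidate leaves; with adversarial inputs
(exact ties at an edge) the final label can fall outside the candidate set,
and the prediction trace records the path so such cases are auditable.

## Validation designs

- **Repeated stratified k-fold CV** (defaults 10×10): per repeat, each
  class's samples are shuffled and dealt round-robin into folds; the entire
  pipeline — optional detection-flag feature filter, hierarchy, node panels,
  edges — is relearned on every training split. Pooled counts across folds
  and repeats form the headline confusion matrix; per-repeat macro
  accuracies are kept for dispersion. A class smaller than the fold count
  raises rather than silently rebalancing.
- **Hold-one-lab-in**: the target class trains from a single study (other
  classes contribute all their samples); accuracy is the fraction of
  held-out-study target samples predicted as the target class, reported per
  (train study, test study) with the plain average as headline.
- **Leave-one-lab-out**: the target class's samples from one study are
  withheld entirely; everything else trains.
- **Subsampled training** (`n` target samples, default 50 where the data
  allow): draws come from one study (`single_study`) or pooled across the
  non-held-out studies (`combined`), with the rest of the pipeline
  identical, isolating training breadth from training size.
- **SNR** = mean accuracy / sample standard deviation (ddof=1; the n−1
  convention is this package's choice). An exactly constant accuracy vector
  reports infinite SNR and is flagged rather than divided.
- Unclassified is a misclassification everywhere; macro accuracy is the
  unweighted mean of per-class accuracies. Train/test sample-id disjointness
  is asserted inside every design.

The feature-allowlist option (e.g. restricting to genes encoding
extracellular products) is a plain subset of the feature universe applied at
load time; everything downstream is unchanged. The detection-flag filter
removes features flagged undetected in **all** training samples and applies
the same removal to test data; the keep/drop decision never sees test
columns.

## Synthetic data generator

Values live on a log-intensity-like scale: baseline + N(0, noise_sd). A
planted pair (i, j) with positive class set S and target Δ* is shifted
±d/2 symmetrically (reversed outside S) with

    d = √2 · noise_sd · Φ⁻¹((1 + Δ*) / 2),

so the Normal difference x<sub>i</sub>−x<sub>j</sub> ~ N(±d, 2·noise_sd²)
realizes P(Z=1|S) − P(Z=1|S̄) = Δ* exactly in expectation (Δ* = 1 is capped
at 1−10⁻⁶ inside Φ⁻¹, i.e. realized as a ~6.9σ separation). Batch structure
has two forms: additive per-(study, feature) offsets ~ N(0, batch_shift_sd),
which perturb cross-feature orderings study-wide, and outright inversion of
a planted pair's orientation within single studies at rate
`batch_reversal_rate` — the confound that makes single-study signatures
misorient pairs. Everything is reproducible from a single integer seed, and
the generator emits its ground truth (realized per-study Δ of every planted
pair, and which (pair, study) combinations were inverted) alongside the data.

Named scenarios freeze the study conditions used by the tests and the
acceptance script:

- `strong_signal_spec`: 7 classes × 2 studies × 6 samples/class/study, one
  Δ*=1 pair per node of a balanced class hierarchy (`hierarchical_planting`),
  noise sd 1. Residual CV error comes only from finite-sample pair selection;
  measured macro accuracy is ~98%. Its noiseless variant (noise sd 0) backs
  the planted-pair recovery check, with the hierarchy fixed to the planted
  topology (`planted_hierarchy`) because saturated separability leaves the
  topology to tie-breaks.
- `pure_noise_spec`: no planted structure; CV macro accuracy sits at ~1/C
  (Unclassified outcomes and symmetric confusions balance out).
- `batch_confounded_spec`: 4 classes × 5 studies × 10 samples/class/study,
  Δ*=0.9 planting, noise sd 1, batch shift sd 0.5, inversion rate 0.25.

### What the generator does and does not emulate

It emulates exactly the properties a rank-pair classifier can see:
class-conditional pair reversals, their calibrated strength, and
study-level distortions of orderings. It does **not** model probe-level
intensity distributions, detection-call statistics, class imbalance between
studies, or — importantly — within-class subtype heterogeneity across
studies (each study draws the target class from the same distribution up to
batch effects). Consequences for interpreting the tests: the dispersion
advantage of pooled multi-study training (lower accuracy SD / higher SNR
than single-study training at equal n) is strong and reproduces robustly,
and leave-one-lab-out beats hold-one-lab-in clearly when training sizes are
allowed to differ; the *mean*-accuracy advantage of pooled training at
strictly equal n, however, is weak under this generator (a few points,
within seed noise on single replicates) — on real data that gap is plausibly
driven by subtype composition differing across studies, which this generator
deliberately does not model. Passing tests therefore demonstrate the
designs' mechanics and the qualitative orderings, not real-data effect
sizes.

## Problem sizes

Test and acceptance runs use deliberately small instances chosen to make
every stochastic check cheap to replicate: tens of features, 4–10 classes,
single-digit-to-low-tens of samples per class per study, CV with 3 or fewer
repeats where the full 10×10 protocol is not itself under test, and 10-seed
replication for the cross-study comparisons. The implementation itself is
vectorized (pair scoring is a Boolean matrix reduction) and handles
genome-scale feature counts through the rank-variance pre-filter.

## Known limitations

- The exact stopping rule for panel growth and the tie-break among equally
  scored pairs are this package's documented surrogates for unspecified
  originals; panels of the right size range emerge, but printed panels from
  other implementations will not be reproduced pair-for-pair.
- Group separability uses the single best pair by default; a top-m average
  is injectable but untested beyond the interface.
- The decision-tree descent can (only under exact ties) label a profile
  outside its candidate set; the trace makes this visible.
- No probabilistic outputs: the classifier is purely combinatorial, and no
  confidence accompanies a label.
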