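# Methods

## Problem setting and model

The package predicts conformational B-cell epitopes on an antigen from its
unbound 3D structure alone (partner-independent prediction). The working
assumptions are:

* each base classifier emits a per-residue interface-likelihood score in
  [0,1] that is informative but noisy, on a query-dependent scale;
* different classifiers capture partially orthogonal structural signal, so
  a nonlinear integrator can outperform every individual track;
* an antigen may carry several epitopes, which are spatially compact and
  mutually separated patches of surface residues.

### Meta-integration

Scores are min–max rescaled to [0,1] **per antigen and per classifier**
before integration, because the base predictors' score scales vary between
queries; a constant track is mapped to zeros (it carries no ranking
information). Missing scores are imputed as 0, read as "no interface
evidence". The integrator is a gradient-boosted tree binary classifier
(XGBoost) on the normalized track values:

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 200 | boosting rounds |
| `max_depth` | 4 | tree depth (grid {3,4,5} under `tune_meta`) |
| `alpha` | 0 | L1 pruning/regularization (grid {0, 0.5, 1}) |
| `learning_rate` | 0.1 | shrinkage |
| `scale_pos_weight` | #neg/#pos | class-imbalance reweighting, computed on the training fold |
| `seed` | 42 | makes train→predict bitwise reproducible |

Epitopal residues are a small minority of an antigen, hence the positive
reweighting. Hyperparameter tuning, when requested, is an inner grid search
scored by mean ROC-AUC over leave-one-training-fold-out rounds; ties go to
the first grid point. Raw normalized scores are the features; no
per-classifier binarization thresholds are introduced.

### Cross-validation folds

Antigens (never residues) are assigned to one held-out test set plus three
training sets, stratified by antigen-size tertile: within each tertile,
shuffled antigens are dealt round-robin with a rotating start fold, under
per-fold quotas. Every fold's tertile count is within one antigen of its
proportional share. Quotas are as equal as possible by default;
`test_size` can pin the held-out set exactly (e.g. 29 of 111, leaving
training sets of 28/27/27) to reproduce a fixed benchmark partition.

### Dynamic threshold

The number of residues called epitopal is N = round(6.1 · R^0.3) with R
the count of surface-exposed residues. Rounding is half-up; floor/ceil are
available as options. Surface exposure is computed by the rolling-probe
(Shrake–Rupley) method with a 1.4 Å probe, normalized by the residue-type
theoretical maximum ASA (Tien et al. values); RSA ≥ 5% flags a residue as
surface. The 5% convention and the RSA method are deliberate choices —
the threshold formula itself does not prescribe them — and both are exposed
as parameters. N deliberately over-predicts relative to any single epitope,
which is what makes the clustering stage meaningful.

### Spatial partitioning

The top-N residues (ties at the boundary broken by file order, so the
selection is deterministic) are clustered by agglomerative hierarchical
clustering with Ward minimum-variance linkage on Euclidean distances
between residue geometric centers. A residue's center is the unweighted
mean of **all** its heavy atoms — not Cα only — as the least arbitrary
reading of "geometric center". The cluster count k maximizes the
dendrogram gap: for candidates k = 2..min(k_max, n−1),
gap(k) = h(n−k+1) − h(n−k) where h(m) is the m-th merge height; ties break
toward smaller k. k_max defaults to 8 (observed optima on real antigens
are 2–3). k = 1 is not a candidate: the rule requires a cut below the
final merge, so a single spatially spread-out epitope is necessarily
split — a documented limitation, and the reason per-cluster evaluation
sometimes beats whole-set evaluation.

### Annotation

An antigen residue is epitopal in a complex iff any of its heavy atoms
lies within 4.0 Å of an antibody heavy atom. Only the distance rule is
implemented; contact-type legitimacy classification (as in dedicated
contact-analysis programs) is out of scope, as are hydrogen- or
water-mediated contacts. Annotations transfer from bound to unbound
structures through global pairwise alignment (BLOSUM62, gap open 11 /
extend 1, free end gaps); identity is matches over alignment columns
excluding end gaps, and transfers below 95% identity are refused.
Epitope–epitope overlap is reported as 100·|a∩b|/|a∪b| (union
denominator; a min-set-size denominator is available — both agree at the
0% and 100% endpoints). Dataset curation: resolution < 3 Å strictly,
antigen length in [100, 450] (a looser >60-residue variant is a parameter
override), and greedy longest-first redundancy clustering at ≤30% pairwise
identity.

### Evaluation

Confusion counts are taken over a residue universe that defaults to all
residues of the antigen (a surface-only universe is a flag; the choice
affects TN-dependent metrics like MCC). Zero-denominator conventions:
F1 = 0 and MCC = 0 when undefined. ROC-AUC is trapezoidal (equivalently
Mann–Whitney concordance with ties at ½); PR-AUC uses step-wise
(average-precision) integration, which avoids the optimistic bias of
trapezoids between PR points. %TP-at-k pools over the test set: total
annotated residues found in each antigen's top-k divided by total annotated
residues. Reported averages are unweighted means over antigens. KS tests
(one-sample against a fitted normal, or two-sample between methods) use
asymptotic p-values with significance at p < 0.05. Per-cluster F1 treats
each cluster alone as the predicted set.

## Synthetic fixtures: what they emulate, and what they don't

A fixture antigen is a self-avoiding 3D random walk (3.8 Å steps,
excluded-volume radius 3.5 Å) with one pseudo-atom per residue. An epitope
patch is the `patch_size` nearest residues around a seed; seeds are placed
by farthest-point sampling and realized patch centroids must be at least
`patch_separation` apart (default 30 Å). Classifier track c scores residue
i as `clip(base + sensitivity_c·1[i ∈ patches covered by c] + N(0,
noise_sd), 0, 1)` with base 0.2. Defaults: 150 residues, two 14-residue
patches — patch sizes sit inside the 6–29 residue range of experimentally
mapped epitopes.

Two documented track regimes:

* **strong** (sensitivities 0.7/0.7/0.5, noise_sd 0.12) — patches clearly
  recoverable; used to test the calling/clustering stages themselves.
* **realistic** (0.28/0.28/0.15, noise_sd 0.15) — single-track ROC-AUC in
  the ~0.6–0.75 band typical of individual interface predictors; used for
  the integration benchmark, where headroom for the meta-model matters.

In both regimes trackA sees only the first patch, trackB only the last,
and the weaker trackC all of them; on three-patch antigens the middle patch
is therefore visible to trackC alone, encoding the orthogonal-information
premise. The benchmark corpus (12 antigens, 100–300 residues, one quarter
with three patches drawn from the upper half of the size range) exercises
fold construction, training, ablation and calling end-to-end; the recovery
benchmark uses 10 two-patch antigens with out-of-fold consensus scores.
These sizes keep a full benchmark run in seconds while leaving hundreds of
test residues per fold.

Fixtures are a pure function of their seed. They do **not** emulate real
protein geometry (no side chains, no secondary structure, no burial — the
open walk leaves essentially every residue surface-exposed, so R ≈ n), nor
sequence realism, nor structured classifier errors (noise is i.i.d.
Gaussian, while real predictors err systematically on e.g. crystal
contacts). Passing fixture benchmarks therefore demonstrates the
correctness and qualitative behaviour of the pipeline — integration gain,
multi-epitope recovery — not its absolute accuracy on real antigens.

## Numerical and degenerate-input choices

* Alternate locations: first altloc kept; hydrogens ignored; non-standard
  residues dropped with a warning; first NMR model only.
* Unknown residue type in RSA normalization: generic 197 Å² maximum with a
  warning.
* Fewer than two called residues: degenerate single-cluster result, no
  dendrogram.
* Two leaves: k = 2 is the only candidate.
* Fixture generation retries: 200 step attempts per walk extension, 50
  walk restarts, and up to 10 fresh walks if patch placement fails.
* Model persistence: a single joblib file embedding the fitted booster,
  feature names and config; feature order is fixed at training and
  verified at prediction.

## Known limitations

* The RSA definition behind R is a convention; structures with many
  marginally exposed residues can shift N by ±1–2.
* The gap rule never returns k = 1 and is sensitive to outlier residues in
  the top set (a far-flung false positive can form its own small cluster).
* Greedy longest-first redundancy clustering is order-dependent; it
  guarantees no retained pair above the threshold but not a maximum subset.
* Transfer of annotations assumes a reliable global alignment; low-complexity
  or heavily tagged constructs should be pre-trimmed.
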