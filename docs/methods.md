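# Methods

## Model

`rbpsvm` classifies proteins as RNA-binding (RBP) or not from primary
sequence alone. A sequence *x* over the 20-letter amino-acid alphabet Σ is
represented by its *k*-spectrum Φ_k(x): the |Σ|^k-dimensional vector of
occurrence counts of all overlapping length-k windows. The spectrum kernel
K_k(x, y) = ⟨Φ_k(x), Φ_k(y)⟩ is a linear kernel on that explicit feature
space, so the trained SVM decision function

    f(x) = Σ_i α_i y_i K_k(x_i, x) + b  =  ⟨w, Φ_k(x)⟩ + b,
    w = Σ_i α_i y_i Φ_k(x_i)

admits an exact per-k-mer weight vector w; the package asserts this
primal–dual reconstruction identity on every trained model. Class imbalance
(real proteomes run ~15% annotated RBPs) is handled by per-class cost
multipliers: the dual box constraints become 0 ≤ α_i ≤ C·W₊ for positives
and 0 ≤ α_i ≤ C·W₋ for negatives.

**Assumptions.** Composition of short motifs carries the class signal;
window position is ignored. Windows containing ambiguity letters
(B, J, O, U, X, Z) are skipped rather than expanded, keeping counts
integral and the feature space fixed at 20^k. Sequences shorter than k
yield the zero vector (and score the bias), with a warning — curation
normally enforces ≥ 50 residues.

**Kernel normalization.** Both the raw and the cosine-normalized spectrum
kernel are implemented; the default is *normalized* (feature vectors scaled
to unit L2 norm). Raw counts grow linearly with sequence length, so an
unnormalized kernel lets very long sequences dominate the margin;
normalization removes that length bias. This was a genuinely open design
point — both variants are exposed via `KernelConfig(normalized=...)` and
the `--raw-counts` CLI flag, and the weight-vector identity holds for
either (w is then built from the normalized support-vector coordinates).

## Solver

Training is delegated to libsvm (scikit-learn `SVC`) with a linear kernel
on the sparse 20^k count matrix — with 8000 dimensions at k = 3 the
explicit feature space is cheap, and the returned model is checked against
the weighted dual contract: |α_i y_i| within the class-specific box bounds
and Σ α_i y_i = 0 (tolerance 1e-6). Solver tolerance is 1e-6 with an
iteration cap of 10^5; non-convergence raises instead of silently returning
a bad model. Inside cross-validation and calibration, where the same data
are refit many times, the Gram matrix is precomputed once and fits use
`kernel="precomputed"`; this solves the identical optimization (decision
values agree bitwise with the explicit-feature path) at a fraction of the
cost.

## Model selection

Data are split 90/10 by stratified sampling (class ratio preserved in both
partitions; deterministic per seed). Hyperparameters are tuned by 10-fold
stratified CV maximizing balanced accuracy, over defaults
k ∈ {1, 2, 3, 4} and C ∈ {0.01, 0.1, 1, 10}; ties break toward the simpler
model (smaller k, then smaller C). The class weights are tuned in a
separate outer loop at fixed (k, C) over W₊ ∈ {1.0, 1.4, 1.8, 2.2} ×
W₋ ∈ {0.05, 0.1, 0.2, 0.5, 1.0}, ties breaking toward the least aggressive
weighting (smaller W₊, then larger W₋). Whether the outer loop may reuse
the same folds as the inner grid was an open protocol choice; here it does
(one fold assignment per search call, derived from the seed), which keeps
results bit-reproducible. As an alternative to weighting,
`bootstrap_balanced` trains `reps = 10` unweighted models on all positives
plus an equal-size negative subsample (without replacement) and averages
test metrics.

## Metrics and operating point

Confusion counts call a protein positive iff score ≥ cutoff. AUROC is
computed over all distinct cutoffs and equals the Mann–Whitney pair
statistic with ties counted ½. AUPR uses the non-interpolated step rule
Σ (R_i − R_{i−1})·P_i — interpolation conventions change AUPR, so the
choice is fixed and the test suite pins it against an exhaustive-sweep
oracle. Ratios with zero denominators are reported as 0 and flagged. The
operating cutoff is the F1-maximizing point of the PR sweep (ties to the
higher cutoff); published per-organism cutoffs (human 0.68,
*Salmonella* 0.28, *E. coli* 0.3) ship as named presets applied on the
calibrated-probability scale by default, since the scale of the original
values is not documented — `--scale decision` applies them to raw decision
values instead. Probabilities come from Platt sigmoid calibration
P(RBP | f) = 1 / (1 + exp(A·f + B)) fitted on out-of-fold decision values
with the standard smoothed targets, so the sigmoid never sees in-sample
scores.

## Curation

Positives are proteins annotated with the GO term for RNA binding
(GO:0003723) or any term from a user-supplied sub-term closure list (the
ontology is not traversed; the closure is data). Negatives start from the
whole proteome and pass an ordered chain: length filter (keep 50–6000
residues, boundaries inclusive), removal of excluded keywords/GO terms
(nucleotide binders, case-insensitive keyword match), removal of proteins
with hits in an excluded Pfam RNA-binding-domain list, removal of all
positive-annotated proteins, then redundancy reduction. Each step logs its
removal count; the chain is idempotent. Redundancy reduction is greedy
incremental clustering in decreasing length order at a strict > 0.90
identity threshold, where identity = maximal matched positions of a global
alignment (match 1, mismatch/gap 0 — i.e. the exact
dynamic-programming optimum) divided by the shorter sequence length. This
is exact at the scales handled here, unlike word-filter heuristics used by
fast clustering tools, and may differ from them on borderline pairs. The
shipped keyword/GO/Pfam lists are editable placeholders; users with
authoritative exports should substitute their own files.

## Disorder analysis

Per-residue disorder scores from an external predictor are thresholded at
0.5 (residue disordered iff score ≥ 0.5). This per-residue rule
approximates predictors whose native output is domain-level (average score
over a predicted globular domain); the approximation is deliberate and
flagged, since the domain segmentation itself is not reimplemented. A
tripeptide occurrence counts as disordered only when all three residues are
disordered — boundary-spanning windows count as ordered, the unambiguous
convention. The disorder fraction of a tripeptide is its disordered
occurrences divided by its total occurrences across the RBP set (ambiguity
windows excluded; never-occurring tripeptides have no row). The
weight–disorder profile sorts tripeptides by decreasing |w| (stable sort),
smooths the fraction with a centered moving average (configurable window,
default 50; window 1 = raw values) in place of a local regression smoother,
and contrasts the mean fraction in the top vs bottom decile of |w| — that
contrast, not the smoother, is the tested quantity.

## Synthetic data

The generator emulates labeled proteomes: residues i.i.d. from a background
distribution (uniform by default), lengths uniform on a range (default
50–500, inside the curation bounds and bracketing the ~300-residue median
of real proteins). Class signal is planted by insertion: for each planted
k-mer and sequence, Poisson((λ−1)·(L−k+1)·p(kmer)) copies overwrite random
windows, so planted k-mers occur ≈ λ-fold above background and λ = 1
reduces exactly to the null. Insertion gives exact control of planted
windows, which the parameter-recovery and disorder tests rely on.
Optionally each inserted window ± 5 residues is marked disordered
(score 0.9 vs 0.1), linking informative k-mers to disordered segments.

What the generator does **not** emulate: residue autocorrelation, domain
architecture, homology/redundancy structure, annotation noise, or
organism-specific composition. Passing tests therefore demonstrate that the
estimator recovers planted spectrum-level signal under controlled
imbalance — not field performance on real proteomes, which depends on
annotation snapshots.

Named fixtures (fixed conditions; seeds are part of the recipe):

| fixture | composition | signal |
|---|---|---|
| `separable` | 500 + 2833 (15% RBP) | 10 pos + 10 neg k-mers, λ = 20 |
| `imbalanced-15pct` | 150 + 850 | 10 positive k-mers, λ = 5 |
| `null` | 300 + 1700 | none (λ = 1) |
| `disorder-toy` | 60 + 340 + 3 hand-written proteins | λ = 20, planted windows disordered |
| `curation-toy` | 10 hand-written proteins | every filter branch, incl. 49/50-length and exact-90%-identity boundaries |

The λ = 20 "separable" regime produces a near-separable problem for
recovery checks; λ = 5 in the imbalanced fixture is deliberately moderate —
an imperfect classifier is the regime where class weighting matters, as in
real RBP prediction. The null control is evaluated on pooled out-of-fold
decision values from 5-fold CV rather than a single small test split: a
200-example split estimates a null AUROC with sampling sd ≈ 0.057, too
noisy to be informative, while pooled out-of-fold scores over all 2000
examples bring the sd to ≈ 0.02.

## Numerical choices and limitations

* All randomness flows through explicit integer seeds; repeated runs are
  bit-identical.
* Gram matrices are symmetrized ((G + Gᵀ)/2) against floating-point
  asymmetry; PSD is verified in tests via eigenvalues ≥ −1e-8.
* Model archives are JSON with shortest-repr floats, so decision values
  survive save/load exactly.
* Degenerate inputs: all-ambiguity sequences score the bias; single-class
  datasets, probability requests on uncalibrated models, and malformed
  input files raise typed errors rather than degrading silently.
* The greedy redundancy reduction is order-dependent (decreasing length,
  ties by id); representatives are cluster founders, matching common
  practice but not guaranteed-optimal clustering.
* Platt calibration assumes a sigmoidal score–probability link; on
  degenerate data a non-negative slope is possible and is logged as a
  warning.
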