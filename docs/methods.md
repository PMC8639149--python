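# Methods

`hemonet` reimplements, as a tested pipeline, a patient-similarity
topological-network analysis of intra-operative mean arterial pressure
(MAP) and heart rate (HR) monitoring in acute spinal cord injury, together
with the confirmatory regression stage that searches for an optimal MAP
range for neurological recovery. This note records the models, the
conventions chosen where the procedure was genuinely open, and what the
synthetic cohort does and does not establish.

## Pre-processing

Monitoring records arrive as per-patient time series at 1-min (Q1) or
5-min (Q5) resolution. Three artifact rules invalidate MAP samples:
values below 10 mmHg, values above 200 mmHg, and point-to-point changes
strictly greater than 40 mmHg. Filtering is implemented as *masking*, not
deletion, so the time grid stays regular and the jump rule remains well
defined; the jump compares each sample with the most recent *valid*
predecessor so a single spike cannot cascade invalidations. Filtering is
idempotent. Q1 records are downsampled to Q5 by averaging the valid
members of each five-sample window (an empty window produces an invalid
Q5 sample; a trailing partial window is averaged over what it has — the
source procedure is silent on partial windows and dropping them would
discard up to 4 min of signal).

Because surgeries have heterogeneous durations and are not aligned in
time, each patient is represented by the empirical CDF of each channel
evaluated on a fixed grid: 100 points per measure spanning the
*cohort-wide* range at 1%-of-range spacing (200 features total). The grid
is cohort-wide rather than per patient because the downstream Euclidean
distance requires bin b to mean the same threshold for every patient. HR
is not artifact-filtered by default (the rules above are stated for MAP);
bounds for HR are configurable in `FilterRules`.

## Embedding and topology preservation

Patient distance is the Euclidean distance between 200-bin CDF vectors.
Isomap runs as its three classical steps: union-symmetrized k-nearest-
neighbour graph (distance ties broken toward the smaller index), graph
geodesics (Dijkstra), and classical MDS of the geodesic matrix
(coordinates = top eigenvectors scaled by the square root of their
eigenvalues; negative eigenvalues discarded; signs fixed by forcing each
axis's largest-magnitude loading positive so repeated runs are
bit-identical).

Candidate solutions are scored two ways:

* **residual variance** RV(d) = 1 − R²(D̂m, Dy): squared Pearson
  correlation between geodesic and embedded pairwise distances over the
  upper triangle;
* **persistence preservation**: Vietoris–Rips diagrams (dimensions 0
  and 1) of the geodesic matrix and of each embedded-space distance
  matrix, compared by the 2-Wasserstein distance (WD0, WD1).

Rips persistence is computed from the distance matrix directly: dimension
0 from the minimum spanning tree, dimension 1 by Z/2 reduction of the
triangle boundary matrix with columns stored as integer bitmasks. The
filtration is truncated at the *enclosing radius*, at which the complex
is a cone and hence contractible: every loop has died and exactly one
connected component survives. That essential dim-0 class is kept with its
death capped at the enclosing radius so WD0 stays finite and comparable
across matrices (the alternative — dropping it — is a convention knob;
the cap is the package's default and the one the tests pin down). The
Wasserstein distance solves the exact optimal partial matching
(assignment problem on the diagonally-augmented squared-cost matrix, L2
ground metric), so `wd(A, ∅)` for a single bar (b, d) is (d − b)/√2.

**Selection rule.** k_min is the smallest k giving a connected graph;
candidates are k_min..k_min+4. The selected k minimizes WD0 + WD1 summed
over candidate dimensions (ties to the sparser graph). At that k, the RV
elbow is located automatically as the maximum second difference of RV(d),
and d is the *smallest* dimension at or beyond the elbow whose WD0 is
within 1% of the minimum. The tolerance matters: WD0 often keeps shaving
off slivers as dimensions are added, and a strict argmin would buy those
slivers with extra coordinates; the 1% rule makes the "good compromise"
judgment deterministic. All per-(k, d) diagnostics are retained for
manual override.

## Network stage

The similarity network is the unweighted union-symmetrized k-NN graph of
the embedded coordinates, with k the smallest value producing a connected
graph. Clustering uses walktrap (Pons–Latapy, via igraph), which is
deterministic: its "random steps" parameter t is the *length* of the
random walks whose transition-probability profiles define community
distance — nothing is sampled and no seed is involved. The walk length is
selected by computing, for every t in 1..100, the max-modularity cut of
that t's dendrogram, and keeping the first t attaining the global maximum
modularity (re-cutting per t, which is what the selection criterion
describes). Modularity is Q = Σ_c (e_cc − a_c²) computed by direct edge
counting. The clustered network can be contracted to one node per cluster
(edge iff any patient edge crosses; numeric attributes averaged per
cluster). Attribute association is measured by numeric assortativity:
the Pearson correlation of the attribute over the two ends of every edge,
both orientations included; zero variance yields an undefined (reported
missing) coefficient.

## MAP-range scan

Per candidate interval [L, U], a patient's exposure is 5 min × the number
of valid Q5 samples with MAP < L or MAP > U. Boundary values count as
*inside* (closed interval) — the source procedure does not state the
convention; the closed choice is documented here and configurable in
spirit by shifting bounds half a unit. Two families are scanned:
symmetric intervals (90 − s, 90 + s) widening 1 mmHg per step around
90 mmHg (the improver-group mean MAP), and asymmetric intervals with the
lower limit fixed at 76 mmHg and the upper limit swept upward 1 mmHg at a
time. Exposure is non-increasing along either nested family, which the
tests assert per patient.

The single most predictive range is chosen by an L1-penalized logistic
path: columns standardized, λ grid geometric from just above λ_max (the
smallest penalty zeroing every coefficient) down to 0.02·λ_max, and the
"last-standing" predictor defined as the column active alone at the
largest λ with exactly one non-zero coefficient (bisection refines λ when
the grid jumps over the one-predictor window; exact ties fall back to the
largest coefficient at first activation). Standardization makes the
selection scale-free; the selected column is reported by its original
identity and refit unpenalized as a solo predictor with Wald test and
leave-one-out validation. Because nested ranges are highly collinear and
exposure is quantized at 5 min, the selected range should be read as an
indicator of where the optimum lies, not a hard clinical boundary — the
grid of near-ties around the winner (visible in the retained path) is the
honest uncertainty statement.

## Regression suite

Models are declarative term lists over a clinical table: plain
covariates, polynomial blocks (entering/leaving as a unit), natural cubic
splines, categorical blocks with an explicit reference level, and
interactions. Fits are maximum-likelihood Bernoulli-logit (statsmodels
GLM), complete-case per model with the dropped-row count recorded.
Polynomials default to an orthonormal coding (QR of the Vandermonde
matrix, columns orthogonal to the intercept with unit norm); deviance,
AIC and likelihood-ratio results are coding-invariant, individual
polynomial coefficients are not — comparisons of printed coefficient
values are therefore basis-dependent, while deviance/AIC comparisons are
basis-free. The natural spline uses the truncated-power natural basis
with boundary knots at min/max and df − 1 interior knots at equally
spaced quantiles; it spans the same function space as the standard R
construction, so likelihood-based quantities agree even though the
columns differ.

Model comparison uses the deviance-difference chi-square LRT (nesting
checked structurally), AIC = deviance + 2p, and
AICc = AIC + 2p(p + 1)/(n − p − 1) with p counting the intercept.
Leave-one-out cross-validation refits the coefficients n times on the
design matrix built once from the complete cases (the basis is a fixed
transformation; only coefficients are re-estimated per fold). The LOOCV
*error* is the mean squared held-out prediction error (Brier) — for the
intercept-only model this has the closed form that reproduces the
published 0.246 with 42/103 improvers, which is what identifies the
published column as a Brier error rather than a misclassification rate.
Classification metrics (accuracy, Cohen's kappa) threshold the held-out
probabilities; the threshold balancing sensitivity and specificity is
found by scanning the observed probabilities plus 0.5, ties resolved
toward 0.5. ROC/AUC uses the rank statistic with ties counted one half.
Exhaustive model search fits every non-empty subset of a term pool
(grouped terms atomic) and ranks by AICc; unfittable subsets (rank
deficiency, separation-induced failure) are warned about and skipped.
Probable separation is flagged on any fit rather than hidden.

## Synthetic cohort

The generator emulates the deposited cohort's structure: by default 118
patients at Q5 with surgery durations uniform on 120–950 min
(series of 24–190 samples, matching the published duration extrema),
patient-level MAP means drawn from a hypo/normo/hypertensive mixture
(75/90/108 mmHg at weights 0.25/0.50/0.25 — the marginal phenotype
distribution is not published, so these are configuration, not claims),
and within-surgery dynamics as a stationary AR(1) (φ = 0.9, innovation SD
4 mmHg), the minimal process reproducing smooth within-surgery drift with
controlled second-order statistics. HR is an independent AR(1) around a
patient-level mean (80 ± 12 bpm). Artifacts are injected at a
configurable per-sample rate as either out-of-band values or >40 mmHg
jumps relative to the most recent uncorrupted sample (mirroring the
filter's reference rule so adjacent artifacts stay detectable), with the
ground-truth corruption mask returned so filter sensitivity is directly
assertable.

Binary improvement follows one of two logit models: a concave quadratic
in standardized average MAP (default coefficients 0.2, 0.6, −1.2, giving
≈40% improvers as in the published cohort) or a linear function of
minutes outside a configurable true range (default intercept 0.37 and
slope −0.006 per minute, the scale of the published solo-predictor fit).
AIS discharge grades are derived from (admission, improved) — admission
from severity frequencies typical of an acute surgical cohort, improvers
moved up exactly one grade — rather than modelled ordinally; multi-grade
recovery is out of scope. Everything is reproducible bit-for-bit from the
configuration seed.

What the synthetic tests show: that the pipeline recovers planted
structure — a true MAP range (76, 110) is recovered by the LASSO scan
within ±3 mmHg (lower) / ±6 mmHg (upper) in the majority of 20 seeds at
n = 500, and a true concave quadratic aMAP effect is detected (negative
quadratic term, significant quadratic-vs-linear LRT) in ≥80% of 50 seeds.
What they do not show: performance under real-data features the generator
lacks — vasopressor interventions, non-stationary drift, center effects,
informative missingness, or multi-surgery patients.

## Numerical choices and limitations

* Eigen-decomposition via symmetric `eigh`; eigenvalues below 1e−10 of
  the largest treated as non-positive and discarded.
* Geodesic computation requires a connected graph and errors with the
  component count otherwise.
* Modularity cut ties and walktrap merge order follow igraph's
  deterministic ordering.
* Degenerate inputs error loudly: empty series, zero cohort-wide range,
  constant predictors (rank-deficient designs), single-class labels for
  ROC/threshold calibration, zero-variance assortativity attributes
  (reported missing rather than raised).
* Problem sizes in the test suite (cohorts of 20–40 for pipeline tests,
  n = 500 for recovery properties) were chosen as the smallest at which
  the targeted effects are stable.
* Dimension-1 persistence is O(n³) in triangles and is the pipeline's
  bottleneck above a few hundred patients; landmark/sparse variants are
  out of scope.
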