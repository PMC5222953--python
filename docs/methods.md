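# Methods

## Model

The pipeline treats a subject's task activation map as a parcel-wise
linear function of their resting-connectivity features.

**Features.** For subject *i* with resting run **R** (T_rest × n) and K
group component maps **S** (K × n), dual regression runs in two stages.
Stage 1 is a spatial multiple regression of every volume on the demeaned
group maps, giving component time courses **A** = **R** pinv(**S̃**)
(T_rest × K); demeaning the maps first means a global intensity offset in
the data cannot leak into the time courses. Stage 2 regresses each
vertex's time course on each component time course *separately*, with an
intercept, so the map value is cov(R_v, a_k)/var(a_k). Single rather than
joint stage-2 regressions are the appropriate choice for short clinical
runs (85 volumes here), where a joint fit over K regressors is poorly
conditioned. The K subject maps are normalised to zero mean and unit
Euclidean norm and prepended with an intercept column to give
**X**⁽ⁱ⁾, n × (1+K). Normalisation makes features — and everything
downstream — invariant to the scale of the resting data. Time courses are
not variance-normalised between stages; the stage-2 covariance ratio is
already offset- and scale-consistent.

**Targets.** The observed map **y**⁽ⁱ⁾ is the effect-size (COPE-like)
contrast from a per-vertex GLM of the task run: intercept, boxcar
convolved with the canonical double-gamma HRF (peak delay 6 s, undershoot
delay 16 s, unit dispersions, undershoot ratio 1/6), and the temporal
derivative of that regressor. Data and regressors are high-pass filtered
identically, by residualising against a discrete-cosine basis with
periods longer than 100 s. The effect-size map is the default prediction
target, with the t-map available behind a flag: which of the two a given
study predicts is a free choice, and for correlation-based evaluation the
distinction is a per-vertex rescaling. No prewhitening is applied — the
simulator's noise is white, and none of the estimators assume otherwise.

**Prediction.** The space is divided into P non-overlapping parcels by
winner-takes-all over component maps (ties to the lowest index). Within
parcel p, each training subject contributes β_p⁽ⁱ⁾ =
pinv(X_p⁽ⁱ⁾) y_p⁽ⁱ⁾, computed by SVD with relative singular-value cutoff
1e-10; a parcel smaller than 1+K falls back to the minimum-norm solution
with a warning. The aggregate model is the unweighted element-wise mean of
training betas — all m−1 others in leave-one-out, the control group in
the transfer regime — and predictions ŷ(v) = X(v,:) β̂(parcel(v)) are
concatenated over parcels. A single whole-space model (P = 1) is provided
for comparison; with parcel-varying coupling it is strictly worse, which
is the rationale for the piecewise approach.

**Evaluation.** The similarity matrix S holds Pearson correlations of
every observed map (rows) against every predicted map (columns);
"inner product" and "correlation" coincide for demeaned, unit-norm maps.
Per subject j, the differences d_k = S(j,j) − S(j,k), k ≠ j (row-wise:
one observed map against all predictions; the column-wise convention is
available behind a flag) are summarised as t = mean(d)/(sd(d)/√(m−1)) and
referred to a null built from 10,000 random sign flips of d, one-sided
(matched > unmatched, the directional hypothesis), with the add-one
estimator p = (1 + #{t* ≥ t})/(1 + n_perm). Each subject's permutation
stream is spawned from a master seed. Degenerate d (zero variance) is
reported as such, with p at its extreme attainable value. Group-level
statistics: Welch t for diagonal vs off-diagonal entries, pooled
two-sample t for control-vs-patient identification, one-way ANOVA across
pathology subgroups, Pearson correlations between per-subject matched
similarities across regimes and against QC measures. Row/column
standardisation of S exists purely for heat-map display and never feeds a
statistic.

**A calibration caveat, stated plainly.** The per-subject sign-flip test
is *anticonservative*. Every difference d_k shares the matched entry's
noise as a common term: writing row entries as c + b_k with iid entry
noise b, d_k = b_j − b_k, so mean(d) = b_j − b̄ while sd(d) estimates
sd(b), and the nominal t is inflated by roughly √(m−1) relative to the
sign-flip null whenever the matched entry sits above its row's average.
On fully null synthetic cohorts (shared coupling, zero spread) the
per-subject rejection rate at α = 0.05 is ≈ 0.47, not 0.05; the
permutation machinery itself is exactly calibrated on independently
sign-symmetric differences (measured 0.043 over 1,000 replicates). The
test should therefore be read as a descriptive ranking of the matched
correlation within its row, not as a calibrated hypothesis test; a rank
(percentile) test of the diagonal among its row would be calibrated under
exchangeability, but is not what this procedure computes. The test is
kept in its published form deliberately.

**Thresholding** is visualisation-grade only. A three-component mixture —
Gaussian (noise), positive Gamma (activations), negated Gamma
(deactivations), both Gammas anchored at zero since the Gaussian owns the
near-zero mass — is fitted per map by EM with exact M-steps (weighted
Gamma MLE via the digamma equation), initialised from the interquartile
bulk and method-of-moments on each tail, with two jittered restarts
keeping the best log-likelihood. The height threshold is the median
(inverse CDF at 0.5) of the fitted positive Gamma; a positive weight
below 0.01 means "no credible positive activation" and yields an empty
mask. Suprathreshold vertices are grouped into connected clusters
(edge-sharing adjacency — the adjacency definition for surface clusters
is a convention, and edge-sharing is assumed) and clusters with mass
c = Σ_v T(v) below a role threshold are dropped: 240 for observed and 120
for predicted maps on the 91,282-grayordinate space. Mass is extensive,
so the analysis scripts scale these defaults by the vertex ratio on
synthetic spaces. Exactly-zero vertices (lesions) are excluded from the
mixture's fit sample.

**QC.** tSNR is the temporal mean over the standard deviation of the
linearly detrended residual (detrending choice documented; the summary is
the median over vertices, mean switchable). Stimulus-correlated motion is
the maximum absolute Pearson correlation of the six motion traces with
the convolved task regressor.

## The synthetic generator

The generator emulates exactly the structure the model assumes, plus the
clinically motivated complications:

- **Space**: a 50 × 40 4-connected lattice (n = 2,000) standing in for the
  cortical surface mesh; real-surface adjacency can be supplied as an edge
  list. Vertices are 0-based internally; the text format for parcellations
  is one 1-based label per line.
- **Group components**: K = 8 Gaussian bumps (peak 1), centres spread by
  farthest-point sampling so pairwise map correlations stay below 0.5;
  a separate draw of P = 10 bumps defines the parcellation by
  winner-takes-all.
- **Subjects**: per component, subject map = group map + spread ×
  ‖group map‖ × (unit-norm smooth field from graph-diffusion smoothing of
  white noise). Spread is 0.3 for controls and 0.6 for patients — the
  patient/control variability ratio is a free simulation parameter chosen
  once; only the ordering matters for the qualitative claims.
- **Resting runs**: Y = A S + E with T_rest = 85, TR 3.5 s, white noise
  (σ = 0.5, with per-subject lognormal jitter emulating scan-quality
  variation) and a baseline of 100 units so tSNR is meaningful. The
  component time courses A are drawn Gaussian and then exactly
  decorrelated (column-centred QR, rescaled to unit sample variance).
  This is a deliberate idealisation: with merely independent draws the
  empirical cross-correlation of time courses is O(1/√T) ≈ 0.11 at
  T = 85, which mixes components in stage 2 and leaves an O(K/T) ≈ 8%
  systematic bias in recovered coupling even at zero noise; exact
  decorrelation makes the planted maps identifiable at finite run length,
  so zero-noise runs of the full pipeline recover the planted coupling
  exactly. Real time courses are of course correlated — recovery on real
  data carries the corresponding attenuation.
- **Task maps**: y(v) = X_true(v,:) · coupling(parcel(v)) + deviation,
  where X_true is built from the subject's (lesion-nulled) maps with the
  same normalisation the pipeline uses. The shared coupling is drawn with
  component coefficients at scale √n and the intercept at scale 1, so
  every column's per-vertex contribution is O(1) (with a common scale the
  intercept column, norm √n against unit-norm features, swamps the
  individual structure). Each parcel's coupling is projected onto the row
  space of the group-level design restricted to that parcel: within a
  parcel, components whose bumps lie elsewhere are near-collinear with
  the intercept, so a raw draw is identifiable only up to the parcel's
  null space — the projection plants the vector that least squares
  recovers in the noise-free limit without changing the generated maps.
  The per-subject deviation (σ = 1, ×1.5 in patients) models activation
  structure the linear model cannot capture; the patient factor encodes
  pathology-driven model mismatch.
- **Task runs**: T_task = 101 at TR 3 s; 5 cycles of 30 s baseline then
  30 s task; vertex time course = map value × HRF-convolved boxcar +
  white noise (σ = 1) + baseline.
- **Lesions**: graph balls of radius 3 (~25 vertices) at random centres
  in round(0.38 × n_patients) patients; resting signal and planted task
  signal are zeroed inside (noise is not — scanners measure noise in
  lesions too).
- **Motion**: six AR(1) traces plus a task-locked component of random
  amplitude on the first trace.
- **Pathology labels**: patients split TLE/tumour/other in proportions
  42:20:9.

Cohorts are byte-reproducible from the spec seed (all streams spawned
from one `SeedSequence`), and the planted truth is stored separately from
the subject data so evaluation code cannot silently touch it.

### What the generator does *not* emulate

White (not autocorrelated) noise — nothing fitted here assumes
whiteness, but real GLM t-values would be optimistic; no head-motion
geometry, susceptibility artefacts, haemodynamic nonlinearity or
registration error; subject deviations live in map space, not time-course
space, because the predictive model consumes maps; and planted "activation"
is dense and signed rather than sparse and positive, so the
mixture-threshold step legitimately reports "no credible positive
activation" for some synthetic maps. Consequently, passing tests show
that the pipeline recovers the structure it assumes when that structure
is present, at clinically realistic run lengths and noise levels — not
that the assumptions hold in real data.

One known qualitative inversion: in clinical data, patients are
identified slightly *worse* than controls; in the generator, larger
planted spread makes synthetic patients more distinctive, and the ×1.5
model-mismatch factor does not fully reverse that, so the synthetic
control-vs-patient difference has the opposite sign. The variability
ordering itself (patients more variable, in observed and predicted maps
alike) is reproduced. Similarly, task tSNR correlates negatively with
identification here because strong individual activation inflates
task-run variance — an artefact of counting signal as "noise" in tSNR.

## Numerical choices

- Pseudoinverse cutoff 1e-10 (relative), everywhere a pinv appears.
- Winner-takes-all ties break to the lowest component index.
- EM: exact weighted-MLE M-steps; convergence when the log-likelihood
  improves by < 1e-6; weights floored at 1e-8; Gaussian variance floored
  at 1e-12; non-convergence is reported via a flag with the best fit
  returned. A missing sign in the data pins the corresponding Gamma
  weight near zero.
- Dice of two empty masks is defined as 0.
- Degenerate similarity rows (zero-variance d): p = 1/(1+n_perm) if all
  d > 0, p = 1 otherwise, flagged.
- Sub-threshold problem sizes: the default study (m = 30, n = 2,000,
  K = 8, P = 10, 10,000 permutations) runs in seconds; the null-
  calibration experiment uses 17 cohorts (510 subject-tests) at 1,000
  permutations, since the rejection decision at α = 0.05 is insensitive
  to the permutation count well above ~500.
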