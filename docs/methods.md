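# Methods

This note documents the models, estimators, and design choices behind
`dynconn`, and what the synthetic-data experiments do and do not establish.

## Generative model

The latent state of M regions evolves as a condition-switched first-order
MVAR, `s(t) = C_{j(t)} s(t−1) + w(t)` with iid Gaussian state noise of
variance Q per region. The block design guarantees at most one active
condition per frame, so the switched sum over conditions reduces to
selecting one matrix per frame. Frames with no active analysis condition
(cues, fixation, trailing rest) are driven by an always-on *baseline*
coupling matrix; without it the latent dynamics would be zeroed through
fixation blocks. The baseline defaults to a diagonal decay 0.5·I in the
generator and is estimated jointly by default in the fitter (a flag freezes
it). This baseline convention is an explicit modeling assumption of this
package, not a property inherited from any particular task dataset.

BOLD observation: region m's signal is the inner product of b_m Φ with the
region's last L latent values plus iid Gaussian noise σ_m². Φ holds the
canonical double-gamma HRF and (by default) its temporal derivative,
sampled at the TR and unit-peak normalized. Double-gamma parameters are the
conventional ones: peak delay 6 s, undershoot delay 16 s, both dispersions
1, undershoot ratio 1/6, support 32.4 s. Latent pre-history before each
session is zero; the generator runs a 50-frame baseline burn-in per session
that is discarded, and sessions are simulated independently.

The default task layout emulates an HCP-style n-back session: per session,
8 task blocks (2.5 s cue + 10 trials × 2.5 s) alternating 0-back/2-back,
4 fixation blocks of 15 s, 405 frames at TR 0.72 s. A frame is labeled
with a condition when its onset falls inside that block's trial period
(cues are unlabeled).

### Cohorts and behavior

A cohort perturbs the template's off-diagonal coupling entries with
Gaussian noise (default sd 0.05), resampling until the spectral radius of
every condition matrix is below 1 (bounded retries). Behavioral scores
(accuracy and reaction time per condition) are a linear function of the
subject's true coupling entries via sparse loadings, plus Gaussian noise,
around group-level baselines (0-back: 0.93 / 738 ms; 2-back: 0.86 /
966 ms). Real behavior is of course not generated by a linear-Gaussian map
of coupling weights; the behavior layer exists so that brain–behavior
analyses have a planted, quantifiable effect to recover.

What the generator does *not* emulate: voxelwise spatial structure beyond a
rank-1 loading fixture, head motion (only optional white-noise confound
columns), physiological noise spectra, hemodynamic nonlinearity
(balloon-type saturation), and session-level drifts. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every artifact of real fMRI.

## Estimation (EM with Kalman smoothing)

The estimator stacks L latent lags into a companion-form augmented state
(dimension M·L). The transition applies the active condition's matrix to
the leading block and shifts the rest; the observation row of region m is
b_m Φ on the region's lag window; process noise enters only the leading
block. The E-step is an exact Kalman filter (Joseph-form updates, Cholesky
innovations) plus RTS smoother with lag-one cross-covariances; sessions are
filtered independently with the prior re-initialized at each session start
(mean 0, covariance 10·Q·I — scaling the prior with Q keeps the latent
gauge exact). The M-step is closed form: each C_j from condition-pooled
smoothed second moments, b_m by regressing the data on Φ-projected
lag-window moments, σ_m² from residual moments. Q is fixed at 1: latent
scale and hemodynamic gain trade off exactly, so the gauge pins the latent
scale, b_m absorbs the gain, and the coupling matrices are invariant to
the choice.

Numerical and design choices:

* **Initialization.** Coupling is initialized by per-condition ridge VAR(1)
  on HRF-deconvolved BOLD (regularized least-squares deconvolution of the
  canonical HRF, session-wise). Initializing from the raw BOLD VAR sits in
  a worse likelihood basin noticeably more often.
* **Multi-start.** Starts vary the deconvolution regularization
  (λ, 0.2λ, 5λ) before adding random perturbations; the best final
  likelihood wins. Default 3 starts.
* **Stability during EM.** M-step iterates are *not* projected back into
  the unit circle: projection breaks the EM monotonicity guarantee, and
  the finite-horizon filter tolerates transiently unstable iterates
  (typically the sparsely sampled baseline matrix). Only the
  initialization is projected.
* **Stopping.** Relative log-likelihood change below `loglik_tolerance`
  (default 1e-5) or `max_iterations` (default 50). The log-likelihood
  trace is non-decreasing up to 1e-6 absolute slack per step; this is
  asserted in the tests on every fit.
* **Convergence caveat.** The likelihood surface can be nearly flat across
  quite different coupling matrices when the HRF strongly low-passes the
  lag-1 dynamics (see below); `converged=True` means the stopping rule
  fired, not that the maximizer is unique.

### Identifiability and the recovery study design

The coupling matrices are identified from the temporal fine structure of
the latent signal, which the HRF attenuates. At TR 0.72 s the canonical HRF
spans ~45 frames and suppresses most frequencies above ~0.15 Hz, while
lag-1 dynamics live up to the 0.69 Hz Nyquist; in that regime the
likelihood is nearly flat across substantially different C (we observed
solutions differing by 0.2 in recovery correlation within ~2 nats), and
median recovery saturates around 0.75 regardless of optimizer effort. The
package's canonical **recovery study** therefore uses TR 2 s with a 12-s
(6-lag) HRF window and a dense alternating block design (2 sessions × 400
frames, no fixation), where the model is well specified and median
recovery across 20 subjects at SNR 1 is ≈ 0.87. The HCP-like TR-0.72
layout remains the generator default for pipeline demonstrations. Problem
sizes in the test suite (subject counts, replicate counts, permutation
counts) are chosen so the full suite runs in minutes on one core;
thresholds are not adjusted to the sizes.

## Network analyses

**Flow degrees.** With weights oriented (m, n) = influence of n on m,
outflow of region n is the mean of column n off the diagonal, inflow of m
the mean of row m; net = outflow − inflow. Net degrees sum to zero exactly.
The group hub test is a per-region one-sample (or paired, for condition
contrasts) two-sided t test of net degree with Benjamini–Hochberg
correction; hubs are the extreme significantly positive / negative regions.

**Communities.** Louvain local moving + aggregation, written for signed
directed weighted graphs: modularity is computed on the positive and
negative parts separately, each with the directed null k_in k_out / s, and
combined as Q = Q⁺ − s⁻/(s⁺+s⁻)·Q⁻ (asymmetric signed convention).
Consensus: many seeded runs (default 1000) produce a co-occurrence matrix;
it is thresholded at 0.5 and re-clustered until all runs agree (fixed
point). Labels are canonicalized by first appearance so identical
partitions always compare equal. The group matrix entering community
detection is the across-subject mean per condition.

**Controllability.** Average controllability of node set B is
trace(W) with A W Aᵀ − W + B Bᵀ = 0 (discrete, default — consistent with
the discrete dynamics and a bounded infinite-horizon Gramian for spectral
radius < 1) or A W + W Aᵀ + B Bᵀ = 0 (continuous, selectable; requires
Hurwitz A). Both are scipy Lyapunov solves. The trace is a modular set
function of the Gramian, so set-level values are means of node-level
values. `prepare_system` offers strict behavior (error on instability,
the default, since the method is meant for stable estimated matrices),
spectral rescaling A/(1+ρ) for robustness runs, and a mean-absolute
off-diagonal weight normalization variant; all transformations are logged
in the result.

## Inference layer

Paired tests report two labeled Cohen's d variants, because the two common
conventions genuinely differ for paired designs: d_pooled = Δmean /
√((s₁²+s₂²)/2) and d_t = t/√n (the latter standardizes by the SD of the
paired differences). Repeated-measures ANOVA is delegated to pingouin
behind the package's interface. Classification is a linear SVM with k-fold
CV where folds are split by subject (both condition rows of a subject
share a fold — otherwise a subject's own data leaks into its test fold);
the permutation null swaps each subject's pair of labels with probability
1/2. CCA computes all canonical correlations via QR + SVD (sklearn's
iterative CCA is used only as a cross-check in the tests); Pillai's trace
is Σ r²; significance comes from re-running CCA on row-permuted Y.
Permutation p-values use (1+b)/(1+B) and therefore never reach zero.

## Stability analyses

Pattern stability: per subsample (drawn without replacement), each edge
gets a t test (one condition, or a paired condition contrast), the matrix
is thresholded by BH-FDR at α = 0.01 with surviving edges keeping their
mean *signed weight* (not binarized — the quantity correlated is the
multivariate influence pattern), and the off-diagonal vector is correlated
with the full-sample matrix built by the identical pipeline. Subsample
indices are sorted so the full-cohort subsample reproduces the reference
exactly. Finding stability: the probability, across replicates, that a
pluggable boolean predicate (e.g. "this region is the significant outflow
hub") holds in the subsample. The default size grid is 20–600; replicate
counts are configurable (500 by default, smaller in the test suite).

## Known limitations

* Per-subject fitting only; no hierarchical group model.
* EM is a local optimizer; multi-start mitigates but cannot guarantee the
  global maximum, and weak identifiability at fast TRs is a property of
  the model class, not of the optimizer.
* The signed directed Louvain and consensus conventions (asymmetric
  negative weighting, 0.5 consensus threshold) are reasonable defaults
  among several in use; results on weakly modular graphs can depend on
  them.
* Whether discrete or continuous Lyapunov conventions are "right" for
  BOLD-derived coupling is a modeling judgment; both are provided and the
  choice is recorded in every output.
* The generator's behavior model is linear-Gaussian by construction;
  detecting its planted effects validates the inference machinery, not
  any claim about real brain–behavior coupling.
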