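# Methods

## The generative model

Each of the four default-mode-network sources (left and right lateral
parietal cortex, precuneus/posterior cingulate, medial prefrontal cortex) is
a convolution-based neural mass with Jansen-Rit kinetics: a granular spiny
stellate population, a pyramidal output population and an inhibitory
interneuron population, coupled through second-order synaptic kernels

    v''(t) = (H / tau) u(t) - (2 / tau) v'(t) - v(t) / tau^2

with excitatory gain/time-constant (He, tau_e) and inhibitory (Hi, tau_i),
and a centred sigmoid firing function S(v) = 2 e0 / (1 + exp(r (v0 - v))) -
2 e0 / (1 + exp(r v0)), so that the resting fixed point sits at the origin.
Within a source the populations are connected by gains g1..g4; between
sources, typed extrinsic connections scale literature prior-mean strengths
(forward 32, backward 16, lateral 4) by e^a with a the estimable
log-scaling.  Forward connections drive the stellate population, backward
connections the pyramidal and inhibitory-interneuron populations, lateral
connections all three — so backward influences are predominantly modulatory
and forward influences driving.  Edge types follow the cortical hierarchy
mPFC > Prec > {lLP, rLP}.  All constants (and which parameters are free)
live in `specdcm/constants/priors.yaml`; they are adopted from the standard
convolution-model literature, not fitted here.  At these values the
linearized network is stable with a spectral resonance near 11 Hz.

The predicted cross-spectral density over the 1-30 Hz grid (0.25 Hz steps,
117 bins) is

    G(f) = g^2 L T(f) Gu(f) T(f)^H L^T + Gn(f)

with T(f) the source-to-source transfer matrix of the dynamics linearized
at the fixed point (innovations enter at the stellate population, the
pyramidal potential is read out), Gu a diagonal per-source innovations
spectrum — a white + 1/f mixture, amplitude and exponent log-scaled — and
Gn channel noise with a channel-specific diagonal and a common rank-one
term.  The lead field L is, by default, a seeded random well-conditioned
8 x 4 matrix with unit column norms standing in for an anatomical forward
operator; a user-supplied matrix is accepted.

Only extrinsic couplings, innovations amplitudes, the lead-field gain and
the channel-noise amplitudes are estimated (19 free parameters); intrinsic
physiology, sigmoid slope and spectral exponents are fixed at their prior
means with zero prior variance, reflecting the analysis goal of
between-source connectivity.

### Numerical notes

The Jacobian of the 32-state system is nearly defective — four almost
identical sources give eigenvector condition numbers around 1e10 — so
resolvents (i 2 pi f I - J)^{-1} are evaluated via a complex Schur
factorization with vectorized triangular substitution (backward stable),
not an eigendecomposition.  Derivatives of G with respect to couplings are
analytic: each edge perturbs J by a rank-one matrix, so dT(f) is an outer
product of two resolvent solves; amplitude-like parameters scale single
additive components of G.  Both are verified against finite differences.

## Time-domain simulator (the oracle)

`simulate_timeseries` integrates the full nonlinear dynamics driven by
coloured innovations whose one-sided spectrum matches Gu (synthesized by
FFT shaping of white Gaussian noise), observed through the lead field plus
channel noise matching Gn.  The default one-step scheme is a stochastic
Heun (second-order) update: a plain Euler-Maruyama step at dt = 1 ms
under-damps the ~11 Hz resonance by O(omega^2 dt) and inflates spectral
power there by 15-25%, which would mask genuine model-vs-simulation
discrepancies; Heun removes this bias at unchanged step size.  Euler
remains available (`integrator="euler"`).  Identical seeds give bitwise
identical recordings.  The simulator agrees with the linearized spectral
prediction to a median relative error of about 13% over the band for a
600-s run (the residual is dominated by Welch estimation noise), which is
what makes it usable as an independent oracle for `predict_csd`.

## Subject-level inversion

Observed cross-spectra are scored, by default, with the complex-Wishart
likelihood whose degrees of freedom equal the number of averaged epochs
recorded in the data's metadata: an epoch-averaged cross-spectrum of
Gaussian data is exactly Wishart distributed, and the synthetic observation
model (below) draws from precisely this distribution.  A Gaussian
feature-space likelihood (real upper triangle + imaginary strict upper
triangle per frequency, one log-precision hyperparameter per block,
variational updates) is also provided; it is the right tool for the
linear-Gaussian surrogate checks, but on spectral data its mis-weighting of
the multiplicative sampling noise measurably attenuates coupling
estimates, so it is not the default.

Optimization is Fisher-scored Gauss-Newton ascent on the Laplace free
energy with Levenberg-Marquardt damping; accepted steps never decrease F,
convergence is declared at dF < 0.01 nats (default cap 128 iterations;
cohort analyses use 24-32).  Initialization is at the prior mean;
candidates with unstable linearizations are rejected and shrink the trust
region (in scoring contexts they receive a large penalty instead of an
exception).

Two properties of this posterior required care.  First, the log-scaling
parametrization makes the exact posterior left-skewed, so the Laplace mean
is biased toward zero.  Second, the local Fisher information varies by
orders of magnitude along narrow likelihood ridges, so the curvature at the
mode alone can overstate precision dramatically.  `FitOptions.refine = n`
draws n importance samples from the (inflated) Laplace proposal, truncates
the weights, and replaces the posterior mean by the re-weighted mean and
the covariance by the inverse of the weight-averaged Fisher information
over the highest-weight draws.  With 300 draws this restores 90%-interval
coverage of a -0.6 coupling perturbation to ~90% under the default study
conditions, at about 0.6 s per subject of extra cost.

## Group level

Subject posteriors, restricted to the 12 couplings, enter a hierarchical
GLM: theta_i = (x_i kron I) beta + eps_i with a design of intercept plus
mean-centred group indicator, Gaussian random effects with fixed diagonal
covariance (1/16 of the first-level prior variance per coupling), and a
shrinkage prior on beta (the first-level prior variance per covariate).
Each subject contributes through its likelihood kernel — posterior
precision minus prior precision (clamped to be PSD) — which analytically
undoes first-level shrinkage.  The posterior over beta and the second-level
free energy are closed-form Gaussian algebra; no iteration.

Nested models switch group-difference effects off by pinning their prior
variance to 1e-8.  Bayesian model reduction gives each reduced model's
evidence and posterior exactly (verified against brute-force re-inversion
to 1e-6).  The default search is exhaustive over the 2^12 on/off patterns
(about a second); greedy pruning is provided for larger spaces.  Bayesian model averaging weights the best 256 models by softmaxed
evidence; a connection's posterior probability Pp is the total weight of
averaged models in which it is on, and connections are retained at strictly
Pp > .99.

## Classification

A held-out subject is scored by fitting the group model to the training
subjects only, forming the label-conditional posterior-predictive density
over the subset couplings (random-effect covariance plus propagated
group-effect uncertainty), and integrating the subject's likelihood kernel
against each; Bayes' rule with equal label priors gives the membership
probability, cut at 0.5 for confusion matrices.  Balanced accuracy is the
reported summary, guarding the 6-vs-11/12 group imbalance.  Leave-one-
subject-out cross-validation refits the group model per fold (training
checksums are recorded per fold, so leakage is detectable);
leave-one-state-out trains on two labelled groups and scores an unlabelled
third.  The data-driven search ranks connections by |expected difference
effect| (ties toward the lower canonical index) and grows subsets greedily,
stopping at the first non-improvement.

## Synthetic cohorts

`make_cohort` emulates the study design: 11 controls, 6 unconscious
patients (UWS with congruent hypometabolism), 12 MCS+ patients and 5
behaviourally unresponsive holdout subjects drawn from the conscious
parameter distribution.  Each subject's true couplings are the group effect
(default: -0.6 log-scaling on the backward mPFC->lLP coupling in the
unconscious group, zero elsewhere) plus independent N(0, 0.1^2) draws per
coupling, redrawn if unstable.  The observed CSD is the model prediction
corrupted by a complex-Wishart draw with 60 degrees of freedom — exactly
the sampling distribution of a 60-epoch average — with a slow path that
simulates 600 s of time series and applies Welch estimation instead; the
two paths agree in scale (tested).  Everything is reproducible from
(config, seed).

What the generator does **not** emulate: volume-conduction geometry and
channel counts of real high-density EEG (8 random channels vs 173
electrodes), artifacts, non-stationarity, inter-subject variability of
intrinsic physiology, or any PET/behavioural structure.  Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the stated statistical conditions, not clinical performance.

## Problem sizes and expected statistical behaviour

Analyses in the test-suite and acceptance script use the full default
frequency grid (117 bins) and cohort sizes; per-fit iteration caps of 24-32
with 300 refinement draws keep a subject inversion near 1.5 s, a 17-subject
cohort near 25 s, and the default 34-subject pipeline run in a few minutes.

An honest caveat on effect detection at these conditions: the Fisher
information a single 60-epoch, 8-channel spectrum carries about the reduced
backward coupling at its true value (-0.6, where the coupling itself is
e^-0.6 weaker) corresponds to a likelihood standard deviation of roughly
0.35-0.45.  With 6 vs 11 subjects the group-difference z-score is then
about 3-4, so the strict Pp > .99 inclusion criterion is met in most but
not all cohort realizations, single-connection classifiers reach balanced
accuracies around 0.8-1.0, and conscious-like holdout subjects are assigned
the conscious class with probabilities nearer 0.6-0.8 than 0.95.
Simulations with idealized, exactly calibrated subject posteriors at the
same noise level behave the same way, so this is the information content of
the design, not an estimator deficiency; real high-density recordings carry
considerably more spatial information.

## Degenerate inputs and tie-breaks

Strictly increasing frequency grids are required; cross-spectra must be
Hermitian within 1e-10 and PSD within -1e-10 (relative).  Wishart sampling
requires at least as many epochs as channels.  Exhaustive search refuses
more than 16 switchable parameters.  Ranking ties break toward the lower
canonical edge index; model-averaging weights are clipped to [0, 1] against
rounding.  Fits that never find an admissible ascent direction return the
prior-centred posterior flagged `converged=False`.
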