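# Methods

## Model

The package simulates systems consolidation — the gradual construction of
neocortical memory traces from hippocampal precursors — as a
teacher–student–notebook system.

**Teacher (environment).** A fixed shallow network generates P experiences
(x^μ, y^μ). Inputs have i.i.d. N(0, 1/N) components (N the teacher's input
dimension). For the linear noisy teacher, y = w̄·x + ε with w̄ componentwise
N(0, σ_w²) and ε ~ N(0, σ_ε²); the constraint σ_w² + σ_ε² = 1 yields
unit-variance outputs, so predictability is fully described by
SNR = σ_w²/σ_ε². Two further teachers make the same point about
unpredictability without explicit noise: a sine teacher y = c·sin(w̄·x)
(a linear learner cannot model the nonlinear part) and a partially observable
teacher (only n_observed of N input coordinates are visible; hidden
coordinates act as noise). `equivalent_snr` reduces any teacher to the
ratio of the best-linear-predictor variance to the residual variance,
estimated by ordinary least squares on a large Monte-Carlo sample
(n_mc = 1e5 by default; relative accuracy ~ a few percent, improving as
1/√n_mc). For the sine teacher the closed form from the Hermite expansion is
available: linearly modellable variance s²e^{−s²} and total variance
(1 − e^{−2s²})/2 for preactivation scale s; for the partially observable
teacher the expected value is n_observed/(N − n_observed).

A realized i.i.d. weight vector has ‖w̄‖²/N = σ_w²(1 ± √(2/N)), so the
*realized* SNR of one teacher fluctuates around the construction value.
Where an analysis targets the construction value exactly (unit-variance
checks, SNR-recovery grids, matched-teacher comparisons) the constructors
accept `fixed_norm=True`, which keeps the direction random but fixes the norm
to its expectation. i.i.d. draws remain the default.

**Student (neocortex).** A bias-free linear map ŷ = w·x, initialized at zero,
trained by batch gradient descent w ← w + learnrate·(ỸX̃ᵀ − wX̃X̃ᵀ) on replayed
batches. Memorization error is the MSE on the stored examples;
generalization error is the expected MSE on fresh teacher samples, including
the irreducible σ_ε² floor (test outputs carry noise), estimated on p_test
fresh examples (default 1000) or exactly via
E_g = (1/N)‖w − w̄‖² + σ_ε² for linear teachers.

**Notebook (hippocampus).** A sparse Hopfield network of M binary units.
Each experience is bound by one-shot Hebbian plasticity to a fresh random
index with exactly k = round(aM) active units (sparsity a): recurrent
weights accumulate (ξ−a)(ξ−a)ᵀ with zero diagonal; hetero-associative
weights bind (ξ−a) to the student activations. Retrieval runs nine
synchronous cycles of recurrent input followed by k-winners-take-all
(exact sparsity, ties broken by a fixed seeded 1e-12 perturbation, lowest
unit index last). Random sparse initial states settle into stored attractors
(offline replay); partial cues through the student→notebook weights
pattern-complete (cued recall). Readout through notebook→student weights is
scaled by 1/(aM(1−a)) so a perfectly retrieved index reproduces the stored
activations at unit gain; the centered hetero rule keeps Hebbian crosstalk
zero-mean with relative magnitude ≈ √(P·a(1−a)/k) (≈ 0.22 at P=100, M=2000,
shrinking as 1/√M).

**Consolidation.** All P examples are encoded once; each epoch a batch
(default 100 reactivations) is replayed and the student takes one gradient
step; epoch 0 is the pre-training state and trace arrays have length
epochs+1. Notebook errors are constants over the run (its weights do not
change during consolidation) and are computed once via cued recall. Three
replay modes exist: `hopfield` (full attractor dynamics), `resample`
(sampled stored pairs, bypassing the dynamics) and `full` (deterministic
full batch). Below capacity the modes yield statistically indistinguishable
student trajectories (a tested property), so long experiments default to the
deterministic modes.

**Regulation (Go-CLS).** Standard consolidation trains to the horizon;
generalization-optimized consolidation stops at the generalization-error
minimum. Implemented policies: oracle stop (argmin of the true error,
first minimum on ties); validation stop (seeded random held-out fraction of
the stored examples, global minimum of the validation MSE within the
horizon; a patience variant for streaming use); and two indirect paths that
first estimate predictability — grid maximum likelihood under the marginal
Gaussian y|X ~ N(0, σ_w²XᵀX + σ_ε²I) (grid: 41 log-spaced points over
2^−8..2^8 plus {0, ∞}; one eigendecomposition reused across the grid;
1e-12 jitter guards singular covariances), and an initial-learning-speed
heuristic — then convert the estimate into a stopping epoch by the oracle
stop of a matched deterministic simulation. "Initial learning speed" is
operationalized as the relative training-error drop over the first 5
full-batch epochs at a fixed probe rate (0.02); the speed→SNR map is a
monotone interpolation of a simulated calibration curve at matched (P, N),
clamped with a warning outside the calibrated range.

**Scores and lesions.** Errors translate to behavioral scores by
score = (E₀ − E_t)/E₀ with E₀ the zero-weight student's error (chance).
The combined system uses whichever module has the lower error. A notebook
lesion at time t removes the notebook from selection and freezes the student
(consolidation requires replay), so post-lesion performance is the student's
at min(t, stop epoch). Amnesia curves sweep the lesion time over a grid
(default 20 points across the horizon, tested immediately after the lesion)
with same-seed intact controls; deficits are paired differences. Curves are
classified as `none` (max deficit < 0.05), `flat` (deficit range/mean <
0.25) or `graded` — thresholds are configurable, since the source
classification is visual. Prior consolidation is modeled by pretraining the
student on an independent example set from the same teacher before the
tested experiences are encoded (schema-consistent prior experience).

## Converged students

"Trained to convergence" quantities use the exact fixed point of full-batch
gradient descent from zero initialization — the minimum-norm least-squares
solution — computed directly. Near α = 1 the smallest Gram eigenvalue is
~1e-5 and literal iteration would need millions of epochs; the iterative
route (`train_to_convergence`, step 1.9/λ_max, stall tolerance 1e-13) is
verified against the pseudoinverse to 1e-6 in the tests. Oracle-stopped
errors take the minimum over a finite-horizon trajectory *and* the converged
limit, so early stopping can never appear worse than convergence by horizon
truncation alone.

## Baselines

The student-only baseline is single-pass SGD with a per-step risk-optimal
learning-rate schedule. For the linear-Gaussian stream the expected risk
obeys r_{t+1} = r_t(1 − 2η/N + η²(N+2)/N²) + η²σ_ε² with E_g = r/N + σ_ε²;
the greedy η*_t = (r_t/N)/((N+2)r_t/N² + σ_ε²) is globally optimal because
the risk is a monotone scalar recursion. The α-sweep evaluates this
recursion (deterministic); simulated SGD is available and agrees with it in
tests. The notebook-only baseline in sweeps is brute-force 1-nearest-neighbor
regression, the idealized limit of cued recall; the Hopfield pathway is
shown equivalent to it at P=100 separately.

## Synthetic data and what passing tests show

There is no external data: the generative teachers *are* the study
conditions (N=100 students; P=100 examples; M=2000–5000 notebooks with
a=0.05; learning rates 0.005–0.015; horizons 500–5000 epochs; P_test=1000;
amnesia SNRs 0.01–8 plus a prior-consolidation condition at SNR 50). The
generator emulates exchangeable, stationary, zero-mean Gaussian experience
with homoscedastic unpredictability. It does not emulate temporal
correlation between experiences, non-Gaussian or structured inputs,
multi-output relationships, or drifting environments — conclusions about
real episodic content rest on the theory's reading of SNR, not on these
simulations. Some checks scale sizes for runtime (M=2000 instead of 5000 in
amnesia tests; 50 000-epoch horizons only where late-time behavior is the
claim); scaled runs were verified to preserve the qualitative regime.

## Numerical choices and known limitations

- k-WTA enforces exact sparsity without a hand-tuned threshold; the
  covariance recurrent rule plus k-WTA is this package's stand-in for the
  unspecified original Hebbian normalization, validated against the
  qualitative retrieval claims (fixed points below capacity, ≥95% perfect
  recalls, pattern completion from 10%-corrupted cues).
- Attractor basin sizes under this rule vary by ≈20% (relative SD) at
  M=2000, P=100, shrinking roughly as 1/M. Retrieval is therefore *near*
  uniform (each memory ≈ 1% ± 0.2% of draws) but fails a literal chi-square
  uniformity test at 1e4 draws; a strict pass would need M ≈ 20 000.
- Hebbian readout crosstalk (≈ √(P·a(1−a)/k)) bounds recall precision;
  notebook memory error ≈ 0.05 at P=100, M=2000 on the unit output scale.
- Nearest-neighbor generalization error in high dimension sits near
  2·Var(y) (predictions are uncorrelated with targets), i.e. a
  generalization score near −1: the curse of dimensionality makes the
  notebook pathway worse than chance for fresh inputs, not merely chance.
- The batch/online comparison is asymptotic: at SNR=1000, N=100 the two
  systems' errors agree within 10% only for α ≳ 10, though both are already
  ~1e-3 on the unit scale at α = 8.
- Divergent runs (training error > 1e6) abort with a diagnostic rather than
  returning traces.
- The sine teacher's preactivation scale is exposed as a parameter
  (`sine_scale_for_snr` inverts the closed form); its output is normalized
  to unit variance by default so matched-teacher comparisons share the
  chance-level error.
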