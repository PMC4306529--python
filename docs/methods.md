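# Methods

## Generative model

### Neural mass dynamics

Each source is a canonical microcircuit of four populations — input cells
(`ss`), superficial pyramidal cells (`sp`), inhibitory interneurons (`ii`) and
deep pyramidal cells (`dp`).  Population `p` has mean depolarisation `v_p`
(mV) filtered through a second-order synaptic kernel with rate constant
`κ_p` (Hz):

    dv_p/dt = x_p
    dx_p/dt = κ_p u_p − 2 κ_p x_p − κ_p² v_p

`u_p` sums signed connection strengths (Hz) times the sigmoid-transformed,
*delayed* presynaptic depolarisation, `S(v) = 1/(1+exp(−γ v)) − ½`.  The
centred sigmoid makes the origin a fixed point of the unforced system, which
is also the expansion point for the spectral linearisation.  Intrinsic
couplings are delayed by τ_i (prior 1 ms), extrinsic ones by τ_e (prior
8 ms).  The intrinsic wiring (10 signed edges per source) and the laminar
targets of extrinsic connections live in one editable table
(`synaptrack.priors`); forward connections originate in `sp` and excite `ss`
and `dp` of the target source, backward connections originate in `dp`, excite
`ii`, and inhibit `sp` (a net effect standing in for unmodelled interneuron
relays — the circuit deliberately trades Dale-compliance for parsimony).
Endogenous fluctuations drive the input cells only; the measured signal is
the superficial-pyramidal depolarisation times an electrode gain.

Two sources are coupled reciprocally.  The `forward` architecture sends a
forward-type connection from the primary source to the secondary and a
backward-type connection in return; the `backward` architecture is the mirror
image.

### Log-scaling parameterisation and priors

Every parameter is `prior_mean × exp(θ)` with a Gaussian prior on θ; zero
prior variance fixes a parameter.  Defaults (configurable through
`PriorSpec` YAML):

| parameter | prior mean | var(θ) |
|---|---|---|
| intrinsic edge rates | [800, 800, 1600, 800, 800, 400, 800, 800, 400, 200] Hz | 1/8 on the `sp` self-inhibition; other edges fixed |
| extrinsic strengths (fw, bw) | 200 Hz | 1/8 |
| rate constants κ (ss, sp, ii, dp) | 500, 500, 62.5, 35.7 Hz | 1/16 |
| sigmoid slope γ | 2/3 | 1/32 |
| delays τ_i, τ_e | 1 ms, 8 ms | 1/32 |
| input amplitude / exponent | 1, 1 | 1/128 |
| noise amplitude / exponent | 1, 1 | 1/128 |
| electrode gain | 4000 per channel | 1/8 |

Only the superficial-pyramidal self-inhibition gain is free among the
intrinsic edges: it is the tracked "intrinsic coupling", and freeing all ten
edges per source is neither identifiable from two-channel spectra nor needed
for the hypotheses the model space encodes.  The electrode gain's magnitude
is a unit conversion (depolarisation in mV to recording units) chosen so that
at prior means the neuronal CSD term stands an order of magnitude above the
measurement-noise floor in band, as in intracranial recordings, while the
endogenous drive stays small enough that the nonlinear simulation remains in
the sigmoid's linear regime.

### Spectral forward model

Linearisation about the fixed point gives a delay state-space system; delays
enter the frequency domain as exact phase factors,
`A(f) = A0 + Ai e^{−i2πf τ_i} + Ae e^{−i2πf τ_e}`, and

    T(f) = C (i2πf I − A(f))⁻¹ B
    G_y(f) = T(f) G_u(f) T(f)ᴴ + G_n(f)

`G_u` is a per-source power-law spectrum `a_u f^{−α_u}` (independent drives
by default; a shared component is a config option), `G_n` has a common-mode
power-law term (scale 1/16) plus a channel-specific term (half the common
scale).  Sources map one-to-one to (bipolar) channels with a diagonal gain.
The analysis grid is 1-Hz bins over 8–48 Hz (41 bins).  Stability is policed
via the zero-frequency system matrix (all eigenvalue real parts negative);
unstable parameter sets raise rather than return garbage.

The time-domain integrator (`neural_mass.integrate`, fixed-step Heun with a
ring buffer and linear interpolation for delayed states, dt = 0.5 ms) is not
used in estimation; it is the independent oracle that validates the transfer
functions: band-integrated Welch spectra of a 120-s simulation agree with the
predicted auto-spectra to well under 10%.

## Windowed data and features

Raw recordings are re-referenced to bipolar derivations, band-passed
0.5–48 Hz with a 4th-order zero-phase Butterworth, and cut into 2-s windows
with 50% overlap — nine windows per 10-s segment before and after the marked
onset, 18 in total.  Per-window CSDs come from an order-8 VAR fit (default)
or a DPSS multitaper cross-periodogram; the estimator and its settings are
recorded in the container metadata.  Each window×frequency CSD matrix is
embedded losslessly in real features: real upper triangle including the
diagonal plus imaginary strict upper triangle (4 numbers per 2×2 matrix;
18×41×4 = 2952 features for the canonical design).

## Slow trajectories and the model space

Flagged couplings deviate per window by `B w`, where `B` is an orthonormal
polynomial basis (order 3) built independently per segment, allowing a jump
at onset — trajectories around seizure onset are discontinuous there, and
per-segment bases keep coefficients identifiable.  The four flags (intrinsic
primary, intrinsic secondary, forward, backward) give 16 change-models;
together with the two architectures this is the hypothesis space.  Drift
coefficients have Gaussian priors with variance 4 (sd 2 per orthonormal
column): weakly informative for excursions of a few log units, the scale of
empirically reported peri-onset changes.  With a per-segment constant column
and a free static log-scaling the total level is deliberately
over-parameterised; the prior renders the posterior proper and the *summed*
trajectory (static + drift) that the package reports is identified.

## Inversion

Variational Laplace with a Gaussian posterior `q = N(μ, Σ)`:

* Gauss–Newton ascent on `F = ⟨log p(y|θ)⟩_q − KL(q‖p) − penalty(λ)` with
  adaptive Levenberg–Marquardt damping; steps are accepted only if F
  increases, so the recorded F trace is non-decreasing.  Rejection after a
  full backtracking sweep under a fresh linearisation is treated as a
  plateau (convergence); "non-convergence" is reserved for runs still
  climbing at the iteration cap.  Non-convergent models are excluded from
  comparison rather than patched.
* Convergence: ΔF < 0.01 nats on 4 consecutive iterations, max 64.
* Gradients: central finite differences, step 1e-3 in log-scaling space.
  Per-window transfer functions are cached against the window's neuronal
  parameters, so perturbing drift coefficients or observation parameters
  reuses unaffected linearisations.
* Observation noise: features are scaled to unit RMS, then modelled with
  band-wise log-precisions λ_b (4 contiguous frequency bands), Gaussian
  hyperprior N(2, 4), updated by Newton steps started from the closed-form
  optimum and treated as MAP within F.
* Frequency correlation: sampling error of spectral estimates is smooth
  across neighbouring bins, so the likelihood assumes an AR(1) correlation
  (coefficient 0.8) along the frequency axis and whitens data and
  predictions with the corresponding innovations transform.  This is a fixed
  linear map, identical for every candidate model, so evidence differences
  remain valid; without it, smooth noise masquerades as structure and model
  comparison rewards superfluous parameters.
* Initialisation at the prior means; no random restarts (deterministic
  inversions).

For linear-Gaussian problems with fixed noise the scheme reproduces the
conjugate posterior and the exact log evidence to 1e-6 (tested), and
sequential inversion with the first half's posterior as the second half's
prior equals the joint inversion.

## Model comparison, updating, trajectories

Evidence is the converged F.  Pooling over sessions is fixed effects (sum of
log evidences); posterior model probabilities are softmax of pooled F over
the models with complete, finite evidence.  Between sessions, static
parameters are carried — prior log-means/variances set from the posterior
with the joint covariance sub-block retained — while electrode gains and
drift coefficients reset to their original priors (gains can change between
sessions; drifts are session-specific by definition).  Trajectories are the
linear map of the posterior through the basis (static column + `B`), with
Gaussian 90% bands (±1.645 sd) from the full covariance.

## Synthetic face validation

The canonical generator mirrors the validation design: 18 windows of
two-channel CSD over 8–48 Hz; all couplings at prior expectations pre-onset;
after onset the forward strength (+1 log unit) decays back with τ = 2 s and
both superficial-pyramidal self-inhibition gains (+2 log units) with τ = 8 s;
SNR 4.  Noise is Hermitian, AR(1)-smooth across frequency (coefficient 0.8),
drawn once as a pool and assigned to windows by permutation, then scaled so
RMS(signal)/RMS(noise) per channel and window equals the requested SNR
exactly.  SNR is an RMS amplitude ratio — the convention is recorded in the
dataset manifest.  Additive residual-style noise can push a near-zero
auto-spectrum slightly negative at band edges; the real-embedded likelihood
is indifferent to this, but it is why noisy data are only required to be
Hermitian with real diagonal, not positive.

Because the generator and the inversion share the forward model, passing
face validation demonstrates identifiability and correctness of the
machinery under realistic sampling noise — not robustness to model mismatch.
Features of real data that the generator does not emulate include
non-stationarity within windows, artefacts, line noise, volume conduction
between derivations, and deviations of true circuitry from the
canonical microcircuit.

Problem sizes were chosen to keep a full face-validation run at a few
seconds per inversion: 2 sources, 2 channels, 41 frequency bins, 18 windows,
~40 free parameters.  The model-recovery study pools three synthetic
sessions, mirroring evidence pooling over three seizures.

## Known limitations

* Gradients are finite differences; analytic gradients would cut inversion
  time several-fold.
* The λ update is MAP, not a full variational step; F omits the λ entropy.
* Bayesian updating carries only the static-parameter covariance block;
  cross-covariances with drift coefficients are dropped.
* Two sources only are wired; the architecture generalises but is not
  exercised.
* The AR(1) whitening coefficient is assumed, not estimated; real residual
  correlation structure will differ.
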