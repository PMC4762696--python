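# Methods

## Representation model

An ensemble of *N* leaky integrate-and-fire (LIF) neurons represents an
*m*-dimensional value **x**. Neuron *i* receives the current
*J_i* = *α_i* (**e**_i · **x** / *r*) + *J*<sub>bias,*i*</sub>, where **e**_i
is a unit encoder drawn uniformly from the sphere (a random sign for
*m* = 1), *r* is the representational radius, and the gain/bias pair is
solved so that the neuron is silent at its intercept and fires at its
sampled maximum rate when **e**_i · **x** = *r*. The steady-state rate is

G[J] = 1 / (τ_ref − τ_RC ln(1 − J_thr/J)) for J > J_thr, else 0,

with the threshold normalized to J_thr = 1; all per-neuron heterogeneity is
carried by (α, J_bias). Defaults: τ_ref = 2 ms, τ_RC = 20 ms, maximum rates
uniform in 200–400 Hz, intercepts uniform in (−1, 1). The rate range and
neuron constants follow common cortical-scale modelling practice; the
intercept distribution is not dictated by the model and is exposed as a
parameter (`LIFParams`).

Decoders minimize the squared reconstruction error over *Q* evaluation
points drawn uniformly from the **solid** *m*-ball of radius *r* (surface
sampling would leave the interior unconstrained), solving
(A Aᵀ + Q γ² max(A)² I) d = A X with γ = 0.1 by default and max(A) the
largest matrix element. Q defaults to max{2Nm, min{max{500m, 750}, 2500}}.

Radius convention: the input is divided by *r* before encoding and decoders
are solved against targets in original units. Consequently the decoded
estimate of *r*·**x** at radius *r* equals *r* times the estimate of **x**
at radius 1 with the same seed (tested exactly), and the inside-radius
distortion obeys E_{x≤r}(r) = r² E₁ where E₁ is the unit-radius distortion.
This single-solve scaling is what makes the radius optimization cheap.

## Subvector length distributions

A *D*-dimensional vector of i.i.d. N(0, σ²) components has a scaled-chi
length density k_D x^{D−1} exp(−x²/2σ²) (half-normal at D = 1, Rayleigh at
D = 2); the normalizing constant is kept in log space so densities remain
evaluable at D = 512 and beyond. Normalizing such a vector to unit length
and keeping *m* of its *D* components gives a subvector whose length has the
square-root-beta density

p_SB(x; n, m) = (2 / B(n/2, m/2)) x^{m−1} (1 − x²)^{n/2−1}, n = D − m,

on [0, 1]; x² is Beta(m/2, n/2). The CDF is evaluated through the
regularized incomplete beta function (numerically stable at large n);
adaptive quadrature of the PDF is retained only as a test oracle. Sampling
uses the generative construction (normalize a Gaussian vector, take the
subvector norm) rather than inverse-CDF — it is the definition, and exact.

## The distortion model and its minimization

Two radius-dependent static error sources are modelled (spiking noise is
independent of *r* and excluded):

* inside the radius: E_{x≤r}(r) = r² E₁, with E₁ estimated once as the mean
  squared residual of the unit-radius decode on its own evaluation points;
* outside the radius: values of length y > r are modelled as projected onto
  the radius-r sphere, E_{x>r}(r) = E[(y − r)² | y > r] under the
  square-root-beta law, evaluated by adaptive quadrature with an
  incomplete-beta closed form as an independent cross-check.

Weighting by the probability of each regime gives
E(r) = r² E₁ F_SB(r) + E_{x>r}(r)(1 − F_SB(r)). The curve is unimodal over
(0, 1] in all tested configurations; bounded scalar minimization (bounds
(10⁻³, 1], tolerance 10⁻⁴ on r, with r ≤ 1 because subvectors of unit
pointers cannot be longer than 1) agrees with a dense grid search to the
grid resolution. For D = m the length distribution degenerates to a point
mass at 1 and the optimum is r = 1 by construction.

The hard-projection assumption overestimates the error at radii well below
the optimum, because LIF saturation beyond the radius is soft; this bias is
asserted as a property test and visible in the validation curve. Validated
against rate-mode simulation (N = 200, D = 64, m = 1), the model tracks the
measured distortion with a mean deviation on the 10⁻³ scale.

The neuron-reduction heuristic converts a measured RMSE reduction factor *f*
into N → max(floor, round(N/f²)) (round-half-to-even), justified by the 1/N
scaling of the decoded spiking mean squared error. Note the *static*
distortion alone falls faster than 1/N in our measurements (between 1/N and
1/N²); the heuristic rests on the noise-dominated decoded error, and the
package tests the 1/N law on that quantity. The floor defaults to 1, and to
5 neurons per dimension in the dot-product benchmark where very small
ensembles introduce error sources outside the model.

## Semantic-pointer algebra

Binding is circular convolution u_i = Σ_j v_j w_{(i−j) mod D} with 0-based
circular indexing, making e₀ = (1, 0, …, 0) the identity; unbinding
convolves with the involution (w₁, w_D, …, w₂). Both an O(D²) direct sum
and an FFT path are implemented and agree to 10⁻¹⁰. Unitary pointers are
generated by assigning unit magnitude and random phase to every free
Fourier bin (random signs for the real-only bins); conjugate symmetry makes
the result real and exactly unit-norm, binding with it preserves norms, and
unbinding under it is exact.

## Benchmark circuits

All three circuits compile to feedforward stacks of scalar LIF ensembles
with an affine input map, per-ensemble decoded functions, and a linear
output map, so every linear transform lives in connection weights and only
representation and scalar squaring are neural.

* **Representation**: D single-dimension ensembles; default radius 1,
  optimized radius from the distortion model for (N, D, m = 1).
* **Binding (circular convolution)**: the DFT of the variable operand is
  applied in the input weights using a real-valued packing (solo bins for
  k = 0 and k = D/2, real/imaginary pairs elsewhere). The second operand is
  fixed to a unitary pointer and enters as a constant offset. Each required
  scalar product x·b is computed by a parabolic multiplier — two channels
  (x ± b)/2 whose ensembles decode squares, recombined as
  ((x+b)² − (x−b)²)/4 in the output weights together with the complex
  recombination and the inverse transform. Default mode mirrors the common
  simulator convention: forward scale 1, inverse scale 1/D, channel radius
  2. Optimized mode uses the orthogonal (1/√D-weighted) packing so the
  coefficient vector of a unit pointer is itself unit length — its
  components then follow the m = 1 square-root-beta law — and sets each
  channel radius to (r_opt + |b|)/2, which exactly covers the channel's
  range. With ideal squares the circuit reproduces the algebraic binding to
  machine precision (tested), so all measured error is neural.
* **Dot product**: D parabolic multipliers against a fixed unit operand,
  their decoded products summed linearly into a single scalar sum ensemble.
  Default radii are 1 everywhere. Optimized mode sets multiplier channel
  radii to (r_opt + |w_d|)/2 and the sum-ensemble radius to r_opt: the dot
  product of a random unit vector with a fixed one is a coordinate of a
  unit vector in a rotated basis, hence follows the same m = 1
  square-root-beta law as the multiplier inputs. Keeping the sum radius at
  1 instead floors the optimized error near the sum ensemble's own noise
  and caps the achievable improvement around 3×.

Simulation runs at dt = 1 ms. Rate mode evaluates G[J] directly (no spiking
noise). Spiking mode integrates the membrane exactly toward J over the
non-refractory fraction of each step, estimates threshold-crossing times
within the step, resets to zero and clamps the refractory window; measured
steady rates match the analytic curve to well under 1% for 200–400 Hz.
Initial voltages are uniform in [0, 1) to desynchronize onset. dt must be
smaller than τ_ref. Decoded outputs of each neuron layer pass through an
exponential synapse (τ = 5 ms by default — a typical decoded-connection
setting, exposed as a parameter); the ideal reference passes through the
identical filter cascade, which removes synaptic-delay bias without ad-hoc
shifting.

## Stimulus and error protocol

The driving stimulus is band-limited white noise: per-component Gaussian
noise low-pass filtered by a 501-tap windowed-sinc FIR at 5 Hz (order and
cutoff exposed), generated with padding so filter edges never reach the
returned window, then normalized to unit length at every step. Adjacent
1 ms steps correlate above 0.99 and stop-band power is ≥ 20 dB below the
pass band (both tested). Generation is bit-exact per seed.

Errors are per-step Euclidean distances between decoded and
reference outputs, pooled across trials after discarding an initial 0.5 s
transient; the reduction factor is the ratio of pooled RMSEs
(default / optimized). The dot-product experiment pairs the time-varying
unit signal with a fixed random unit operand, mirroring the binding
protocol, since only the binding operands are prescribed.

## Problem sizes

The full protocol uses 20 trials of 10 s per condition. The shipped tests
and the acceptance script use 5 trials of 4 s, a 10-point radius grid for
model validation, circuit dimensionalities D ∈ {16, 64} (binding at
D = 16), and 50 neurons per dimension — sizes chosen so the complete
validation runs in minutes on one CPU while keeping the reduction-factor
estimates stable to within a few percent. The improvement grows with D (the
component-length distribution tightens as 1/√D), so the headline reduction
factors are reported at the largest tested dimensionality, D = 64; the
per-D factors at D = 16 are roughly 1.5× (representation) and 2.5–3×
(dot product).

## What the synthetic stimulus does and does not show

The band-limited unit-norm trajectory matches the benchmark protocol, but
real cognitive models drive ensembles with structured, task-dependent
pointer sequences: discrete switches, superpositions of a few items, and
feedback loops. Passing benchmarks here demonstrates the radius-distortion
trade-off and its optimization under the stated stationary input statistics;
it does not by itself establish gains for recurrent memories, fixed-point
hardware, or inputs whose length distribution departs from the
square-root-beta law (e.g. unnormalized sums of many pointers). The error
measure is L2 throughout; other norms would trade the many-small-errors /
few-large-errors balance differently.

## Known limitations

* Only LIF neurons (rate and spiking) are implemented; no adaptive or
  hardware-constrained neuron models.
* No recurrent dynamics; all circuits are feedforward.
* The distortion model ignores spiking noise by design; it predicts static
  distortion, while experiment RMSEs include noise. The two agree in rate
  mode only.
* The binding circuit fixes one operand; a fully neural two-operand binding
  would double the product ensembles and add a second source of
  coefficient error.
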