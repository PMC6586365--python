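# Methods

## The model

All networks in this package share one architecture. A population of
N leaky integrate-and-fire (LIF) neurons, membrane dynamics

    tau_m dV_j/dt = (V_leak - V_j) + R_m I_j,

fires spikes that are filtered by an exponential synaptic kernel
H(t) = exp(-t / tau_syn) into traces u(t). D latent variables are read
out linearly, x(t) = Phi u(t), and fed back as input currents
I_fb = K x(t). Because both steps are linear, the loop collapses into
one synaptic matrix W = K Phi of rank at most D: the columns of the
encoder matrix K simultaneously set the feedback weights and the
*intrinsic manifold* — the plane in N-dimensional rate space that the
activity occupies. With an integrator loop the network is a
D-dimensional line attractor: values written into the latents persist.

Three frameworks provide the decoders Phi:

* **FORCE** — a chaotic echo-state reservoir (sparse random weights
  Omega, entries Normal(0, G^2 / (p N)) with p = 0.1, G = 10, rows
  balanced to zero mean) plus the feedback loop. Phi is learned online
  by recursive least squares (RLS) while the network runs: the helper
  matrix P tracks the inverse correlation of u, with P(0) = 5e-6 I,
  Phi(0) = 0, and updates every 0.5 ms of simulated time. Normalized
  units R_m = 1, V_th = 0, V_reset = -1, V_leak = 0 put the rheobase
  at exactly zero current, so the reservoir is tonically active.
  tau_m = 10 ms, tau_syn = 20 ms, t_ref = 2 ms. Encoders: entries
  uniform on [-100, 100].
* **Batch decoders (NEF)** — each neuron has a unit-norm preferred
  direction k_j, a maximal rate drawn from [80, 120] Hz and an
  intercept from [-1, 1); gain and bias follow from the closed-form
  LIF rate curve. Phi minimizes the squared decoding error of 2000
  uniform evaluation points in [-1, 1]^D with ridge regularization
  (0.01 x max activity). tau_m = 20 ms, tau_syn = 10 ms, dt = 1 ms.
* **Efficient coding (EC)** — no learning. Phi = lambda K^T with
  lambda = 1/tau_syn, slow recurrent weights W = lambda K K^T, fast
  (instantaneous) weights Omega = -K K^T - mu lambda^2 I, per-neuron
  thresholds (nu lambda + mu lambda^2 + ||k_j||^2) / 2 with
  nu = 1e-3, mu = 1e-6, tau_syn = 20 ms. Spikes greedily keep the
  decoded latents near the coded signal; the inhibitory autapse
  replaces the reset.

## Perturbations

An inside-manifold perturbation replaces K by K Q with Q a D x D
matrix; for orthogonal Q (latent permutations, rotations) the spanned
manifold and, in the ideal rank-D case, the weights W = K Q Q^T Phi^T
are unchanged. An outside-manifold perturbation permutes rows of K
(block swap of the two network halves, or 4-block permutations for
D = 4), which moves the modes out of the original subspace; the
relearned weights then decorrelate from the originals as completely
as with freshly drawn encoders. Relearning always re-runs the full
framework procedure with the original targets and hyperparameters and
a fresh learning-phase seed; comparisons use Pearson correlation over
all N^2 entries of the feedback component W only (the static
reservoir, and for EC the fast weights, are excluded) plus the
Frobenius norm of the difference.

For EC the Frobenius comparison of *non-orthogonal* inside
perturbations is not meaningful as an ordering: W~ = lambda K Q Q^T
K^T scales with ||Q Q^T||, which is unbounded for Gaussian or
rank-one Q, even though the element-wise correlation stays high.

## The sign-constrained (Daleian) network

To obtain a biologically plausible W the factorization is abandoned
and W itself is optimized row by row under a fixed constraint matrix
C in {-1, 0, +1}: entries with C = 0 are absent (sparsity xi = 0.75),
columns of the first eps N = 0.8 N neurons must be non-negative
(excitatory), the rest non-positive (inhibitory). Each row solves a
non-negative least squares problem (inhibitory columns negated,
masked columns dropped) against the current the neuron needs for the
latents to follow the 4-D double oscillator (2 Hz and 4 Hz pairs,
radial term alpha (1 - r^2) with alpha = 0.2 attracting amplitude 1)
through the exponential synapse: gain_j k_j . (x + tau_syn f(x)).
Because all rows share the design matrix, the package solves the
Gram-reduced problem (Cholesky of A'A, then NNLS on the triangular
factor), which is exact and ~20x faster than per-row dense NNLS.

## Numerical choices

* **Integration** — exponential-Euler for the membrane (exact for the
  linear part), spike test once per step, spike times on the grid,
  refractory clamp in whole steps. Bins are left-closed, the trailing
  partial bin dropped.
* **EC voltage** — in the exact derivation of this network class,
  V_j = k_j . (x - x_hat), whose dynamics already contain the decay
  the membrane leak would provide; the leak is cancelled by a matching
  V-proportional term of the derived current. The simulation therefore
  integrates the slow/external currents without an extra leak; with
  the leak left in, the retained latents decay to zero within about a
  second instead of persisting. Voltages start at 0 (the error is zero
  at t = 0); fast synapses are applied one spike at a time, largest
  threshold overshoot first, before re-testing within the step.
* **EC encoders** — the row distribution is a free parameter. Entries
  are i.i.d. Normal(0, 0.025^2): with the x100 latent convention this
  makes the per-spike decode step lambda ||k_j|| about 2% of the
  signal scale and yields sparse (~1.5 Hz) firing that retains clamped
  values to a few percent while still leaving enough spikes in 2.5 s
  to identify the modes. Unit-norm rows at the dead-zone-optimal norm
  sqrt(nu lambda + mu lambda^2) retain slightly better but fire so
  sparsely that mode identification is shot-noise limited.
* **Discrete-time rate bias** — a grid simulator quantizes interspike
  intervals to whole steps, losing ~r dt of each neuron's rate. At
  dt = 1 ms this is a 5-10% loop-gain deficit, enough to damp the
  recurrently implemented oscillators; the sign-constrained network is
  therefore simulated at dt = 0.1 ms with the exact discrete rate
  normalization (1 - e^{-dt/tau}) / dt.
* **Loop phase calibration** — the spiking loop turns over 15-20%
  faster than the ideal exponential-synapse model predicts. The
  constrained solve compensates by evaluating the latent field 3.5 ms
  back along its own flow (`PHASE_COMP_S`); calibrated once on the
  unperturbed network, it restores 2.0-2.15 / 4.1-4.3 Hz oscillations
  at amplitude ~1 in closed loop.
* **FORCE training schedule** — the feedback ramps linearly from the
  target signal (open loop) to the decoded latents over the first 40%
  of the learning phase; most of learning is then fully closed-loop.
  Evaluation replays the trained hold values (retention of unseen
  values is not part of the protocol).
* **PCA/FA** — binned counts are centered per neuron, never variance
  scaled; factor analysis uses exactly D factors (tolerance 1e-3, max
  1000 iterations). Principal-angle cosines clip singular values to
  [0, 1] before arccos.

## Problem sizes

The `desk` profile targets single-CPU minutes: FORCE at N = 300
(dt = 0.1 ms, 25 s of training) for mode identification and N = 200
(15 s) for the perturbation sweep; the batch-decoder and EC networks
at the published N = 1000; the sign-constrained network at N = 500
with 4000 evaluation points. The `full` profile restores N = 1000
FORCE at dt = 0.05 ms with 50 s training and the N = 5000 / 40,000-
point constrained solve (hours on one CPU); the published connection
probabilities (10.8% / 19.0%) and log-weight kurtosis (4.56) are
full-profile quantities — at desk scale they come out near 7.7% /
17.0% and 4.6.

## What the synthetic protocol does and does not show

The fixation protocol (fresh uniform values clamped for 100 ms every
500 ms, 2.5 s total) emulates writing variables into a working-memory
circuit through exaggeratedly strong inputs; real circuits receive
weaker, structured input and their latents evolve under both local
dynamics and drive. Passing tests show that the implemented loops
retain, oscillate and rewire as the theory predicts under this
idealized drive; they do not show anything about learning *rates* (the
decoders, not W, are what the rules adapt, and Phi before/after a
perturbation is essentially uncorrelated), nor about networks whose
activity is low-dimensional for other reasons (clustering, structured
input).

## Known limitations

* At desk scale the double-oscillator attractor is only transiently
  stable against representation error: the latent-readout experiment
  primes the state on the cycle and reads frequencies from a 2.5 s
  window. Self-ignition from x(0) = 0, as in the full-scale network,
  is not reproduced at N = 500.
* The batch-decoder network identifies its modes more cleanly than
  the reference implementation appears to: the cosine between the
  encoder subspace and the top-2 principal components comes out
  0.75-0.92 across instantiations (mean ~0.8) rather than ~0.7.
  Uncentered SVD of the count matrix — which lets the all-positive
  mean-count direction into the leading components — yields 0.61-0.69
  and would explain a framework-independent value near 0.7; the
  package keeps properly centered PCA.
* Conductance synapses, heterogeneous synaptic time constants and
  online learning variants of the batch frameworks are out of scope.
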