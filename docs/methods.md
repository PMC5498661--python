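# Methods

This note documents the models and procedures implemented in `hopfnet`,
the assumptions behind them, the tunable parameters and their defaults,
and the choices made where the design was genuinely open.

## The scientific setting

The package compares two vigilance states — wakeful rest and slow-wave
(N3) sleep — on ROI-level BOLD recordings, and interprets the differences
mechanistically with a whole-brain model of coupled nonlinear
oscillators.  The empirical design it targets is a paired cohort: each of
18 subjects contributes one awake and one sleep recording of 90 AAL
regions, 1505 volumes at TR = 2.08 s.  Because such clinical recordings
are not redistributable, the package ships a synthetic-cohort generator
(below) that reproduces the statistical structure the analysis assumes;
all tests and the reproduction script run on synthetic cohorts.

## Narrowband preprocessing

Analyses operate on the 0.04–0.07 Hz band, where slow BOLD fluctuations
are most reliable and where instantaneous phases are well defined.  Each
ROI signal is linearly detrended, band-pass filtered with a 6-pole
Butterworth filter applied forward–backward, and z-scored (population
SD).  Choices:

* **Zero-phase filtering.** Phases enter the synchrony analysis; any
  group delay would bias them, so `sosfiltfilt` is used (the effective
  attenuation is the squared magnitude response).
* **Filter order.** "Sixth order" is read as six poles for the band-pass
  (scipy prototype order 3).
* **Edge handling.** Filter and Hilbert transients decay over roughly one
  period of the slowest band component; `edge_trim_samples` =
  ceil(1/(low·TR)) samples (13 at defaults) are discarded at each end
  before phase-based statistics.  FC uses the full recording.

## Connectivity and synchrony metrics

FC is the Pearson correlation matrix over the whole recording (no
windowing).  Group FC is the Fisher average: atanh → mean over subjects →
tanh, diagonal forced to 1.  Summary statistics (mean/SD of FC) use the
strictly-upper triangle; the diagonal is excluded.

Global phase locking is the Kuramoto order parameter
R(t) = |mean_k exp(i φ_k(t))| with φ_k the Hilbert phase of node k.
**Synchrony** is the temporal mean of R, **metastability** its temporal
SD; group values average these over subjects.  SDs are population SDs
(divide by T): the quantities describe a realised series rather than
estimate an ensemble parameter; at T ≈ 1500 the distinction is
immaterial but has to be fixed for reproducibility.

## Surrogates and permutation inference

The design is paired, so nulls are built by flipping each subject's two
state labels with probability 1/2 — group sizes and within-subject
pairing are preserved exactly, while any systematic state difference is
destroyed.  P-values use the inclusive (add-one) convention
p = (1 + #extreme)/(1 + n_surrogates), whose floor with the default 100
surrogates is 1/101 ≈ 0.0099.  Sidedness defaults to one-sided in the
direction of the observed statistic, with two-sided available; each
reported test records its choice.  No multiple-testing correction is
applied.

## Gaussian state classifier

Since recordings are z-scored, each state is summarised by its spatial
covariance Σ, fitted from the time-wise concatenation of the training
subjects' recordings.  A held-out recording X (N×T, time points treated
as independent) is scored by the zero-mean multivariate normal
log-likelihood, computed through a Cholesky factorisation (log-det plus
linear solves; the raw determinant is never formed):

    L(X|Σ) = −T/2 (N log 2π + log det Σ) − ½ Σ_t X_tᵀ Σ⁻¹ X_t.

The proper (2π)^(−N/2) normalisation is used.  Cross-validation is
jackknife (leave one subject out); each of the held-out subject's two
recordings is assigned to the state with the larger likelihood, exact
ties going to the second state in sorted label order (sleep, for
awake/sleep labels) and being counted in the report.  If a training
covariance is not positive definite, a minimal ridge (|λ_min| + 1e−10
relative) is added and logged.  Chance level for n binary tests is the
smallest k with P(X ≥ k) < α under Binomial(n, ½); at n = 18, α = 0.05
this is 13/18 ≈ 72%.

The similarity procedure asks whether one subject's recording is
distinguishable from a random sample of the pooled group: per resample,
T random time-vectors are excluded from the pooled other-subject data to
form a pseudo-series, the covariance is fitted on the remainder, and the
ratio r = L(X_subject)/L(X_pseudo) of the two log-likelihoods is
averaged over resamples (ratios near 1 mean indistinguishable).  The
resample count is configurable (5000 at full fidelity; 50 in tests).

## The Hopf whole-brain model

Each node obeys the normal form of a supercritical Hopf bifurcation,

    dz_j/dt = z_j (a + i ω_j) − z_j |z_j|² + β η_j(t),

with a stable focus for a < 0 and a limit cycle of amplitude √a for
a > 0.  Nodes couple diffusively through the structural matrix C with
global gain G on both real and imaginary parts; the BOLD proxy is the
real part x_j sampled on the TR grid.  Parameters and conventions:

* β = 0.04; noise is added as β·√dt·N(0,1) independently on both parts
  (the √dt scaling is the consistent Euler–Maruyama discretisation of
  additive white noise; β is exposed in config because legacy
  implementations differ on this point).
* dt = 0.1·TR/2 = 0.104 s at TR 2.08 s; one output sample per
  round(TR/dt) = 20 steps.
* The first 20 TR-equivalents are discarded as transient.
* Initial state uniform in [−0.1, 0.1]² per node.
* Intrinsic frequencies ω_j are estimated from data as the per-ROI
  periodogram peak inside the band, averaged over subjects and clipped
  to the band.
* Identical parameters (including the seed) give bit-identical output;
  the integration core is JIT-compiled.

## Working-point fitting

The sweep varies G (0–3, step 0.1 at full fidelity) and a (−0.5–0.5,
step 0.02), simulating series of the empirical length, filtering and
z-scoring them exactly like the data, and comparing model and empirical
FC by the Euclidean distance over strictly-upper-triangle entries.
Repeats (50 at full fidelity; 4–8 at desk scale) are averaged **as FC
matrices before the distance**: averaging per-repeat distances instead
adds a uniform sampling-noise inflation that flattens the (G, a) valley
and destroys parameter identifiability at reduced scale.  Synchrony and
metastability are averaged per repeat.  Optimal-fit curves take the
per-G argmin over a (for G ≥ 0.2) and the per-a argmin over G; exact
ties break toward a nearest 0 and toward smaller G.  Between-state
difference curves are compared pointwise against label-shuffled
surrogate curves with inclusive p-values.

## Effective connectivity

EC reinterprets structural link weights as effective interaction
strengths: starting from the prepared SC, weights of anatomically
existing links are nudged by the FC mismatch,

    EC_ij ← EC_ij + α (FC_target,ij − FC_model,ij),   α = 0.01,

with simulations at the fixed working point (G = 1, a = 0).  Updates are
symmetric; links driven negative are floored at 2⁻⁵² (the same epsilon
device used for missing links) so they stay updatable; zeros outside the
anatomical mask are never touched.  An update is accepted only when it
lowers the Euclidean FC distance; the procedure runs a fixed 200
iterations.  Two preparation steps: the SC is scaled to a maximum of
0.2, and each missing homologous (mirror-region) pair receives a 2⁻⁵²
entry — interhemispheric links are systematically under-detected by
tractography.  "Homologous" defaults to the (i, i+N/2) pairing of a
two-hemisphere ordering and is configurable for other atlas orders.
Before the descent, all weights are multiplicatively re-scaled by the
empirical/model synchrony ratio until the mismatch is below 0.1
(capped at 20 rounds).

Numerical choices specific to the descent:

* **Common random numbers.** Every candidate is evaluated under the same
  fixed set of noise realisations (cfg.n_repeats seeds reused across
  iterations), so accept/reject decisions compare matrices rather than
  noise draws.  With fresh noise per iteration the greedy acceptance
  stalls after a handful of lucky draws; with common draws the descent
  converges steadily and deterministically for a fixed seed.
* **Repeat averaging** is per iteration (FC matrices averaged across the
  noise repeats); whole-run averaging is available by averaging final EC
  matrices over independent seeds.
* Validation is a round trip: estimate EC against the target FC, then
  re-estimate using the first pass's best simulated FC as the target,
  and correlate the two EC matrices over nonzero links.
  Self-consistency of the procedure appears as a correlation near 1.
  By default the second pass runs under the same simulation conditions
  (the same noise seed set) as the first, so the correlation isolates
  whether the procedure finds its way back to its own output — the
  second pass's final FC distance indeed drops to ≈ 0.  With
  independent noise (available via a flag) the correlation additionally
  absorbs the sampling noise of the model FC, which scales as
  1/√(repeats × effective samples); the narrow band leaves roughly
  2·bandwidth·duration effective samples per repeat, so at desk-scale
  repeat counts that variant measures sampling noise rather than the
  procedure.  At full-fidelity repeat counts the two variants coincide.

## Forced-node response

The noise-free forced node dz/dt = z(a + iω₀) − z|z|² + F e^{iω_F t} is
integrated in the frame co-rotating with the stimulus (the exact change
of variables u = z e^{−iω_F t}, under which |z| = |u|) with an adaptive
Runge–Kutta scheme; the response amplitude is the mean |u| over the
final 20% of a horizon long enough for the slowest regime to
equilibrate.  Fixed-step forward Euler is avoided here because its
per-step amplitude inflation (≈ ω²dt/2) exceeds the small amplitudes of
interest at any affordable step size.  At the bifurcation the resonant
response follows |Z| = F^{1/3} (cubic balance r³ = F); for a < 0 and
weak forcing it is linear, |Z| ≈ F/|a|.  The reported exponent is the
least-squares slope of log|Z| vs log F over at least two decades of F.

## Synthetic cohorts: what they emulate and what they do not

The generator stands in for the non-deposited empirical data.  It
reproduces: the paired two-state design; the ROI count, TR, recording
length and frequency band; a two-hemisphere structural matrix with
sparser interhemispheric links (cross-hemisphere link density 0.3× the
within-hemisphere value) and heavy-tailed weights
(lognormal, σ = 1.6, matching the several-orders-of-magnitude span of
fiber-density matrices, ~8×10⁻⁵ to 0.2 after scaling); and a
state difference injected through the model's working point.  Defaults:
awake a = −0.05, G = 1.6; sleep a = −0.10, G = 1.4.  The a values sit in
the ranges the working-point fit identifies for the two states; the G
values were calibrated once so the group-level synchrony, metastability
and FC of the default 90-node cohort land near the empirically observed
levels (awake ≈ 0.57/0.22/0.46; sleep ≈ 0.39/0.18/0.22).  Intrinsic
frequencies are drawn uniformly in 2π·[0.04, 0.07] rad/s and shared
across subjects and states so the generating truth is known.

Deliberately not modelled: scanner and physiological noise, head motion,
hemodynamic convolution, EEG.  Consequently, passing tests demonstrate
the correctness and self-consistency of the analysis chain under the
model's own assumptions — not robustness to the artefact structure of
real fMRI.

## Degenerate inputs and error behaviour

Constant or zero-variance ROI signals, flat in-band spectra, all-zero
structural matrices, unpaired cohorts, |r| = 1 entries under the Fisher
transform, and non-finite integration states each raise a typed error
naming the offending ROI/subject/step.  A sweep cell whose simulation
blows up is marked invalid and skipped by the curve extractors; other
cells proceed.

## Problem sizes used in tests and the reproduction script

Full-fidelity settings (18×90×1505, 50 repeats, 31×51 grid, 5000
resamples) are available through configuration.  The shipped tests and
`scripts/acceptance.py` use desk-scale versions chosen as the smallest
sizes at which each property is stable: cohorts of 4–8 subjects with
12–30 ROIs for unit behaviour; the full 18×90×1505 cohort for the
classifier check; 20-node, 5×5-grid sweeps with 10 repeats and
full-length (1505-volume) recordings for parameter recovery — shorter
recordings leave the (G, a) valley a flat ridge along which the
minimiser wanders; and 90-node EC runs (6 noise repeats, 800-volume
recordings, 200 iterations) for the round-trip validation.

## Known limitations

* The bifurcation parameter is uniform over nodes; node-heterogeneous
  working points are out of scope.
* EC is symmetric and undirected by construction.
* The greedy descent under simulation noise is conservative: with few
  repeats the accepted-step count, and hence the attainable FC fit,
  degrades before the round-trip correlation does.
* The similarity ratio divides raw log-likelihoods; with near-zero
  denominators it would be unstable, which does not occur at the data
  sizes used here.
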