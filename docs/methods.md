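# Methods

`srcconn` implements a source-space directed-connectivity analysis for
epoched EEG: sensor-level time-frequency statistics, frequency- and
time-domain beamforming, density-based source clustering, an ANN-based
nonlinear multivariate autoregressive (nMVAR) estimator of directed
coupling with time-shifted surrogate significance, and cohort-level
asymmetry statistics.  A synthetic generator of coupled oscillatory
sources makes every stage testable by recovery of known structure.  This
note records the model, the parameters that matter, the numerical choices
made where the design was genuinely open, and what the synthetic world
does and does not establish.

## Sensor-level statistics

**Time-frequency decomposition.**  Sliding Hann-tapered segments are
Fourier-transformed and read out at the DFT bin nearest each requested
frequency (no zero-padding; edge windows that do not fit are dropped).
Power is a one-sided density, so summing over all bins times the bin
width recovers the time-domain variance (checked to 5% for stationary
noise).  Baseline modes are percent change and dB relative to the
time-mean over a baseline interval.

**Cross-spectral density.**  Per trial, the analysis window is
Hann-tapered; complex sensor spectra are averaged as outer products over
the DFT bins inside the band and over trials.  The window must span at
least three cycles of the band's lowest frequency: 0.75 s for a 4-Hz
floor (theta 4–7 Hz), 0.375 s for an 8-Hz floor (alpha 8–12 Hz).  This
precondition is enforced, and the default analysis windows ([0.2, 0.95] s
theta, [0.6, 1.0] s alpha for contrasts; [0, 1] s for connectivity)
satisfy it.

**Cluster-based permutation test (CBPT).**  Paired per-sensor t values
are thresholded at the two-sided critical t (0.05, df = n−1);
suprathreshold sensors of common sign form clusters under a
distance-defined neighbor graph (neighbors = sensors within a fixed
radius), scored by summed t (mass).  The null is the maximum |mass| over
Monte-Carlo sign flips of the per-subject condition differences
(within-subject condition swaps — the standard exchangeable scheme for a
paired design).  A cluster's p is the usual add-one permutation p.
Because |observed mass| is compared against a max-|mass| null, the test
is two-sided at level alpha directly; no additional per-tail alpha/2 is
applied (doing both would halve the intended family-wise rate — the
calibration test verifies the 5% family-wise level empirically with
1000 simulated null datasets).

## Source localization

**Forward model.**  A deliberately analytic toy: sensors on a Fibonacci
lattice of the upper unit hemisphere; a cubic source lattice clipped to a
ball strictly inside the sensor sphere; scalar (fixed-orientation)
dipole-potential leadfield rows `m·(r_s−r_v)/|r_s−r_v|³`, scaled to unit
norm.  Dipole moments vary smoothly over the grid (radial plus a small
seeded perturbation); with mutually incoherent random moments a compact
source *patch* would project like no single voxel and beamformer scanning
would misbehave — smooth moments are what makes patch sources behave like
slightly blurred point sources, as in realistic head models.  No
BEM/FEM realism is attempted; conclusions about real anatomy are out of
scope.

**DICS.**  The common spatial filter is built from the real part of the
condition-pooled CSD (trial-count weighted), with diagonal loading
`lambda = reg_fraction · trace/N_s` (default 5%):
`w = (l C⁻¹ lᵀ)⁻¹ l C⁻¹`, unit-gain by construction.  Power is
`Re(w C wᴴ)`; the noise-normalized activity index divides by the
smallest eigenvalue of Re(C) projected through the filter
(`lambda_min · |w|²`), canceling the depth-dependent gain (center-of-head
bias).  Using the real part is a documented choice: it yields real power
and matches common practice; filters from the complex CSD differ only
when sensor-level imaginary coherence is large.

**Selection and clustering.**  The top 2% of voxels by |value| (ties
broken by ascending index for determinism) are clustered with DBSCAN at
eps = 1.5 × grid spacing (includes edge-adjacent lattice voxels) and
minimum 3 voxels; noise points are dropped.  Activity clusters (ACs) for
connectivity are taken from the condition-pooled power map so that both
conditions share one region set; contrast clusters (CCs) come from the
signed difference map (condition A − condition B), with the dominant sign
recorded.

**LCMV and virtual series.**  The common LCMV filter applies the same
regularized unit-gain formula to the pooled time-domain covariance of the
windowed, per-trial-demeaned data.  Per voxel the filter output on the
full epoch is band-passed with a Hamming-windowed sinc FIR
(order = ceil(3.3/normalized 2-Hz transition), rounded up to even, so the
group delay is an integer and centred convolution gives zero net delay),
then cropped to the analysis window.  The FIR order (~423 taps at 256 Hz)
exceeds a 1-s window, which is why filtering precedes cropping; the error
condition therefore compares filter order with the epoch length.  Within
a cluster, voxel series are sign-aligned to the largest-power voxel
(beamformer signs per voxel are arbitrary; unaligned averaging can cancel
coherent activity) and averaged.  Finally the series are decimated to
roughly 4× the band's upper edge (factor `floor(fs/(4·band_hi))`; the FIR
doubles as the anti-alias filter).  Without decimation a 256-Hz
narrowband series is ~30× oversampled: one-step prediction is trivially
near-deterministic (NMSE < 0.001) and autoregressive modelling of it is
ill-conditioned.

## Directed connectivity (nMVAR + ANN)

**Model.**  Trials are concatenated; training samples whose lag window
would straddle a trial boundary are excluded (concatenation otherwise
fabricates spurious transitions).  Inputs are per-channel z-scored lag
vectors (length K·p); one hidden tanh layer (default 10 units) with
linear outputs predicts the next z-scored sample of all K regions.
Training minimizes MSE with L-BFGS from a seeded initialization: hidden
units are random unit directions with per-unit gains log-uniform on
[0.3, 3] (spanning near-linear to saturating regimes) and the output
layer is pre-solved by least squares on those features.  This start point
removes most optimizer burn-in; the fit is a pure function of (data,
seed, config) and is bit-reproducible.  Diagnostics (per-channel NMSE and
prediction correlation) are stored on the model.

**Model order.**  A linear VAR is fitted by least squares for
p = 1..p_max on the common sample set valid at p_max (fits exactly
nested), giving `AIC(p) = ln det S_p + 2pK²/N` and
`SBC(p) = ln det S_p + pK² ln N/N`.  The elbow of a criterion is the
smallest p whose relative improvement falls below a tolerance (default
0.05) of the total span; the selected order is the larger of the AIC and
SBC elbows.  Following the group-level policy, the order is selected once
on pooled cohort data and applied to all subjects.

**Linear/nonlinear split.**  The published estimator this follows does
not document its internal decomposition; this package fixes one concrete,
first-principles operationalization.  The linear part is the first-order
Taylor expansion of the network at the origin,
`A = W_out diag(1−tanh²(b_in)) W_in` (per-lag blocks), which reduces
exactly to the VAR coefficients when the network is linear.  The linear
connectivity strength is `LCS(j→i) = sqrt(Σ_k A[i,j,k]²)`.  The nonlinear
strength is the RMS deviation of the per-sample Jacobian from that linear
part over the training inputs,
`NCS(j→i) = sqrt(mean_t Σ_k (J_t−A)[i,j,k]²)`, computed in closed form
from the hidden-activation covariance of `d_t − d_0`
(`d_t = 1−tanh²(z_t)`).  For a network operating in tanh's linear regime
NCS is zero to machine precision (tested at NCS/LCS < 1e-3), and the
linearization agrees with central finite differences to 1e-6.

**Significance and normalization.**  Time-shifted surrogates circularly
shift each region's concatenated series independently (offsets uniform on
[0.1N, 0.9N]), destroying cross-region alignment while preserving
marginal autocovariance, and the *entire* estimator — ANN fit included —
is recomputed per surrogate with a derived seed (the null must propagate
through the estimator).  Two calibration details matter.  First, shifting
moves each region's trial edges (and adds one wrap seam) to new
positions; surrogate fits exclude lag windows crossing any region's
shifted discontinuity, exactly as observed fits exclude boundary-crossing
windows — otherwise the seams read as artificial nonlinear transitions
and the null is right-shifted (measured false-positive rate ~1% instead
of 5%).  Second, the threshold is the k-th surrogate order statistic with
k = ceil((1−q)(n+1)) — the permutation convention that counts the
observed value as part of the exchangeable set — so the per-connection
false-positive rate is ~q for any surrogate count (with the plain
ceil((1−q)n) rule, 20 surrogates at q = 0.05 would give 2/21 ≈ 9.5%).
A connection is significant if it strictly exceeds that threshold
(q = 0.05 one-sided; an observation equal to a zero-variance null is
conservatively non-significant); non-significant entries are set to 0.
Per subject and measure, values are then divided by the maximum
non-self value across both conditions, giving [0, 1] with the subject
maximum exactly 1.

**Group statistics.**  Directional asymmetry is a paired two-sided t on
(forward − reverse) per directed pair and condition, BH-FDR-corrected
within the family of all contrasts in one band and measure (the
narrowest defensible family; configurable).  Masked values enter as
their stored zeros.  Average network connectivity is the mean of non-self
values; planned single contrasts (condition or band comparisons of the
average) use a paired t without FDR.  Cohen's d for paired data is
mean difference / SD of differences.

## Synthetic world

Each subject has K = 2 source patches (anterior driver, posterior
receiver, centers at ±70% of the grid radius; each patch is the voxel and
its lattice neighbors within 1 grid step, projected through the mean
patch leadfield).  Source dynamics follow the nMVAR generative equation:
stable AR(2) self-dynamics (0.5, −0.2), band-limited stochastic drive
(white noise band-passed to theta or alpha, unit variance), white
innovation noise (sd 0.2), and a unidirectional saturating coupling
`c·tanh(x_driver(t−1))` with c = 0.8 into the receiver.  Drive amplitudes
are asymmetric by design — 1.0 for the driver (which saturates the tanh,
making the transfer genuinely nonlinear) and 0.35 for the receiver (so a
substantial share of its activity is inherited through the coupling).
The "high" condition multiplies drive amplitudes by 1.5, emulating a
band-power demand effect.  Per-subject multiplicative jitter (sd 0.1) on
all coupling coefficients is resampled until stable (at most 100 draws).
Sensor projection adds white noise at a configurable average SNR (default
5 dB; the emulated recordings' true SNR is unknown, so this is a
calibration choice, not an empirical claim).  Everything is a pure
function of a master seed via `SeedSequence.spawn`.

**What a green test establishes — and an honest limitation.**  The
generator validates each stage against ground truth: localization
recovery, order recovery, directionality recovery, null calibration.  It
does *not* emulate realistic anatomy, artifacts, 1/f background, or
cross-frequency structure.  One consequence is structural: a *static*
saturating coupling expresses its nonlinearity largely in harmonics
(roughly 3× the driver's frequency) and, once virtual series are
band-pass filtered to the analysis band, what survives in-band is an
envelope-dependent gain too weak to clear surrogate thresholds at desk
scale.  Empirically, held-out NMSE of the ANN shows no advantage over a
linear VAR on band-passed + decimated data from this generator (this was
also true for several envelope-gated coupling variants tested during
design).  Directed-asymmetry recovery is therefore validated on
source-level region time courses, where the estimator sees the dynamics
that actually carry the nonlinearity; the full beamformer chain is
validated for localization, mechanics and calibration.  Real broadband
EEG need not share this limitation, but establishing that is beyond a
synthetic desk-scale world.

## Defaults that matter

| parameter | default | why |
| --- | --- | --- |
| bands | theta 4–7 Hz, alpha 8–12 Hz | the two bands the analysis targets |
| contrast windows | [0.2, 0.95] s (theta), [0.6, 1.0] s (alpha) | ≥ 3 cycles of the band floor |
| connectivity window | [0, 1] s | target-locked interval |
| DICS/LCMV regularization | 5% of mean sensor variance | standard diagonal loading |
| top-voxel fraction | 2% | compromise between scattered and diffuse clusters |
| DBSCAN | eps = 1.5 × spacing, min 3 voxels | edge-adjacent voxels connect; ≥3-voxel clusters |
| FIR transition | 2 Hz, Hamming | order ~3.3/Δf_norm; zero net delay |
| decimation | floor(fs/(4·band_hi)) | avoid degenerate oversampled AR fits |
| hidden units | 10 | small K·p input spaces; capacity vs. overfit |
| L-BFGS max_iter | 200 (70–120 in Monte-Carlo suites) | converged diagnostics vs. runtime; scaled-down runs are noted where used |
| surrogates | 100 (20 in CI-scale runs) | empirical q = 0.05 needs ≥ 20 |
| CBPT | 500 permutations, alpha 0.05 two-sided | add-one p floor 1/501 |
| cohort | 50 subjects (12 at desk scale), 60 sensors, 256 Hz, SNR 5 dB | emulated experiment; SNR by calibration |

## Known limitations

- Scalar source orientations; no free-orientation beamforming.
- No anatomical atlas naming; cluster labels are free text hooks.
- The linear/nonlinear decomposition is one defensible operationalization
  of an underdocumented estimator; others may differ in detail.
- Whether surrogates should shift all regions or all-but-one is not
  settled; all regions are shifted here.
- EDF import requires an external reader not present in this
  installation; HDF5 and delimited dialects are the supported inputs.
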