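# Methods

## Switching-diffusion model

Trajectories are modelled as two-dimensional Brownian motion whose
diffusion coefficient switches among K discrete states. The hidden state
evolves as a first-order Markov chain at frame boundaries only (matching
the inference model, which assigns one state per displacement step); given
state k, the displacement over one frame interval Δt is isotropic Gaussian
with per-coordinate variance 2·D_k·Δt. Derived per-state quantities follow
the usual discrete-chain conventions: dwell time τ_k = Δt/(1 − A_kk),
occupancy = stationary distribution of A, off-diagonal rates A_kj/Δt.

Confinement uses specular reflection of the sub-step overshoot at the
boundary of the disc (default 8 µm diameter) or rectangle (default
1 × 2 µm, a small disc lobule). The boundary rule is a modelling choice —
confined "reaction-diffusion" motion does not single one out — and at the
default geometry/diffusivity scale the choice is immaterial because
boundary contacts are rare within a track.

Observed positions add i.i.d. zero-mean Gaussian localization error
(default σ = 50 nm per coordinate). Static error inflates the apparent
step variance: MSD(nΔt) = 4DnΔt + 4σ², i.e. every apparent state D is
inflated by σ²/Δt (0.075 µm²/s at the defaults). Noise-free positions and
true state sequences are carried alongside for validation only; inference
never reads them.

Track lengths are shifted-geometric with minimum 16 and mean 35 frames —
the experimental protocol fixes only the minimum (>15) and mean (~35), and
the geometric tail is the maximum-entropy choice for a memoryless
detection-loss process.

## Condition presets

The `dark` preset encodes the dark-adapted disc: K = 3 with stationary
occupancies (0.20, 0.50, 0.30) and a 100 ms slow-state dwell time. The
exact per-state diffusion coefficients are not published numerically, so
the preset derives them from the physics the analysis itself asserts:
D₁ = D(90 nm) = 0.078 µm²/s and D₂ = D(2 nm) = 0.392 µm²/s from the
extended Saffman–Delbrück relation (cluster and dimer radii), and
D₃ = 3·D₂ = 1.177 µm²/s, chosen so the ensemble median D_100ms falls
inside the 0.1–0.6 µm²/s literature range (verified by simulation: the
default pipeline gives ≈ 0.48 µm²/s).

The transition matrix is the reversible construction A = I + Δt·Q with
Q_kj = φ·π_j (k ≠ j): its stationary distribution is exactly the requested
π, every pair of states exchanges, and the single free rate φ is fixed by
the slow-state dwell time (φ = 12.5 s⁻¹ for τ₁ = 100 ms), which puts the
other dwell times at 160 ms and 114 ms. `light_noGTP` raises slow-state
occupancy to 40 % by lengthening its dwell to 250 ms at unchanged D's
(light slows rhodopsin by increasing slow-state occupancy, not by changing
state coefficients); `dark_MCD` is state-2 dominant (cholesterol
depletion); `single_state` is a one-state control.

Cluster-movie kinetics (`dark`): nucleation 15 s⁻¹ per disc so a 700-frame
movie yields ≳300 events at a steady state of ~1.5 concurrent clusters
(trackable without ambiguity); exponential mean lifetime 100 ms (the
slow-state dwell, which the cluster interpretation equates with cluster
lifetime); cluster D = D₁; centre-biased nucleation with a 1.5 µm Gaussian
radial scale (clusters concentrate in the disc centre); cluster brightness
2000 photons/frame against a 40-spot monomer background at 150
photons/frame (clusters are far brighter than single fluorophores), PSF
σ = 0.15 µm, Poisson shot noise over a 20-photon background, camera offset
100 counts, Gaussian read noise σ = 2.

What the generator does *not* emulate: photophysics (blinking/bleaching
beyond the track-length distribution), axial diffusion, motion blur within
a frame, disc incisures (the experimental protocol removed
incisure-confined tracks rather than modelling them), and non-stationary
kinetics. Passing tests therefore demonstrate correctness of the inference
chain under the stated model, not robustness to those real-data effects.

## MSD analysis

Time-averaged MSD uses all overlapping pairs. D_100ms is slope/4 of an
ordinary least-squares line over the lags within 100 ms (three lags at
30 frames/s) with a free intercept; the free intercept absorbs the 4σ²
static-error offset, so the slope estimates the true (not apparent) D.
The confinement filter computes R² of a linear fit over the first quarter
of available lags (the conventional clip factor for MSD linearity checks)
and removes tracks with R² ≤ 0.8 or fewer than 16 frames. The histogram
bin width (0.05 µm²/s) is presentational.

Two-sample comparison uses the Mann–Whitney U test with midrank ties:
exact enumeration when the smaller sample has ≤ 8 values and no ties,
otherwise the normal approximation with tie and continuity corrections
(delegated to `scipy.stats.mannwhitneyu`, whose `auto` policy implements
exactly this rule).

## Variational-Bayes HMM

Beal-style conjugate VBEM. Per state, a gamma posterior over the step
precision λ_k = 1/(2D_kΔt) (each 2-D step contributes one shape count and
|x|²/2 to the rate); Dirichlet posteriors over each transition row and the
initial distribution. The E-step runs scaled forward–backward under
expected log-parameters (tilted, sub-normalized weights); the ELBO — the
forward log-normalizer minus the KL of each posterior factor from its
prior — is exact for this family and non-decreasing across iterations,
which the tests assert on every fit.

Priors are weak and data-dominated: symmetric Dirichlet with concentration
1 per element on each row and the initial distribution, and a gamma prior
with one pseudo-count whose mean matches the pooled moment estimator of
the step precision. At the default data scale (~13,000 steps) the prior
contributes < 0.1 % to any point estimate.

Numerical choices: 25 independent restarts per model size (the
best-evidence restart wins), initialized from randomized data quantiles of
the squared step norms with a random sticky transition matrix; at most 500
VBEM iterations per restart with convergence at a relative ELBO change of
1e-8 (a restart that exhausts the cap is returned with `converged=False`
and a warning); per-step log-emission shifts guard against underflow;
point D is the posterior mean E[1/λ]/(2Δt) = b/((a−1)·2Δt). Restart r of
model size K draws from the derived stream (seed, K, r), so results do not
depend on execution order. Model selection chooses the K with the maximal
ELBO, breaking ties within tolerance towards smaller K; states with fewer
than one expected step are pruned from the report. Reported states are
always sorted by ascending D. Bootstrap uncertainty resamples whole
trajectories (steps within a track are dependent), refits at fixed K, and
matches states across replicates by the same ordering.

The emission deliberately ignores localization error, as the reference
analysis does; apparent state coefficients are therefore inflated by
σ²/Δt. An optional correction subtracts σ²/Δt from the reported D
(`correct_localization=True`), which removes ≥ 80 % of the bias on
simulated data; the pipeline's sizing stage applies the same subtraction
by default so radii reflect diffusion rather than measurement noise. The
forward–backward and Viterbi inner loops are compiled with numba; their
semantics are plain recursions over padded sequence batches.

## Hydrodynamic sizing and engagement stoichiometry

The extended Saffman–Delbrück relation uses the Petrov–Schwille (2008)
interpolation in the reduced radius ε = 2µ_wR/(µ_mh) (symmetric solvent on
both leaflets), which reduces to the classical logarithmic form
kT/(4πµ_mh)·(ln(2/ε) − γ) within 1 % for ε ≤ 0.01 and remains valid for
µm-scale inclusions. Defaults: µ_m = 0.8 Pa·s (8 Poise), µ_w = 0.02 Pa·s
(0.2 Poise), h = 4 nm (standard bilayer thickness), T = 298 K; the
membrane thickness and temperature are not fixed by the source analysis
and are exposed as configuration. Inversion is monotone Brent root-finding
on a [0.1 nm, 10 µm] bracket, with roundtrip accuracy at machine
precision; a requested D outside the attainable range raises an error
naming the bracket. Inter-leaflet friction, curvature and crowding
corrections are out of scope.

The engagement model counts rhodopsin sequestered into slow 2:1
photoactivated-rhodopsin–transducin complexes: complexes per rhodopsin =
min(1/r_Gt, iso/r_cx) with r_Gt rhodopsins per transducin (10) and r_cx
rhodopsins per complex (2); the sequestered fraction is r_cx times that —
piecewise linear, saturating at iso = r_cx/r_Gt = 20 %.

## Cluster-movie analysis

Detection: scale-normalized Laplacian-of-Gaussian response at the PSF
scale; threshold in robust noise units (1.4826·MAD of the response);
sub-pixel refinement by 3×3 response centroid. The analysis default of
SNR 10 sits between the monomer-background response and the ~13× brighter
cluster response, so monomers are excluded by construction.

Linking: greedy reciprocal nearest-neighbour assignment with a per-frame
displacement cap (scaled by gap length when closing gaps), an adequate
approximation of LAP tracking at ~1–2 concurrent spots per disc; splits
and merges are never produced. Tracks touching the movie's first or last
frame are flagged censored.

Lifetime: track durations are frame-quantized, so the shifted-exponential
MLE is evaluated in its discrete (geometric) form,
τ* = −Δt/ln(m/(1+m)) with m the mean number of frames beyond the
minimum detectable duration (2 frames — a 1-frame blip is
indistinguishable from noise). The continuous formula mean(d − d_min) is
its Δt → 0 limit and would carry a ≈ −16 % quantization bias at
τ = 100 ms, which the discrete form removes; for exponential lifetimes the
discrete MLE is unbiased under ideal detection. The default policy
discards censored tracks (memorylessness makes this unbiased); an
alternative keeps right-censored tracks in the at-risk time.

Kymographs mean-project a band of configurable width across the scan line
(a mean is reproducible where a "3-D projection" display is ambiguous).
Radial profiles use 20 bins to the disc radius around the intensity
centroid (or a supplied centre); the confinement index is the mean pixel
intensity at r < 0.5R over the mean at 0.8R < r < R — above 1 means
centre-confined, below 1 annular.

## Problem sizes and reproducibility

Default analyses run at the experimental data scale: ~400 trajectories of
mean 35 frames (~13,000 steps) for trajectory inference, and 700-frame
movies (≳300 nucleation events) for the cluster pipeline. The acceptance
script reports medians over five seeds (occupancies) and three seeds
(lifetime). All stochastic stages consume seeds derived from one master
seed via `numpy.random.SeedSequence`; identical configuration and seed
reproduce every report byte for byte.

## Known limitations

- The HMM assumes memoryless per-frame switching and ignores the negative
  step autocorrelation induced by localization error; occupancies remain
  accurate but apparent D's are biased as described.
- Model selection at short dwell times (~3 frames) and moderate state
  separation is seed-dependent in principle; at the default scale K = 3 is
  selected consistently, but occupancy estimates retain a few percentage
  points of scatter between seeds.
- The linking stage can fragment tracks when two clusters approach within
  the displacement cap; at the default nucleation rate this affects a few
  percent of tracks and biases the recovered lifetime slightly downward,
  well inside the validation tolerance.
- The continuous-time interpretation of dwell times (τ = Δt/(1 − A_kk))
  breaks down as A_kk → 0; dwell times close to one frame are reported but
  not resolved.
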