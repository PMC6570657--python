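# discspt

Diffusive-state analysis of single-particle tracking in photoreceptor disc
membranes.

Rhodopsin, the photopigment of rod photoreceptors, does not diffuse
uniformly in the disc membrane: single-molecule trajectories switch between
a few distinct diffusive states, thought to correspond to transient
receptor-cluster rafts, dimers and more freely moving protein. `discspt`
implements the complete quantitative workflow for characterizing such
states from trajectory data, for researchers analysing single-particle
tracking of membrane proteins:

- **Synthetic data** — Markov-switching Brownian motion confined to an
  8 µm disc (or a 1 × 2 µm lobule) with reflecting boundaries, realistic
  track-length statistics and 50 nm localization error, plus rendered
  fluorescence movies of transiently nucleating, centrally confined
  clusters with full ground truth.
- **MSD analysis** — time-averaged mean square displacement, the effective
  diffusion coefficient within 100 ms (D_100ms = slope/4 of the MSD–Δt line
  over lags ≤ 100 ms, free intercept), the track filters (length > 15
  frames, R² > 0.8 against confinement-bent curves), and Mann–Whitney U
  comparison of D_100ms histograms.
- **Variational-Bayes HMM** — the core inference. Each displacement
  x_t ∈ ℝ² is emitted by a hidden state k as an isotropic Gaussian with
  per-coordinate variance 2·D_k·Δt; the state follows a Markov chain with
  per-frame transition matrix A. Conjugate priors (gamma over step
  precision, Dirichlet over transition rows) give closed-form VBEM updates,
  and the evidence lower bound (ELBO) both drives the fit and selects the
  number of states K by maximum evidence. Exposed as scikit-learn style
  estimators (`VariationalBayesDiffusionHMM`, `DiffusionHMMSelector`) with
  trajectory-level bootstrap uncertainty and Viterbi state decoding.
- **Hydrodynamic sizing** — the extended (Petrov–Schwille) Saffman–Delbrück
  relation D(R) for a cylindrical inclusion of radius R in a membrane of
  viscosity µ_m and thickness h in solvent µ_w, valid at all reduced radii
  ε = 2µ_wR/(µ_mh), and its monotone inversion R(D); plus the
  transducin-engagement stoichiometry model, which saturates at
  (rhodopsins per complex)/(rhodopsins per transducin) photoisomerization —
  20 % for the physiological 10:1 ratio and 2:1 complex.
- **Cluster imaging** — Laplacian-of-Gaussian spot detection, reciprocal
  nearest-neighbour linking (no splits or merges), exponential
  maximum-likelihood cluster lifetimes with censoring policies, kymographs,
  and radial confinement profiles of the disc.

## Worked example

Run the default pipeline — 400 simulated trajectories (mean 35 frames,
minimum 16) from the dark-adapted three-state preset with 50 nm
localization noise, filtering, MSD analysis, model selection over K = 1..5
with 25 restarts, and hydrodynamic sizing of the slowest state:

```python
from discspt import run_pipeline

report = run_pipeline({"seed": 1})
print("chosen K:", report["hmm"]["chosen_k"])
print("D_state (um^2/s):", [round(d, 3) for d in report["hmm"]["d_states_um2_per_s"]])
print("occupancies:", [round(o, 3) for o in report["hmm"]["occupancies_fraction"]])
print("dwell times (s):", [round(t, 3) for t in report["hmm"]["dwell_times_s"]])
print("median D_100ms (um^2/s):", round(report["msd"]["median_d100ms_um2_per_s"], 3))
print("slow-state radius (nm):", round(report["sizing"]["radius_nm"], 1))
```

prints (about a minute on one CPU):

```
chosen K: 3
D_state (um^2/s): [0.16, 0.492, 1.227]
occupancies: [0.23, 0.501, 0.269]
dwell times (s): [0.111, 0.199, 0.114]
median D_100ms (um^2/s): 0.48
slow-state radius (nm): 79.0
```

Model selection recovers the three generating states. The reported
`D_state` values are *apparent* coefficients, inflated by the static
localization error by σ²/Δt = 0.075 µm²/s (0.050² × 30); the generating
values are 0.078, 0.392 and 1.177 µm²/s. Occupancies recover the
generating 20/50/30 % split, the slowest state's dwell time recovers its
100 ms setting, and the median D_100ms sits in the 0.1–0.6 µm²/s range
reported for rhodopsin. The sizing stage removes the σ²/Δt inflation
before inverting the Saffman–Delbrück relation, mapping the slow state
back towards its generating 90 nm cluster radius.

The same stages are available as CLI subcommands (`discspt simulate-traj`,
`msd`, `hmm`, `size`, `engagement`, `simulate-movie`, `clusters`,
`compare`, `run`); see `discspt --help`.

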