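# Methods

`defibopt` simulates episodes of fibrillation-like spiral-wave chaos in
two phenomenological models of human ventricular tissue, evaluates
low-energy multi-pulse pacing protocols against those episodes, derives
spectrum-guided deceleration reference protocols, and optimises
protocols with a genetic algorithm. This note records the models, the
numerical choices, the synthetic-episode generator, the scaled-down
study sizes used by the test suite, and known limitations.

## Tissue models

Both models evolve a normalised transmembrane potential `u` on a
homogeneous, isotropic 2D sheet,

    du/dt = D ∇²u − I_tot / C_m ,     I_tot = I_fi + I_so + I_si − I_stim ,

with no-flux boundaries. `I_fi` is a fast inward (excitation) current,
`I_so` a slow outward (repolarising) current, `I_si` a slow inward
(plateau) current, and `I_stim` the externally applied pacing current; a
positive stimulus amplitude depolarises.

**Fenton–Karma (FK)** has gates `v`, `w` and the standard three-current
forms

    I_fi = −(v/τ_d) H(u−u_c) (1−u)(u−u_c)
    I_so =  (u/τ_0) H(u_c−u) + H(u−u_c)/τ_r
    I_si = −(w/(2τ_si)) (1 + tanh[K(u−u_c^si)])

with Heaviside-gated gate relaxation and the `τ_v⁻(u)` switch at `u_v`.
Three named parameter sets FK1–FK3 (shipped as YAML under
`defibopt/params/`) give distinct action-potential durations,
restitution and spiral-breakup behaviour; all share `D = 0.2 mm²/ms`.

**Bueno-Orovio–Cherry–Fenton (BOCF)** adds a third gate `s` and uses the
minimal-model currents with voltage-blended time constants `τ_so(u)`,
`τ_w⁻(u)`, switched `τ_o`, `τ_s`, `τ_v⁻`, and infinity functions
`v_∞`, `w_∞`. Its parameter set emulates a detailed physiological
model; `D = 0.3 mm²/ms`, peak voltage ≈ 1.5 a.u.

Conventions fixed here: `H(0) = 1`; at exactly `u = u_c` the
complementary Heaviside pair is split as `H(u−u_c)` and `1 − H(u−u_c)`
(ties are measure-zero on trajectories). The BOCF resting state uses
`s = s_∞(0) ≈ 0.0216`, the exact fixed point of the printed s-equation
(`s = 0` is not stationary). For `u < 0` the BOCF `w_∞ = 1 − u/τ_w∞`
exceeds 1; gates are therefore clamped to `[0, 1]` after every Euler
step rather than asserted.

## Numerics

Forward-in-time, centred-in-space (FTCS) explicit integration,
first-order in time, with one `Δt = 0.1 ms` for voltage and gates;
`h = Δx = Δy = 1.0 mm`. Stability guard `D·Δt/h² ≤ 0.25`.

The Laplacian uses the isotropic 9-point stencil
`[1 4 1; 4 −20 4; 1 4 1]/(6h²)` at every interior pixel except the four
grid vertices, which use the 5-point stencil so the undefined corners of
the ghost ring are never referenced. No-flux boundaries are enforced by
a one-pixel ghost ring holding copies of the adjacent edge pixels
("linked" pixels one row/column apart), which makes the discrete
boundary flux exactly zero.

Consequences worth knowing:

* Pure diffusion conserves total voltage exactly except at a 2×2 seam
  at each corner, where the 5-/9-point weight mismatch acts on the
  local second difference. For fields that are flat near the corners
  the drift is below 1e−10 relative over 10³ steps (tested); fields
  with corner curvature see a slow O(1e−4) drift instead.
* Observer sampling uses round-to-nearest accumulated time, so a
  120 Hz record at `Δt = 0.1 ms` alternates 83- and 84-step gaps.
* Every transcendental in both reaction terms is univariate in `u`;
  the compiled kernels evaluate `tanh`-based factors through dense
  piecewise-linear voltage tables (65536 points over `u ∈ [−4, 6]`,
  saturating outside). The table error (~1e−7) is far below the O(Δt)
  discretisation error; a numpy reference path computes the exact
  expressions and the suite asserts agreement to 1e−7.
* Trajectories are bitwise reproducible for identical inputs.

## Fibrillation episodes (synthetic fixtures)

The episode generator is this package's own protocol (how the original
initial conditions were made is not documented anywhere). Two seeded
schemes exist, with a per-model default:

* **Cross-field S1–S2** (FK1, FK2, BOCF): S1 launches a plane wave from
  the left edge; when the repolarisation tail crosses the domain
  centre, S2 fires a half-plane stimulus (orientation seed-chosen,
  timing jittered by a seed-drawn 0–10 ms for FK, 40–80 ms for BOCF)
  into the partially refractory tissue. The broken front curls into
  spirals that break up (FK1) or settle into sustained rotor-dominated
  activity (FK2, BOCF). Additional recovery-timed half-plane breakup
  stimuli are available for domains below a model's native size.
* **Dense random-field seeding** (FK3): thresholded smooth random
  voltage blobs over independently varying gate fields create many
  simultaneous wavebreaks. FK3 needs this because a single wavebreak
  relaxes to a slow stable spiral, while its fibrillation regime —
  dense wavelets at short diastolic intervals, where the tissue never
  repolarises into the slow branch of the v-gate recovery — is only
  reachable from a dense start.

After initiation the episode evolves freely for the burn-in (default
2000 ms, minimum 1000 ms) plus a seed-drawn 0–300 ms span that
decorrelates episodes generated from neighbouring seeds. Failed
attempts (quiescent tissue) are re-randomised up to 8 times.

Episode libraries built for termination-ratio estimation are
persistence-screened: each candidate is integrated unperturbed for
5×T_dom and must stay active, so TR estimates are not biased by
spontaneous self-termination (chaotic transients in these models are
finite, with mean lifetime growing exponentially in domain area).

What the generator emulates: sustained multi-wavelet reentry with
realistic dominant frequencies per model. What it does not: anatomical
geometry, tissue heterogeneity, electromechanical feedback, and any
claim that the specific IC ensemble matches the original study's —
dominant periods and spectrum shapes are reproduced, individual
episodes are not.

## Dominant period and deceleration (ADP) protocols

`T_dom` is estimated from a 10 s whole-grid voltage record at 120
samples/s (1200 points per pixel): per-pixel FFT, per-pixel argmax of
spectral magnitude excluding DC, frequencies averaged over active
pixels (time-series variance > 1e−8), `T_dom = 1/mean(f)`. Averaging
in frequency (not period) follows the defining procedure.

Adaptive-deceleration timings come from the pixel-averaged
squared-magnitude spectrum of a 10 s record sampled every 10 ms: the
cumulative spectral mass on `(0, cutoff]` (DC excluded) is normalised
and split at levels `k/n_pulses`; boundary frequencies are located by
linear interpolation between the 0.1 Hz bins (bin-snapping would
quantise periods by >5 ms); reciprocals, sorted ascending, are the
inter-pulse periods. Cutoffs are configuration inputs with per-model
defaults of 15, 15, 33 and 6 Hz (FK1, FK2, FK3, BOCF). The reference
amplitude for a given TR level is read off a dose-response curve as the
smallest sampled PC whose TR reaches the level (no interpolation —
conservative).

## Pacing model and metrics

A protocol is `N` non-negative amplitudes plus `N−1` onset-to-onset
intervals at a uniform 2 ms pulse length (2N−1 parameters; 5 pulses by
default). Stimuli enter through non-overlapping 3×3-pixel injection
sites placed by rejection sampling — 2000 sites on 256² and 8000 on
512², i.e. ~27.5% coverage — each with a uniform(0,1) efficacy
coefficient abstracting virtual-electrode geometry; site current is
`amplitude × efficacy`. Site maps are frozen within an attempt and
resampled across distributions.

* `PC = Σ_k a_k² × pulse_len` (a.u.): squared amplitudes penalise
  single potent pulses.
* `TR`: one termination attempt integrates through the protocol plus
  5×T_dom of free evolution, then applies `max(u) < 0.05 a.u.` once at
  that horizon. TR is the success fraction over the IC library crossed
  with seeded site distributions (5 × 10 = 50 binary samples at
  defaults); exact counts are reported alongside the float.

Dose-response curves here are non-monotone: TR rises from 0 to a
plateau of 1 at moderate amplitudes (for the FK3 dense state,
amplitudes ~1-2 a.u., i.e. PC ~10-40) and then falls again, because
overdosed pulses excite every recovered region at once and the
refractory pattern re-fragments the induced fronts into fresh
wavelets. Grid-wide single shocks never terminate the dense state for
the same reason. Reference amplitudes should therefore be read off a
measured dose-response curve, never extrapolated upward.

Intervals are onset-to-onset (the spectral derivation produces periods,
which are onset-to-onset by construction); with 2 ms pulses the
distinction from gap-based timing is at most 2 ms.

## Genetic algorithm

Fixed-size population (default 50) of evaluated protocols. Per
generation: with probability `p_mutation` (default 0.5) one uniformly
drawn protocol gets exactly one parameter replaced by a uniform draw
from that parameter type's mutation interval; otherwise two parents
drawn uniformly without replacement are cut at a random pulse
`k ∈ {1..N−1}` and recombined into two children (the bridging interval
travels with the leading segment — the sketch-level definition does not
resolve this; fixed here). Candidates are evaluated (TR via a backend,
PC analytically) and accepted iff their would-be percentile ranks clear
both thresholds (defaults 0.5/0.5); ties count half. An accepted
candidate replaces the bottom of a stable lexicographic sort whose
primary metric alternates on every replacement (TR-desc/PC-asc, then
PC-asc/TR-desc) — deliberately non-elitist. Two accepted crossover
children are processed in birth order against the already-updated
population. Each generation draws its stream from the master seed, so
runs are reproducible and resumable at generation boundaries.

The original hyperparameter values are not public; the defaults here
(`p_mutation = 0.5`, thresholds 0.5, amplitude interval `[0, 2]` a.u.,
interval range `[0.3, 2]×T_dom`) are this package's documented choices,
config-exposed, and not claims about the original runs. The same holds
for the two initialisation schemes (`uniform` and `adp-jitter` with
±10% multiplicative jitter). A slope-sign heuristic labels convergence
histories as asymptotic / rebounding / quasi-linear; it is diagnostic
only.

Fitness backends: `SimulationBackend` (termination attempts on a
library) and `SurrogateBackend` (deterministic Gaussian fitness around
a hidden target protocol in interval-normalised coordinates) for
desk-scale exercise of the machinery.

## Scaled-down study sizes

Full-scale campaigns (10⁴ generations × 50 simulated TR evaluations,
10⁵-attempt dose-response curves) are cluster-scale and out of scope.
The shipped tests use sizes chosen so the whole suite runs on one CPU
in well under half an hour:

* Dominant periods and ADP timings: one episode per FK model at the
  native 256², full 10 s records (the defining conditions).
* BOCF: trend check at the native 512² with a shortened 3 s record
  (0.33 Hz resolution, ~9 dominant periods); the full 10 s estimate
  runs through the same API when time permits.
* Dose-response smoke and the simulation-backed GA: FK3 (shortest
  T_dom, hence cheapest attempts) on a 160² domain with a 10-episode
  persistence-screened library; 160² is the smallest domain where FK3
  episodes reliably outlive the observation horizons. The GA run uses
  population 8, 20 generations, 2 ICs × 2 distributions.
* Surrogate GA: 20 seeds × 200 generations at population 50.

## Known limitations

* Two parameter sets miss their reference dominant periods. FK2
  relaxes to a stable large-core rotor near 250 ms in every regime
  reachable here (single wavebreaks, dense random seeding, rapid-
  pacing trains; measured inter-upstroke intervals confirm the rotor
  genuinely turns at ~250 ms, with no period-2 alternation), against a
  157 ms reference — notably close to the set's 1:1 capture limit
  (~160 ms), suggesting the reference describes a maintained dense
  transient this implementation cannot sustain at 256². FK3's dense
  state runs at 73–85 ms against a 68 ms reference, with a
  low-frequency tail that also stretches the upper spectrum-partition
  intervals. FK1 and BOCF reproduce their references within a few
  percent, anchoring the solver and estimator; the episode-generation
  protocol (nowhere documented for the original study) is the open
  degree of freedom.
* Homogeneous square sheets only; no anisotropy, no 3D, no anatomical
  geometry, no physiological ionic models.
* Virtual electrodes are abstracted to efficacy-weighted 3×3 injection
  sites; no emergent electrode physics.
* TR estimates are binomial with n = 50 at defaults; a protocol's TR
  confidence interval is wide (±0.14 at TR = 0.5).
* The corner seam makes pure diffusion very slightly non-conservative
  for fields curved at the corners (see Numerics).
* Episode libraries are model- and domain-specific; cross-domain reuse
  is not supported.
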