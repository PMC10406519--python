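"""Fibrillation episode generation and dominant-period estimation.

Fibrillation initial conditions are created by cross-field (S1-S2)
stimulation: a plane wave is launched from one edge, and once its
repolarisation tail crosses the domain centre a half-plane stimulus is
fired into the partially refractory tissue.  The broken activation
front curls into spiral waves that break up into the multi-wavelet
chaos used as the study's fibrillation states.  Timing jitter, the
orientation of the S2 half-plane and an extra post-burn-in integration
span are all drawn from the seed, so distinct seeds give distinct
(bitwise-reproducible) episodes.  Models whose chaotic transients are
short-lived in a given domain can request additional half-plane
breakup stimuli fired when enough tissue has recovered.

The dominant period of a model, T_dom, is the reciprocal of the
grid-averaged per-pixel peak FFT frequency of a long voltage record
(10 s at 120 samples/s by default).  DC is excluded from the peak
search and near-silent pixels are excluded from the average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .models import BOCFParams, FKParams, TissueState, load_parameter_set, resting_state
from .solver import FieldSampler, GridSpec, StimulusSchedule, integrate

__all__ = [
    "U_CRIT",
    "DominantPeriod",
    "EpisodeLibrary",
    "is_terminated",
    "make_fibrillation_ic",
    "build_episode_library",
    "record_episode",
    "estimate_dominant_period",
    "estimate_dominant_period_from_record",
    "count_wavefronts",
    "default_grid",
]

#: Global termination threshold (a.u.): below it no new action
#: potentials can form in any of the (voltage-normalised) models.
U_CRIT = 0.05

_STIM_AMPLITUDE = 2.0  # a.u., suprathreshold for all models
_STIM_LEN = 2.0  # ms

#: Per-model initiation defaults.  "s1s2" is cross-field stimulation
#: (jitter = S2 timing window after tail repolarisation, n_extra =
#: additional breakup stimuli); "dense" seeds a multi-wavelet state
#: directly from smooth random fields.  FK2 and FK3 relax to slow,
#: stable near-periodic rotors when started from a single wavebreak,
#: so their fibrillation regime (dense wavelets at short diastolic
#: intervals) must be seeded densely; FK1 reaches it by natural
#: breakup, and BOCF needs extra wavelet seeding below its native
#: 512^2 domain.
_GEN_DEFAULTS = {
    "FK1": {"scheme": "s1s2", "jitter": (0.0, 10.0), "n_extra": 0},
    "FK2": {"scheme": "s1s2", "jitter": (0.0, 10.0), "n_extra": 0},
    "FK3": {"scheme": "dense"},
    "BOCF": {"scheme": "s1s2", "jitter": (40.0, 80.0), "n_extra": 0},
}


def default_grid(params: FKParams | BOCFParams) -> GridSpec:
    """Default domain: 256^2 for the FK sets, 512^2 for BOCF (h=1mm, dt=0.1ms)."""
    n = 512 if isinstance(params, BOCFParams) else 256
    return GridSpec(n, n)


def is_terminated(state_or_u, u_crit: float = U_CRIT) -> bool:
    """True iff max(u) < u_crit strictly, everywhere on the grid."""
    u = state_or_u.u if isinstance(state_or_u, TissueState) else np.asarray(state_or_u)
    return bool(u.max() < u_crit)


def count_wavefronts(state_or_u, threshold: float = 0.3) -> int:
    """Number of disjoint supra-threshold regions (connected components)."""
    u = state_or_u.u if isinstance(state_or_u, TissueState) else np.asarray(state_or_u)
    _, n = ndimage.label(u > threshold)
    return int(n)


def _resolve(model) -> FKParams | BOCFParams:
    return load_parameter_set(model) if isinstance(model, str) else model


def _half_plane_field(shape: tuple[int, int], which: int) -> np.ndarray:
    ny, nx = shape
    f = np.zeros(shape)
    sel = [
        np.s_[: ny // 2, :],
        np.s_[:, : nx // 2],
        np.s_[ny // 2 :, :],
        np.s_[:, nx // 2 :],
    ][which % 4]
    f[sel] = _STIM_AMPLITUDE
    return f


def _one_attempt(
    params, grid: GridSpec, rng: np.random.Generator, burn_in: float, n_extra: int,
    jitter_window: tuple[float, float],
) -> TissueState | None:
    """One seeded S1-S2 attempt; returns the state or None on failure."""
    state = resting_state(params, grid.shape)

    # S1: plane wave from the left edge
    s1 = np.zeros(grid.shape)
    s1[:, :3] = _STIM_AMPLITUDE
    sched = StimulusSchedule()
    sched.add(0.0, _STIM_LEN, s1)
    probe = (grid.ny // 2, grid.nx // 2)
    excited = False
    t_rep = None
    t = 0.0
    state = integrate(state, params, grid, sched, duration=10.0)
    t = 10.0
    while t < 5000.0:
        u_probe = float(state.u[probe])
        if u_probe > 0.5:
            excited = True
        if excited and u_probe < 0.1:
            t_rep = t
            break
        state = integrate(state, params, grid, None, duration=10.0)
        t += 10.0
    if t_rep is None:
        return None

    # S2 into the repolarisation tail, jittered, random orientation
    delay = rng.uniform(*jitter_window)
    if delay > 0:
        state = integrate(state, params, grid, None, duration=round(delay, 1))
    which = int(rng.integers(0, 2))  # bottom or left half-plane
    s2 = StimulusSchedule()
    s2.add(0.0, _STIM_LEN, _half_plane_field(grid.shape, which))
    state = integrate(state, params, grid, s2, duration=_STIM_LEN)

    # optional extra breakup stimuli once enough tissue has recovered
    fired = 0
    t_since = 0.0
    while fired < n_extra and t_since < 2000.0:
        state = integrate(state, params, grid, None, duration=20.0)
        t_since += 20.0
        frac = float((state.u > 0.3).mean())
        if t_since >= 100.0 and 0.05 < frac < 0.35:
            which += 1
            sx = StimulusSchedule()
            sx.add(0.0, _STIM_LEN, _half_plane_field(grid.shape, which))
            state = integrate(state, params, grid, sx, duration=_STIM_LEN)
            fired += 1
            t_since = 0.0

    # burn-in plus a seed-dependent extra span for state diversity
    extra = float(rng.uniform(0.0, 300.0))
    state = integrate(state, params, grid, None, duration=round(burn_in + extra, 1))
    if is_terminated(state):
        return None
    return state


def _dense_attempt(
    params, grid: GridSpec, rng: np.random.Generator, burn_in: float
) -> TissueState | None:
    """One seeded dense random-field attempt; None on failure.

    Smooth random fields seed many wavebreaks at once: thresholded
    filtered noise for the voltage (excited blobs a few mm wide) over
    independently varying gate fields, so fronts fragment immediately
    and the tissue settles into multi-wavelet chaos at short diastolic
    intervals during the burn-in.
    """
    ny, nx = grid.shape

    def smooth(sigma):
        f = ndimage.gaussian_filter(rng.normal(size=(ny, nx)), sigma)
        return (f - f.min()) / (f.max() - f.min())

    u = np.where(smooth(4.0) > rng.uniform(0.58, 0.64), 1.0, 0.0)
    v = smooth(8.0)
    w = 0.3 + 0.7 * smooth(8.0)
    state = TissueState(u, v, w)
    extra = float(rng.uniform(0.0, 300.0))
    state = integrate(state, params, grid, None, duration=round(burn_in + extra, 1))
    if is_terminated(state):
        return None
    return state


def make_fibrillation_ic(
    model,
    seed: int,
    burn_in: float = 2000.0,
    grid: GridSpec | None = None,
    max_attempts: int = 8,
    min_fronts: int = 1,
    scheme: str | None = None,
) -> TissueState:
    """Generate one seeded fibrillation initial condition.

    Two seeded initiation schemes: ``"s1s2"`` (cross-field stimulation:
    plane wave, then a half-plane stimulus timed into the refractory
    tail) and ``"dense"`` (many simultaneous wavebreaks from smooth
    random fields); the per-model default picks whichever reaches that
    model's sustained multi-wavelet regime.  ``burn_in`` ms of free
    evolution follow the initiation.  On failure (quiescent tissue or
    fewer than ``min_fronts`` wavefronts) the attempt is re-randomised,
    up to ``max_attempts`` times.  Identical arguments give
    bitwise-identical states.
    """
    if burn_in < 1000.0:
        raise ValueError("burn_in must be at least 1000 ms")
    params = _resolve(model)
    grid = grid or default_grid(params)
    gen = _GEN_DEFAULTS[params.name]
    scheme = scheme or gen["scheme"]
    for attempt in range(max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed) % 2**31, spawn_key=(attempt,))
        )
        if scheme == "dense":
            state = _dense_attempt(params, grid, rng, burn_in)
        elif scheme == "s1s2":
            state = _one_attempt(
                params, grid, rng, burn_in, gen["n_extra"], gen["jitter"]
            )
        else:
            raise ValueError(f"unknown initiation scheme {scheme!r}")
        if state is not None and count_wavefronts(state) >= min_fronts:
            state.t = 0.0
            return state
    raise RuntimeError(
        f"no sustained fibrillation for {params.name} on {grid.shape} after "
        f"{max_attempts} {scheme} attempts; consider a larger domain or a "
        f"different parameter set"
    )


@dataclass
class EpisodeLibrary:
    """A seeded library of fibrillation initial conditions for one model."""

    model: str
    grid: GridSpec
    states: list[TissueState] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    burn_in: float = 2000.0
    validated: list[bool] = field(default_factory=list)
    validate_ms: float | None = None

    def __len__(self) -> int:
        return len(self.states)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "model": self.model,
            "grid": {"nx": self.grid.nx, "ny": self.grid.ny,
                     "h": self.grid.h, "dt": self.grid.dt},
            "seeds": self.seeds,
            "burn_in": self.burn_in,
            "validated": self.validated,
            "validate_ms": self.validate_ms,
            "n": len(self.states),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for k, st in enumerate(self.states):
            arrays = {"u": st.u, "v": st.v, "w": st.w, "t": np.array(st.t)}
            if st.s is not None:
                arrays["s"] = st.s
            np.savez_compressed(d / f"ic_{k:03d}.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "EpisodeLibrary":
        d = Path(directory)
        mpath = d / "manifest.json"
        if not mpath.exists():
            raise FileNotFoundError(
                f"no episode library at {d}; create one with "
                f"'defibopt episodes make'"
            )
        m = json.loads(mpath.read_text())
        lib = cls(
            model=m["model"],
            grid=GridSpec(**m["grid"]),
            seeds=list(m["seeds"]),
            burn_in=m["burn_in"],
            validated=list(m["validated"]),
            validate_ms=m.get("validate_ms"),
        )
        for k in range(m["n"]):
            with np.load(d / f"ic_{k:03d}.npz") as z:
                lib.states.append(
                    TissueState(
                        z["u"], z["v"], z["w"],
                        z["s"] if "s" in z.files else None,
                        float(z["t"]),
                    )
                )
        return lib


def build_episode_library(
    model,
    n: int = 10,
    seed: int = 0,
    burn_in: float = 2000.0,
    grid: GridSpec | None = None,
    validate_ms: float | None = None,
) -> EpisodeLibrary:
    """Generate ``n`` seeded fibrillation ICs, optionally persistence-checked.

    With ``validate_ms`` set (typically 5 x T_dom), each candidate is
    integrated unperturbed for that span and must stay unterminated;
    failing candidates are replaced by the next seed.  This screens out
    self-terminating episodes so that termination-ratio estimates are
    not biased by spontaneous decay.
    """
    params = _resolve(model)
    grid = grid or default_grid(params)
    lib = EpisodeLibrary(
        model=params.name, grid=grid, burn_in=burn_in, validate_ms=validate_ms
    )
    sub = np.random.SeedSequence(entropy=int(seed) % 2**31).generate_state(8 * n)
    idx = 0
    while len(lib) < n:
        if idx >= len(sub):
            raise RuntimeError(
                f"exhausted seed pool building {params.name} library "
                f"({len(lib)}/{n} valid episodes)"
            )
        ic_seed = int(sub[idx] % 2**31)
        idx += 1
        try:
            state = make_fibrillation_ic(params, ic_seed, burn_in, grid)
        except RuntimeError:
            continue
        ok = True
        if validate_ms is not None:
            horizon = round(round(validate_ms / grid.dt) * grid.dt, 6)
            final = integrate(state, params, grid, None, duration=horizon)
            ok = not is_terminated(final)
        if ok:
            lib.states.append(state)
            lib.seeds.append(ic_seed)
            lib.validated.append(validate_ms is not None)
    return lib


def record_episode(
    model,
    ic: TissueState,
    grid: GridSpec | None = None,
    record_s: float = 10.0,
    rates_hz: tuple[float, ...] = (120.0,),
) -> tuple[dict[float, np.ndarray], TissueState]:
    """Integrate an episode, sampling whole-grid voltage at given rates.

    Returns ``({rate: (n_samples, ny, nx) record}, final_state)``.  A
    single integration serves all requested sampling rates.
    """
    params = _resolve(model)
    grid = grid or default_grid(params)
    samplers = [
        FieldSampler(fs, int(round(record_s * fs))) for fs in rates_hz
    ]
    final = integrate(
        ic, params, grid, None, duration=record_s * 1000.0, observers=tuple(samplers)
    )
    return {fs: s.record for fs, s in zip(rates_hz, samplers)}, final


@dataclass(frozen=True)
class DominantPeriod:
    """Dominant period estimate from per-pixel FFT peak frequencies."""

    t_dom: float  # ms
    mean_freq_hz: float
    freq_quartiles_hz: tuple[float, float, float]
    fs_hz: float
    record_s: float
    n_pixels_used: int


def estimate_dominant_period_from_record(
    record: np.ndarray, fs_hz: float, var_floor: float = 1e-8
) -> DominantPeriod:
    """Per-pixel FFT peak frequencies averaged over active pixels.

    ``record`` has shape (n_samples, ny, nx).  The DC bin is excluded
    from the peak search (the mean voltage offset would otherwise
    dominate) and pixels with time-series variance below ``var_floor``
    are excluded from the average.  T_dom = 1 / mean peak frequency.
    """
    rec = np.asarray(record)
    n = rec.shape[0]
    flat = rec.reshape(n, -1).astype(np.float32).T  # (npix, n)
    active = flat.var(axis=1) > var_floor
    if not active.any():
        raise ValueError("silent record: no pixel shows activity")
    spec = np.abs(np.fft.rfft(flat[active], axis=1))
    peak_bin = 1 + np.argmax(spec[:, 1:], axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    peak_f = freqs[peak_bin]
    mean_f = float(peak_f.mean())
    q = np.percentile(peak_f, [25, 50, 75])
    return DominantPeriod(
        t_dom=1000.0 / mean_f,
        mean_freq_hz=mean_f,
        freq_quartiles_hz=(float(q[0]), float(q[1]), float(q[2])),
        fs_hz=float(fs_hz),
        record_s=n / fs_hz,
        n_pixels_used=int(active.sum()),
    )


def estimate_dominant_period(
    model,
    ic: TissueState,
    grid: GridSpec | None = None,
    record_s: float = 10.0,
    fs_hz: float = 120.0,
) -> DominantPeriod:
    """Record an episode and estimate its dominant period.

    Defaults follow the study conditions: 10 s at 120 samples/s, i.e.
    1200 samples per pixel, 0.1 Hz frequency resolution.
    """
    records, _ = record_episode(model, ic, grid, record_s, (fs_hz,))
    return estimate_dominant_period_from_record(records[fs_hz], fs_hz)
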