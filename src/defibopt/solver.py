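"""Explicit FTCS integration of the cardiac reaction-diffusion system.

The voltage field diffuses on a square grid (spacing ``h``) with
no-flux Neumann boundaries enforced by a one-pixel ghost ring: every
ghost pixel holds a copy of the adjacent edge pixel, so the discrete
normal derivative across the boundary vanishes and the symmetric
stencil conserves total voltage under pure diffusion.  The Laplacian
uses the isotropic 9-point stencil (weights 4 for edge neighbours, 1
for corner neighbours, -20 centre, divided by 6 h^2) at every interior
pixel except the four grid vertices, which fall back to the 5-point
stencil so the undefined ghost-ring corners are never referenced.

Time stepping is forward Euler at a single ``dt`` for voltage and
gates.  The fused compiled kernels in :mod:`defibopt._kernels` carry
the production load; the numpy functions here define the reference
semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .models import BOCFParams, FKParams, TissueState

__all__ = [
    "GridSpec",
    "StimulusEntry",
    "StimulusSchedule",
    "BlowUpError",
    "extend_with_ghosts",
    "laplacian",
    "ftcs_step",
    "integrate",
    "FieldSampler",
    "sample_steps",
    "save_state",
    "load_state",
]


class BlowUpError(RuntimeError):
    """Raised when the explicit integration produces non-finite values."""


@dataclass(frozen=True)
class GridSpec:
    """Square-grid discretisation: pixel counts, spacing (mm), step (ms)."""

    nx: int = 256
    ny: int = 256
    h: float = 1.0
    dt: float = 0.1

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3")
        if self.h <= 0 or self.dt <= 0:
            raise ValueError("h and dt must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def check_stability(self, D: float) -> None:
        """Guard the explicit-scheme bound D*dt/h^2 <= 0.25."""
        ratio = D * self.dt / self.h**2
        if ratio > 0.25:
            raise ValueError(
                f"unstable discretisation: D*dt/h^2 = {ratio:.3g} > 0.25"
            )


@dataclass(frozen=True)
class StimulusEntry:
    """One stimulus window: additive current field active on [onset, offset)."""

    onset: float
    offset: float
    current: np.ndarray

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ValueError("stimulus offset must exceed onset")


@dataclass
class StimulusSchedule:
    """Time-indexed additive stimulus fields (ms windows, a.u./ms currents)."""

    entries: list[StimulusEntry] = field(default_factory=list)

    def add(self, onset: float, offset: float, current: np.ndarray) -> None:
        self.entries.append(StimulusEntry(onset, offset, np.asarray(current, float)))

    def __len__(self) -> int:
        return len(self.entries)


def extend_with_ghosts(field_arr: np.ndarray) -> np.ndarray:
    """Extend a field by one ghost pixel per side enforcing no-flux.

    Each ghost pixel copies the adjacent edge pixel of the original
    grid ("linked" pixels one row/column apart holding the same value).
    The four extension corners are filled with the nearest edge value
    but are never referenced by the stencils.
    """
    f = np.asarray(field_arr)
    if f.shape[0] < 3 or f.shape[1] < 3:
        raise ValueError("field must be at least 3x3")
    return np.pad(f, 1, mode="edge")


def laplacian(ext: np.ndarray, h: float) -> np.ndarray:
    """Discrete Laplacian of a ghost-extended field (un-extended shape).

    9-point isotropic stencil everywhere except the four interior
    vertices, which use the 5-point stencil.
    """
    ext = np.asarray(ext, dtype=float)
    c = ext[1:-1, 1:-1]
    n, s = ext[:-2, 1:-1], ext[2:, 1:-1]
    w_, e = ext[1:-1, :-2], ext[1:-1, 2:]
    nw, ne = ext[:-2, :-2], ext[:-2, 2:]
    sw, se = ext[2:, :-2], ext[2:, 2:]
    lap = (4.0 * (n + s + e + w_) + nw + ne + sw + se - 20.0 * c) / (6.0 * h * h)
    lap5 = (n + s + e + w_ - 4.0 * c) / (h * h)
    for i in (0, -1):
        for j in (0, -1):
            lap[i, j] = lap5[i, j]
    return lap


_table_cache: dict[str, tuple] = {}


def _tables(p) -> tuple:
    """Per-parameter-set voltage lookup tables (built once, cached)."""
    if p.name not in _table_cache:
        if isinstance(p, BOCFParams):
            _table_cache[p.name] = _kernels.bocf_tables(p)
        else:
            _table_cache[p.name] = _kernels.fk_tables(p)
    return _table_cache[p.name]


def _fk_args(p: FKParams) -> tuple:
    return _tables(p) + (
        p.C_m, p.tau_v_plus, p.tau_v1_minus, p.tau_v2_minus, p.tau_w_plus,
        p.tau_w_minus, p.tau_d, p.tau_0, p.tau_r, p.tau_si, p.K, p.u_c_si,
        p.u_c, p.u_v,
    )


def _bocf_args(p: BOCFParams) -> tuple:
    return _tables(p) + (
        p.C_m, p.theta_v, p.theta_v_minus, p.theta_w, p.theta_o,
        p.tau_v_plus, p.tau_v1_minus, p.tau_v2_minus,
        p.tau_w_plus, p.tau_w1_minus, p.tau_w2_minus,
        p.tau_fi, p.tau_o1, p.tau_o2, p.tau_so1, p.tau_so2,
        p.tau_s1, p.tau_s2, p.tau_si,
        p.tau_w_inf, p.w_inf_star, p.k_w_minus, p.k_so, p.k_s,
        p.u_o, p.u_u, p.u_w_minus, p.u_so, p.u_s,
    )


_NO_STIM = np.zeros((1, 1))


def ftcs_step(
    state: TissueState,
    params: FKParams | BOCFParams,
    grid: GridSpec,
    stim_field: np.ndarray | None = None,
    reaction: bool = True,
) -> TissueState:
    """Advance the tissue state by one explicit step of ``grid.dt``.

    ``reaction=False`` is a test hook integrating pure diffusion of the
    voltage field (gates untouched).  Raises :class:`BlowUpError` on
    non-finite output.
    """
    grid.check_stability(params.D)
    if state.shape != grid.shape:
        raise ValueError(f"state shape {state.shape} != grid shape {grid.shape}")
    new = state.copy()
    ue = extend_with_ghosts(np.asarray(state.u, dtype=float))
    un = ue.copy()
    if stim_field is None:
        stim, use_stim = _NO_STIM, False
    else:
        stim = np.ascontiguousarray(stim_field, dtype=float)
        use_stim = True
    if not reaction:
        _kernels.diffusion_step(ue, un, grid.dt, params.D, grid.h)
    elif isinstance(params, BOCFParams):
        _kernels.bocf_step(
            ue, un, new.v, new.w, new.s, stim, use_stim,
            grid.dt, params.D, grid.h, *_bocf_args(params),
        )
    else:
        _kernels.fk_step(
            ue, un, new.v, new.w, stim, use_stim,
            grid.dt, params.D, grid.h, *_fk_args(params),
        )
    new.u = un[1:-1, 1:-1].copy()
    new.t = state.t + grid.dt
    if not np.isfinite(new.u.sum()):
        raise BlowUpError(f"non-finite voltage at t = {new.t:.1f} ms")
    return new


def sample_steps(n_samples: int, fs_hz: float, dt: float) -> np.ndarray:
    """Step indices sampling ``n_samples`` points at ``fs_hz``.

    Uses round-to-nearest accumulated time, so rates that do not divide
    1/dt (e.g. 120 Hz at dt = 0.1 ms) alternate between 83- and 84-step
    gaps.
    """
    times = np.arange(n_samples) * (1000.0 / fs_hz)
    return np.rint(times / dt).astype(np.int64)


def save_state(path, state: TissueState, model: str, grid: GridSpec) -> None:
    """Write a tissue-state snapshot (npz: fields + model/grid metadata)."""
    arrays = {
        "u": state.u, "v": state.v, "w": state.w,
        "t": np.array(state.t),
        "model": np.array(model),
        "grid": np.array([grid.nx, grid.ny, grid.h, grid.dt]),
    }
    if state.s is not None:
        arrays["s"] = state.s
    np.savez_compressed(path, **arrays)


def load_state(path) -> tuple[TissueState, str, GridSpec]:
    """Read a snapshot written by :func:`save_state`."""
    with np.load(path) as z:
        state = TissueState(
            z["u"], z["v"], z["w"],
            z["s"] if "s" in z.files else None,
            float(z["t"]),
        )
        nx, ny, h, dt = z["grid"]
        return state, str(z["model"]), GridSpec(int(nx), int(ny), float(h), float(dt))


class FieldSampler:
    """Observer collecting voltage snapshots at a fixed sampling rate.

    Snapshots are stored as float32 to keep 10 s whole-grid records
    within desk memory; spectral estimates are insensitive to this.
    """

    def __init__(self, fs_hz: float, n_samples: int):
        self.fs_hz = float(fs_hz)
        self.n_samples = int(n_samples)
        self.frames: list[np.ndarray] = []

    def steps(self, dt: float) -> np.ndarray:
        return sample_steps(self.n_samples, self.fs_hz, dt)

    def collect(self, t: float, u: np.ndarray) -> None:
        self.frames.append(u.astype(np.float32))

    @property
    def record(self) -> np.ndarray:
        """(n_samples, ny, nx) voltage record."""
        return np.stack(self.frames)


def integrate(
    state: TissueState,
    params: FKParams | BOCFParams,
    grid: GridSpec,
    schedule: StimulusSchedule | None = None,
    duration: float = 0.0,
    observers: tuple = (),
    check_interval: int = 200,
) -> TissueState:
    """Integrate for ``duration`` ms, applying the stimulus schedule.

    Observers are sampled at their configured step indices (step 0 is
    the input state).  The trajectory is bit-reproducible for identical
    inputs.  Returns the final state.
    """
    grid.check_stability(params.D)
    if state.shape != grid.shape:
        raise ValueError(f"state shape {state.shape} != grid shape {grid.shape}")
    dt = grid.dt
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        warnings.warn(
            f"duration {duration} ms is not a multiple of dt={dt}; "
            f"truncating to {n_steps * dt} ms",
            stacklevel=2,
        )

    new = state.copy()
    ue = extend_with_ghosts(np.asarray(new.u, dtype=float))
    un = ue.copy()
    v, w = np.asarray(new.v, float), np.asarray(new.w, float)
    s = None if new.s is None else np.asarray(new.s, float)
    is_bocf = isinstance(params, BOCFParams)
    pargs = _bocf_args(params) if is_bocf else _fk_args(params)

    # stimulus windows -> [start_step, end_step) with contiguous fields
    windows = []
    if schedule is not None:
        for e in schedule.entries:
            k0 = int(round(e.onset / dt))
            k1 = int(round(e.offset / dt))
            cur = np.ascontiguousarray(e.current, dtype=float)
            if cur.shape != grid.shape:
                raise ValueError("stimulus field shape does not match grid")
            if k1 > k0:
                windows.append((k0, k1, cur))
    windows.sort(key=lambda x: x[0])

    obs_steps = [ob.steps(dt) for ob in observers]
    obs_ptr = [0] * len(observers)

    def notify(step: int, t: float, u_ext: np.ndarray) -> None:
        for k, ob in enumerate(observers):
            st = obs_steps[k]
            while obs_ptr[k] < len(st) and st[obs_ptr[k]] == step:
                ob.collect(t, u_ext[1:-1, 1:-1])
                obs_ptr[k] += 1

    stim_buf = np.zeros(grid.shape)
    active_key: tuple | None = None
    t0 = new.t
    notify(0, t0, ue)
    for step in range(n_steps):
        key = tuple(
            idx for idx, (k0, k1, _) in enumerate(windows) if k0 <= step < k1
        )
        if key != active_key:
            if key:
                stim_buf[:] = 0.0
                for idx in key:
                    stim_buf += windows[idx][2]
            active_key = key
        use_stim = bool(key)

        if is_bocf:
            _kernels.bocf_step(
                ue, un, v, w, s, stim_buf, use_stim, dt, params.D, grid.h, *pargs
            )
        else:
            _kernels.fk_step(
                ue, un, v, w, stim_buf, use_stim, dt, params.D, grid.h, *pargs
            )
        ue, un = un, ue
        t = t0 + (step + 1) * dt
        notify(step + 1, t, ue)
        if (step + 1) % check_interval == 0 and not np.isfinite(
            ue[1:-1, 1:-1].sum()
        ):
            raise BlowUpError(f"non-finite voltage at t = {t:.1f} ms")

    new.u = ue[1:-1, 1:-1].copy()
    new.v, new.w = v, w
    if s is not None:
        new.s = s
    new.t = t0 + n_steps * dt
    if not np.isfinite(new.u.sum()):
        raise BlowUpError(f"non-finite voltage at t = {new.t:.1f} ms")
    return new
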