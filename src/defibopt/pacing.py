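"""Pacing protocols, injection sites, and the PC / TR protocol metrics.

A monophasic N-pulse protocol has N non-negative amplitudes and N-1
onset-to-onset inter-pulse intervals at a uniform 2 ms pulse length
(2N-1 free parameters).  Pulses are delivered through randomly placed,
non-overlapping 3x3-pixel injection sites, each with a uniform(0,1)
efficacy coefficient standing in for the geometry- and
orientation-dependent recruitment of virtual electrodes in real
tissue.  The default site counts (2000 on 256^2, 8000 on 512^2) give
~28% coverage.

Protocol metrics:

* pacing cost  PC = sum_k amplitude_k^2 * pulse_len  (a.u.)
* termination ratio  TR = terminated attempts / all attempts over a
  fixed library of fibrillation initial conditions crossed with several
  seeded site distributions (5 x 10 = 50 binary samples by default).

A termination attempt integrates through the full protocol, continues
unperturbed for 5 x T_dom after the final pulse offset, and applies the
max(u) < 0.05 criterion once at that horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .episodes import EpisodeLibrary, is_terminated
from .models import TissueState, load_parameter_set
from .solver import GridSpec, StimulusSchedule, integrate

__all__ = [
    "PacingProtocol",
    "InjectionSiteMap",
    "AttemptResult",
    "place_sites",
    "build_schedule",
    "attempt_termination",
    "pacing_cost",
    "termination_ratio",
    "default_n_sites",
]


@dataclass(frozen=True)
class PacingProtocol:
    """N pulse amplitudes (a.u.) and N-1 onset-to-onset intervals (ms)."""

    amplitudes: tuple[float, ...]
    intervals: tuple[float, ...]
    pulse_len: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        object.__setattr__(self, "intervals", tuple(float(i) for i in self.intervals))
        if self.n_pulses < 1:
            raise ValueError("protocol needs at least one pulse")
        if len(self.intervals) != self.n_pulses - 1:
            raise ValueError(
                f"{self.n_pulses} pulses require {self.n_pulses - 1} intervals, "
                f"got {len(self.intervals)}"
            )
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative (monophasic)")
        if any(i <= self.pulse_len for i in self.intervals):
            raise ValueError("intervals must exceed the pulse length")

    @property
    def n_pulses(self) -> int:
        return len(self.amplitudes)

    @property
    def n_params(self) -> int:
        return 2 * self.n_pulses - 1

    @property
    def onsets(self) -> tuple[float, ...]:
        """Pulse onset times, first pulse at t = 0."""
        return tuple(np.concatenate([[0.0], np.cumsum(self.intervals)]))

    @property
    def duration(self) -> float:
        """Time from first onset to final pulse offset (ms)."""
        return self.onsets[-1] + self.pulse_len

    def as_vector(self) -> np.ndarray:
        """Flat parameter vector: N amplitudes then N-1 intervals."""
        return np.array(self.amplitudes + self.intervals)

    @classmethod
    def from_vector(cls, vec, n_pulses: int, pulse_len: float = 2.0) -> "PacingProtocol":
        vec = np.asarray(vec, float)
        if vec.size != 2 * n_pulses - 1:
            raise ValueError("parameter vector has wrong length")
        return cls(tuple(vec[:n_pulses]), tuple(vec[n_pulses:]), pulse_len)

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "amplitudes": list(self.amplitudes),
                    "intervals": list(self.intervals),
                    "pulse_len": self.pulse_len,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path) -> "PacingProtocol":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["amplitudes"]), tuple(d["intervals"]), d["pulse_len"])


def default_n_sites(grid: GridSpec) -> int:
    """Site count giving ~28% coverage: 2000 on 256^2, 8000 on 512^2."""
    return round(0.275 * grid.nx * grid.ny / 9.0 / 100) * 100 or 1


@dataclass(frozen=True)
class InjectionSiteMap:
    """Non-overlapping 3x3 injection sites with per-site efficacies."""

    anchors: np.ndarray  # (n_sites, 2) top-left row/col, 0-based
    efficacies: np.ndarray  # (n_sites,) in [0, 1]
    grid_shape: tuple[int, int]
    seed: int

    @property
    def n_sites(self) -> int:
        return len(self.anchors)

    @property
    def coverage(self) -> float:
        ny, nx = self.grid_shape
        return 9.0 * self.n_sites / (nx * ny)

    def efficacy_field(self) -> np.ndarray:
        """Grid with each site's 3x3 block set to its efficacy, 0 elsewhere."""
        f = np.zeros(self.grid_shape)
        for (r, c), e in zip(self.anchors, self.efficacies):
            f[r : r + 3, c : c + 3] = e
        return f


def place_sites(grid_shape: tuple[int, int], n_sites: int, seed: int) -> InjectionSiteMap:
    """Rejection-sample ``n_sites`` non-overlapping 3x3 blocks.

    Efficacies are drawn uniform(0, 1), one per site.  Deterministic
    under ``seed``.  Raises if the requested density is infeasible
    (more than 90% of the grid) or placement stalls.
    """
    ny, nx = grid_shape
    if 9 * n_sites > 0.9 * nx * ny:
        raise ValueError(
            f"{n_sites} sites of 9 px exceed 90% of a {ny}x{nx} grid"
        )
    rng = np.random.default_rng(seed)
    # a site anchored at (r, c) blocks anchors within Chebyshev distance 2
    forbidden = np.zeros((ny - 2, nx - 2), dtype=bool)
    anchors = np.empty((n_sites, 2), dtype=np.int64)
    placed = 0
    attempts = 0
    max_attempts = 300 * n_sites + 1000
    while placed < n_sites:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"site placement stalled after {attempts} attempts "
                f"({placed}/{n_sites} placed)"
            )
        r = int(rng.integers(0, ny - 2))
        c = int(rng.integers(0, nx - 2))
        if forbidden[r, c]:
            continue
        anchors[placed] = (r, c)
        placed += 1
        forbidden[max(0, r - 2) : r + 3, max(0, c - 2) : c + 3] = True
    efficacies = rng.uniform(0.0, 1.0, size=n_sites)
    return InjectionSiteMap(anchors, efficacies, (ny, nx), int(seed))


def build_schedule(protocol: PacingProtocol, sites: InjectionSiteMap) -> StimulusSchedule:
    """Stimulus schedule delivering the protocol through the site map.

    Pulse k is active on [t_k, t_k + pulse_len) with current
    amplitude_k x efficacy_j inside site j and zero elsewhere.
    """
    eff = sites.efficacy_field()
    sched = StimulusSchedule()
    for amp, onset in zip(protocol.amplitudes, protocol.onsets):
        sched.add(onset, onset + protocol.pulse_len, amp * eff)
    return sched


@dataclass(frozen=True)
class AttemptResult:
    """Outcome of one termination attempt."""

    success: bool
    final_pulse_offset: float  # ms, relative to attempt start
    horizon: float  # ms of post-pacing observation (5 x T_dom)
    max_u_at_horizon: float


def attempt_termination(
    model,
    ic: TissueState,
    sites: InjectionSiteMap,
    protocol: PacingProtocol,
    t_dom: float,
    grid: GridSpec | None = None,
) -> AttemptResult:
    """Run one defibrillation attempt and apply the binary criterion.

    Integrates through the full protocol, continues unperturbed for
    5 x T_dom after the final pulse offset, then checks
    max(u) < 0.05 a.u. once at that horizon.
    """
    params = load_parameter_set(model) if isinstance(model, str) else model
    if grid is None:
        ny, nx = ic.shape
        grid = GridSpec(nx, ny)
    horizon = 5.0 * t_dom
    sched = build_schedule(protocol, sites)
    duration = protocol.duration + horizon
    duration = round(round(duration / grid.dt) * grid.dt, 6)
    final = integrate(ic, params, grid, sched, duration=duration)
    return AttemptResult(
        success=is_terminated(final),
        final_pulse_offset=protocol.duration,
        horizon=horizon,
        max_u_at_horizon=float(final.u.max()),
    )


def pacing_cost(protocol: PacingProtocol) -> float:
    """PC = sum of squared pulse amplitudes integrated over pulse length."""
    return float(sum(a * a for a in protocol.amplitudes) * protocol.pulse_len)


def termination_ratio(
    protocol: PacingProtocol,
    library: EpisodeLibrary,
    t_dom: float,
    n_distributions: int = 5,
    seed: int = 0,
    n_sites: int | None = None,
) -> tuple[float, int, int]:
    """TR over the IC library crossed with seeded site distributions.

    Each (IC, distribution) pair contributes exactly one binary sample;
    site maps are frozen within an attempt and resampled (with fresh
    efficacies) across the ``n_distributions`` repetitions.  Returns
    ``(tr, successes, attempts)`` so the exact rational is available
    alongside the float.
    """
    if len(library) == 0:
        raise ValueError("episode library is empty")
    params = load_parameter_set(library.model)
    grid = library.grid
    if n_sites is None:
        n_sites = default_n_sites(grid)
    dist_seeds = np.random.SeedSequence(entropy=int(seed) % 2**31).generate_state(
        n_distributions
    )
    successes = 0
    attempts = 0
    for ds in dist_seeds:
        sites = place_sites(grid.shape, n_sites, int(ds % 2**31))
        for ic in library.states:
            res = attempt_termination(params, ic, sites, protocol, t_dom, grid)
            successes += int(res.success)
            attempts += 1
    return successes / attempts, successes, attempts
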