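"""Spectrum-guided adaptive-deceleration pacing (ADP) reference protocols.

ADP protocols have uniform pulse amplitudes and inter-pulse periods
that grow from pulse to pulse.  The periods come from the fibrillating
tissue's own frequency content: the pixel-averaged squared-magnitude
Fourier spectrum of a long voltage record (10 s sampled every 10 ms)
is cumulatively integrated up to a cutoff frequency, the normalised
integral is split into equal parts — one per pulse — and the
reciprocal boundary frequencies, sorted ascending, are the inter-pulse
periods.  Faster spectral content thus paces early pulses and slower
content the later ones, decelerating the train.

The uniform amplitude stays free; a dose-response curve of termination
ratio against amplitude (equivalently pacing cost) then fixes it at
the desired TR level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .episodes import EpisodeLibrary
from .pacing import PacingProtocol, pacing_cost, termination_ratio

__all__ = [
    "PowerSpectrum",
    "ADPProtocolSpec",
    "DEFAULT_CUTOFFS_HZ",
    "mean_power_spectrum",
    "adp_intervals",
    "derive_adp_spec",
    "dose_response",
    "pc_threshold_at_tr",
]

#: Cutoff frequencies used for the reference protocols of each model.
DEFAULT_CUTOFFS_HZ = {"FK1": 15.0, "FK2": 15.0, "FK3": 33.0, "BOCF": 6.0}


@dataclass(frozen=True)
class PowerSpectrum:
    """Pixel-averaged squared-magnitude Fourier spectrum."""

    freqs_hz: np.ndarray
    power: np.ndarray
    record_s: float
    sampling_ms: float

    def __post_init__(self):
        if (self.power < 0).any():
            raise ValueError("power values must be non-negative")

    @property
    def df(self) -> float:
        """Frequency resolution (Hz) = 1 / record length."""
        return 1.0 / self.record_s


@dataclass(frozen=True)
class ADPProtocolSpec:
    """An ADP timing spec: derived intervals plus a free uniform amplitude."""

    cutoff_hz: float
    n_pulses: int
    intervals: tuple[float, ...]  # ms, ascending

    def protocol(self, amplitude: float, pulse_len: float = 2.0) -> PacingProtocol:
        return PacingProtocol(
            (float(amplitude),) * self.n_pulses, self.intervals, pulse_len
        )


def mean_power_spectrum(
    record: np.ndarray, sampling_ms: float = 10.0, var_floor: float = 1e-8
) -> PowerSpectrum:
    """Per-pixel |FFT|^2 averaged over active pixels.

    ``record`` has shape (n_samples, ny, nx) sampled every
    ``sampling_ms``; at least a 10 s record is required so that the
    0.1 Hz resolution of the reference protocols is met.  Flat pixels
    (variance below ``var_floor``) are excluded from the average.
    """
    rec = np.asarray(record)
    n = rec.shape[0]
    record_s = n * sampling_ms / 1000.0
    if record_s < 10.0 - 1e-9:
        raise ValueError(
            f"record of {record_s:.2f} s is too short; at least 10 s needed"
        )
    flat = rec.reshape(n, -1).astype(np.float32).T
    active = flat.var(axis=1) > var_floor
    if not active.any():
        raise ValueError("silent record: no pixel shows activity")
    power = (np.abs(np.fft.rfft(flat[active], axis=1)) ** 2).mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=sampling_ms / 1000.0)
    return PowerSpectrum(freqs, power.astype(float), record_s, float(sampling_ms))


def adp_intervals(
    spectrum: PowerSpectrum, cutoff_hz: float, n_pulses: int
) -> tuple[float, ...]:
    """Equal-partition the cumulative spectral mass below the cutoff.

    The cumulative integral of the power over (0, cutoff] (DC excluded)
    is normalised to [0, 1]; the n_pulses - 1 boundary frequencies at
    levels k / n_pulses are located by linear interpolation between
    frequency bins, and their reciprocal periods are returned sorted
    ascending (deceleration: shortest interval first).
    """
    if n_pulses < 2:
        raise ValueError("need at least 2 pulses for inter-pulse intervals")
    f = spectrum.freqs_hz
    if cutoff_hz <= 0 or cutoff_hz > f[-1]:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz outside spectrum range (0, {f[-1]:.3g}]"
        )
    mask = (f > 0) & (f <= cutoff_hz)
    pf = f[mask]
    pw = spectrum.power[mask]
    total = pw.sum()
    if total <= 0:
        raise ValueError("zero spectral mass below the cutoff frequency")
    cum = np.cumsum(pw) / total
    # piecewise-linear cumulative mass anchored at 0 just below the first bin
    xs = np.concatenate([[pf[0] - spectrum.df], pf])
    ys = np.concatenate([[0.0], cum])
    levels = np.arange(1, n_pulses) / n_pulses
    bounds_hz = np.interp(levels, ys, xs)
    periods = np.sort(1000.0 / bounds_hz)
    return tuple(float(p) for p in periods)


def derive_adp_spec(
    spectrum: PowerSpectrum, cutoff_hz: float, n_pulses: int = 5
) -> ADPProtocolSpec:
    """Convenience wrapper returning an :class:`ADPProtocolSpec`."""
    return ADPProtocolSpec(
        cutoff_hz=float(cutoff_hz),
        n_pulses=int(n_pulses),
        intervals=adp_intervals(spectrum, cutoff_hz, n_pulses),
    )


def dose_response(
    model,
    adp_spec: ADPProtocolSpec,
    amplitudes,
    library: EpisodeLibrary,
    t_dom: float,
    n_distributions: int = 5,
    seed: int = 0,
    n_sites: int | None = None,
) -> pd.DataFrame:
    """TR as a function of the uniform amplitude of an ADP protocol.

    Returns a table with columns amplitude, pc, successes, attempts,
    tr.  Site-distribution seeds are shared across amplitudes so the
    curve varies only through the protocol.
    """
    amplitudes = np.sort(np.asarray(amplitudes, float))
    rows = []
    for a in amplitudes:
        proto = adp_spec.protocol(a)
        tr, succ, att = termination_ratio(
            proto, library, t_dom, n_distributions, seed, n_sites
        )
        rows.append((a, pacing_cost(proto), succ, att, tr))
    return pd.DataFrame(
        rows, columns=["amplitude", "pc", "successes", "attempts", "tr"]
    )


def pc_threshold_at_tr(curve: pd.DataFrame, level: float) -> float:
    """Smallest sampled PC whose TR reaches the level (no interpolation).

    Returns NaN when the level is never attained on the sampled grid.
    """
    hit = curve[curve["tr"] >= level]
    if hit.empty:
        return float("nan")
    return float(hit["pc"].min())
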