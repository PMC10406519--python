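"""Phenomenological cardiac-tissue models: Fenton-Karma and Bueno-Orovio.

Both models describe the transmembrane potential ``u`` of a homogeneous
2D tissue sheet together with dimensionless ion-channel gating variables
(``v``, ``w`` for Fenton-Karma; ``v``, ``w``, ``s`` for Bueno-Orovio).
The reaction term is a sum of three intrinsic currents — fast inward
(``I_fi``), slow outward (``I_so``) and slow inward (``I_si``) — plus an
external stimulation current.  Voltages are normalised so that the
resting state is ``u = 0`` for every parameter set.

This module holds the named parameter sets (shipped as one YAML file per
set under :mod:`defibopt.params`), the reaction-term reference
implementations used by tests and single-cell integrations, and the
resting states.  The tissue solver uses fused compiled kernels in
:mod:`defibopt._kernels` that are cross-checked against the functions
here.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "FKParams",
    "BOCFParams",
    "TissueState",
    "MODEL_NAMES",
    "load_parameter_set",
    "fk_reaction",
    "bocf_reaction",
    "resting_state",
]

MODEL_NAMES = ("FK1", "FK2", "FK3", "BOCF")


def _heaviside(x):
    """Heaviside step with the H(0) = 1 convention used throughout."""
    return np.where(np.asarray(x) >= 0.0, 1.0, 0.0)


@dataclass(frozen=True)
class FKParams:
    """One named Fenton-Karma parameter set.

    Time constants are in ms, the diffusion constant ``D`` in mm^2/ms,
    thresholds in a.u. and the slope ``K`` in 1/a.u.  ``tau_0``,
    ``tau_r`` and ``tau_si`` are printed with mixed units in the source
    table; they all act as the time-constant denominators of the
    standard current formulas here.
    """

    name: str
    D: float
    C_m: float
    tau_v_plus: float
    tau_v1_minus: float
    tau_v2_minus: float
    tau_w_plus: float
    tau_w_minus: float
    tau_d: float
    tau_0: float
    tau_r: float
    tau_si: float
    K: float
    u_c_si: float
    u_c: float
    u_v: float

    def __post_init__(self):
        for f in fields(self):
            if f.name == "name":
                continue
            val = getattr(self, f.name)
            if f.name.startswith(("tau_", "C_m", "D")) and val <= 0:
                raise ValueError(f"{self.name}: {f.name} must be > 0, got {val}")
        if not (0.0 < self.u_v < self.u_c < 1.0):
            raise ValueError(
                f"{self.name}: thresholds must satisfy 0 < u_v < u_c < 1"
            )

    @property
    def gate_names(self) -> tuple[str, ...]:
        return ("v", "w")


@dataclass(frozen=True)
class BOCFParams:
    """The Bueno-Orovio minimal ventricular model parameter set."""

    name: str
    D: float
    C_m: float
    theta_v: float
    theta_v_minus: float
    theta_w: float
    theta_o: float
    tau_v_plus: float
    tau_v1_minus: float
    tau_v2_minus: float
    tau_w_plus: float
    tau_w1_minus: float
    tau_w2_minus: float
    tau_fi: float
    tau_o1: float
    tau_o2: float
    tau_so1: float
    tau_so2: float
    tau_s1: float
    tau_s2: float
    tau_si: float
    tau_w_inf: float
    w_inf_star: float
    k_w_minus: float
    k_so: float
    k_s: float
    u_o: float
    u_u: float
    u_w_minus: float
    u_so: float
    u_s: float

    def __post_init__(self):
        for f in fields(self):
            if f.name.startswith("tau_") and getattr(self, f.name) <= 0:
                raise ValueError(f"{self.name}: {f.name} must be > 0")
        if not (0.0 <= self.u_o < self.theta_w < self.theta_v < self.u_u):
            raise ValueError(
                f"{self.name}: need 0 <= u_o < theta_w < theta_v < u_u"
            )

    @property
    def gate_names(self) -> tuple[str, ...]:
        return ("v", "w", "s")


@dataclass
class TissueState:
    """Voltage and gate fields on a rectangular grid at one time point.

    All fields share one shape; gates live in [0, 1].  ``s`` is ``None``
    for the Fenton-Karma models.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    s: np.ndarray | None = None
    t: float = 0.0

    def __post_init__(self):
        shapes = {f.shape for f in self.fields()}
        if len(shapes) != 1:
            raise ValueError(f"state fields have mismatched shapes: {shapes}")

    def fields(self) -> list[np.ndarray]:
        out = [self.u, self.v, self.w]
        if self.s is not None:
            out.append(self.s)
        return out

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def copy(self) -> "TissueState":
        return TissueState(
            self.u.copy(),
            self.v.copy(),
            self.w.copy(),
            None if self.s is None else self.s.copy(),
            self.t,
        )


def load_parameter_set(name: str) -> FKParams | BOCFParams:
    """Load one of the named parameter sets (FK1, FK2, FK3, BOCF).

    Values come from the versioned YAML files shipped with the package
    and are returned as an immutable dataclass.
    """
    if name not in MODEL_NAMES:
        raise ValueError(
            f"unknown parameter set {name!r}; valid sets are {', '.join(MODEL_NAMES)}"
        )
    text = resources.files("defibopt.params").joinpath(f"{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    kind = raw.pop("model")
    cls = FKParams if kind == "FK" else BOCFParams
    return cls(**raw)


def resting_state(params: FKParams | BOCFParams, shape: tuple[int, int]) -> TissueState:
    """Spatially uniform resting state (a fixed point of the reaction).

    For the Bueno-Orovio model the s-gate rests at its equilibrium
    s_inf(0) = (1 + tanh(-k_s u_s)) / 2 (about 0.02), the exact fixed
    point of the printed s-equation at u = 0.
    """
    u = np.zeros(shape)
    v = np.ones(shape)
    w = np.ones(shape)
    if isinstance(params, BOCFParams):
        s_rest = 0.5 * (1.0 + np.tanh(params.k_s * (0.0 - params.u_s)))
        return TissueState(u, v, w, s=np.full(shape, s_rest), t=0.0)
    return TissueState(u, v, w, t=0.0)


def _check_shapes(*arrs):
    shapes = {np.asarray(a).shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"field shape mismatch: {shapes}")


def fk_reaction(u, v, w, p: FKParams, I_stim=0.0):
    """Fenton-Karma reaction terms (no diffusion).

    Currents (standard three-current forms; H = Heaviside, H(0) = 1)::

        I_fi = -(v / tau_d)  H(u - u_c) (1 - u)(u - u_c)
        I_so =  (u / tau_0)  H(u_c - u) + H(u - u_c) / tau_r
        I_si = -(w / (2 tau_si)) (1 + tanh(K (u - u_c_si)))

    ``du/dt = -(I_fi + I_so + I_si)/C_m + I_stim/C_m``: a positive
    stimulus depolarises.  Gate dynamics are Heaviside-gated relaxations
    with the voltage-dependent ``tau_v_minus`` switching at ``u_v``.

    Returns ``(du_dt, dv_dt, dw_dt)``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    I_stim = np.broadcast_to(np.asarray(I_stim, dtype=float), u.shape)
    _check_shapes(u, v, w)

    above = _heaviside(u - p.u_c)       # H(u - u_c)
    below = 1.0 - above                 # H(u_c - u), consistent split at u_c
    I_fi = -(v / p.tau_d) * above * (1.0 - u) * (u - p.u_c)
    I_so = (u / p.tau_0) * below + above / p.tau_r
    I_si = -(w / (2.0 * p.tau_si)) * (1.0 + np.tanh(p.K * (u - p.u_c_si)))
    du = -(I_fi + I_so + I_si) / p.C_m + I_stim / p.C_m

    tau_v_minus = np.where(u >= p.u_v, p.tau_v1_minus, p.tau_v2_minus)
    dv = below * (1.0 - v) / tau_v_minus - above * v / p.tau_v_plus
    dw = below * (1.0 - w) / p.tau_w_minus - above * w / p.tau_w_plus
    return du, dv, dw


def bocf_reaction(u, v, w, s, p: BOCFParams, I_stim=0.0):
    """Bueno-Orovio minimal-model reaction terms (no diffusion).

    Uses the minimal-model currents with voltage-switching time
    constants and infinity functions::

        I_fi = -v H(u - theta_v) (u - theta_v)(u_u - u) / tau_fi
        I_so =  (u - u_o)(1 - H(u - theta_w)) / tau_o(u)
                + H(u - theta_w) / tau_so(u)
        I_si = -H(u - theta_w) w s / tau_si

    with ``tau_o``, ``tau_so``, ``tau_s``, ``tau_v_minus``,
    ``tau_w_minus`` switching/blending in ``u``, and ``v_inf``,
    ``w_inf`` as target values.  Returns ``(du, dv, dw, ds)``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    s = np.asarray(s, dtype=float)
    I_stim = np.broadcast_to(np.asarray(I_stim, dtype=float), u.shape)
    _check_shapes(u, v, w, s)

    H_v = _heaviside(u - p.theta_v)
    H_w = _heaviside(u - p.theta_w)
    H_o = _heaviside(u - p.theta_o)
    H_vm = _heaviside(u - p.theta_v_minus)

    tau_v_minus = (1.0 - H_vm) * p.tau_v1_minus + H_vm * p.tau_v2_minus
    tau_w_minus = p.tau_w1_minus + (p.tau_w2_minus - p.tau_w1_minus) * 0.5 * (
        1.0 + np.tanh(p.k_w_minus * (u - p.u_w_minus))
    )
    tau_so = p.tau_so1 + (p.tau_so2 - p.tau_so1) * 0.5 * (
        1.0 + np.tanh(p.k_so * (u - p.u_so))
    )
    tau_s = (1.0 - H_w) * p.tau_s1 + H_w * p.tau_s2
    tau_o = (1.0 - H_o) * p.tau_o1 + H_o * p.tau_o2

    v_inf = np.where(u < p.theta_v_minus, 1.0, 0.0)
    w_inf = (1.0 - H_o) * (1.0 - u / p.tau_w_inf) + H_o * p.w_inf_star

    I_fi = -v * H_v * (u - p.theta_v) * (p.u_u - u) / p.tau_fi
    I_so = (u - p.u_o) * (1.0 - H_w) / tau_o + H_w / tau_so
    I_si = -H_w * w * s / p.tau_si
    du = -(I_fi + I_so + I_si) / p.C_m + I_stim / p.C_m

    dv = (1.0 - H_v) * (v_inf - v) / tau_v_minus - H_v * v / p.tau_v_plus
    dw = (1.0 - H_w) * (w_inf - w) / tau_w_minus - H_w * w / p.tau_w_plus
    ds = (0.5 * (1.0 + np.tanh(p.k_s * (u - p.u_s))) - s) / tau_s
    return du, dv, dw, ds
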