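"""Fused numba kernels for one explicit FTCS step.

Each kernel refreshes the no-flux ghost ring of the extended voltage
grid, evaluates the 9-point Laplacian (5-point at the four interior
vertices), adds the model reaction and stimulus, and writes the updated
voltage into a second extended buffer while updating gates in place.
Gates are clamped to [0, 1] after the Euler update.

Every transcendental in both reaction terms is a univariate function
of the voltage, so the tanh-based factors are evaluated through dense
piecewise-linear tables (65536 points over u in [-4, 6], clamped and
saturating outside): this is the dominant per-step cost and the table
agrees with the exact expression to ~1e-7, far below the O(dt)
discretisation error.  The pure-numpy reference path lives in
:mod:`defibopt.models` / :mod:`defibopt.solver`; the test suite
asserts the two agree.
"""

from __future__ import annotations

import numba
import numpy as np

_jit = numba.njit(cache=True, fastmath=True, boundscheck=False)

#: Voltage-table range and resolution shared by all lookup tables.
TAB_LO = -4.0
TAB_HI = 6.0
TAB_N = 65536
TAB_INV_DU = TAB_N / (TAB_HI - TAB_LO)

_tab_u = np.linspace(TAB_LO, TAB_HI, TAB_N + 1)


def fk_tables(p) -> tuple[np.ndarray]:
    """(1 + tanh(K (u - u_c_si))) tabulated over the voltage range."""
    return (1.0 + np.tanh(p.K * (_tab_u - p.u_c_si)),)


def bocf_tables(p) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """tau_w_minus(u), tau_so(u) and s_inf(u) tables."""
    tau_wm = p.tau_w1_minus + (p.tau_w2_minus - p.tau_w1_minus) * 0.5 * (
        1.0 + np.tanh(p.k_w_minus * (_tab_u - p.u_w_minus))
    )
    tau_so = p.tau_so1 + (p.tau_so2 - p.tau_so1) * 0.5 * (
        1.0 + np.tanh(p.k_so * (_tab_u - p.u_so))
    )
    s_inf = 0.5 * (1.0 + np.tanh(p.k_s * (_tab_u - p.u_s)))
    return tau_wm, tau_so, s_inf


@_jit
def _lut(tab, u):
    """Piecewise-linear table lookup, clamped to the table range."""
    x = (u - TAB_LO) * TAB_INV_DU
    if x <= 0.0:
        return tab[0]
    if x >= TAB_N:
        return tab[TAB_N]
    ix = int(x)
    fr = x - ix
    return tab[ix] * (1.0 - fr) + tab[ix + 1] * fr


@_jit
def refresh_ghosts(ue):
    """Copy edge pixels into the ghost ring (no-flux boundary)."""
    ny2, nx2 = ue.shape
    for j in range(1, nx2 - 1):
        ue[0, j] = ue[1, j]
        ue[ny2 - 1, j] = ue[ny2 - 2, j]
    for i in range(1, ny2 - 1):
        ue[i, 0] = ue[i, 1]
        ue[i, nx2 - 1] = ue[i, nx2 - 2]
    # corners are never referenced by the stencils; keep them finite
    ue[0, 0] = ue[1, 1]
    ue[0, nx2 - 1] = ue[1, nx2 - 2]
    ue[ny2 - 1, 0] = ue[ny2 - 2, 1]
    ue[ny2 - 1, nx2 - 1] = ue[ny2 - 2, nx2 - 2]


@_jit
def _lap(ue, I, J, vertex, inv_h2, inv_6h2):
    if vertex:
        return (
            ue[I - 1, J] + ue[I + 1, J] + ue[I, J - 1] + ue[I, J + 1]
            - 4.0 * ue[I, J]
        ) * inv_h2
    return (
        4.0 * (ue[I - 1, J] + ue[I + 1, J] + ue[I, J - 1] + ue[I, J + 1])
        + ue[I - 1, J - 1] + ue[I - 1, J + 1]
        + ue[I + 1, J - 1] + ue[I + 1, J + 1]
        - 20.0 * ue[I, J]
    ) * inv_6h2


@_jit
def diffusion_step(ue, un, dt, D, h):
    """Pure-diffusion FTCS step (reaction disabled test hook)."""
    refresh_ghosts(ue)
    ny, nx = ue.shape[0] - 2, ue.shape[1] - 2
    inv_h2 = 1.0 / (h * h)
    inv_6h2 = inv_h2 / 6.0
    for i in range(ny):
        for j in range(nx):
            vertex = (i == 0 or i == ny - 1) and (j == 0 or j == nx - 1)
            lap = _lap(ue, i + 1, j + 1, vertex, inv_h2, inv_6h2)
            un[i + 1, j + 1] = ue[i + 1, j + 1] + dt * D * lap


@_jit
def fk_step(
    ue, un, v, w, stim, use_stim, dt, D, h, si_tab,
    C_m, tau_v_plus, tau_v1_minus, tau_v2_minus, tau_w_plus, tau_w_minus,
    tau_d, tau_0, tau_r, tau_si, K, u_c_si, u_c, u_v,
):
    refresh_ghosts(ue)
    ny, nx = v.shape
    inv_h2 = 1.0 / (h * h)
    inv_6h2 = inv_h2 / 6.0
    inv_Cm = 1.0 / C_m
    for i in range(ny):
        top = i == 0 or i == ny - 1
        for j in range(nx):
            vertex = top and (j == 0 or j == nx - 1)
            I = i + 1
            J = j + 1
            u = ue[I, J]
            lap = _lap(ue, I, J, vertex, inv_h2, inv_6h2)

            vi = v[i, j]
            wi = w[i, j]
            if u >= u_c:
                I_fi = -(vi / tau_d) * (1.0 - u) * (u - u_c)
                I_so = 1.0 / tau_r
                dv = -vi / tau_v_plus
                dw = -wi / tau_w_plus
            else:
                I_fi = 0.0
                I_so = u / tau_0
                tvm = tau_v1_minus if u >= u_v else tau_v2_minus
                dv = (1.0 - vi) / tvm
                dw = (1.0 - wi) / tau_w_minus
            I_si = -(wi / (2.0 * tau_si)) * _lut(si_tab, u)

            du = -(I_fi + I_so + I_si) * inv_Cm
            if use_stim:
                du += stim[i, j] * inv_Cm

            un[I, J] = u + dt * (D * lap + du)
            vn = vi + dt * dv
            wn = wi + dt * dw
            v[i, j] = min(max(vn, 0.0), 1.0)
            w[i, j] = min(max(wn, 0.0), 1.0)


@_jit
def bocf_step(
    ue, un, v, w, s, stim, use_stim, dt, D, h,
    tau_wm_tab, tau_so_tab, s_inf_tab,
    C_m, theta_v, theta_v_minus, theta_w, theta_o,
    tau_v_plus, tau_v1_minus, tau_v2_minus,
    tau_w_plus, tau_w1_minus, tau_w2_minus,
    tau_fi, tau_o1, tau_o2, tau_so1, tau_so2, tau_s1, tau_s2, tau_si,
    tau_w_inf, w_inf_star, k_w_minus, k_so, k_s,
    u_o, u_u, u_w_minus, u_so, u_s,
):
    refresh_ghosts(ue)
    ny, nx = v.shape
    inv_h2 = 1.0 / (h * h)
    inv_6h2 = inv_h2 / 6.0
    inv_Cm = 1.0 / C_m
    for i in range(ny):
        top = i == 0 or i == ny - 1
        for j in range(nx):
            vertex = top and (j == 0 or j == nx - 1)
            I = i + 1
            J = j + 1
            u = ue[I, J]
            lap = _lap(ue, I, J, vertex, inv_h2, inv_6h2)

            vi = v[i, j]
            wi = w[i, j]
            si = s[i, j]

            above_w = u >= theta_w
            tau_s_u = tau_s2 if above_w else tau_s1
            tau_o_u = tau_o2 if u >= theta_o else tau_o1

            if u >= theta_v:
                I_fi = -vi * (u - theta_v) * (u_u - u) / tau_fi
                dv = -vi / tau_v_plus
            else:
                I_fi = 0.0
                tvm = tau_v2_minus if u >= theta_v_minus else tau_v1_minus
                v_inf = 1.0 if u < theta_v_minus else 0.0
                dv = (v_inf - vi) / tvm

            if above_w:
                I_so = 1.0 / _lut(tau_so_tab, u)
                I_si = -wi * si / tau_si
                dw = -wi / tau_w_plus
            else:
                I_so = (u - u_o) / tau_o_u
                I_si = 0.0
                if u >= theta_o:
                    w_inf = w_inf_star
                else:
                    w_inf = 1.0 - u / tau_w_inf
                dw = (w_inf - wi) / _lut(tau_wm_tab, u)

            ds = (_lut(s_inf_tab, u) - si) / tau_s_u

            du = -(I_fi + I_so + I_si) * inv_Cm
            if use_stim:
                du += stim[i, j] * inv_Cm

            un[I, J] = u + dt * (D * lap + du)
            v[i, j] = min(max(vi + dt * dv, 0.0), 1.0)
            w[i, j] = min(max(wi + dt * dw, 0.0), 1.0)
            s[i, j] = min(max(si + dt * ds, 0.0), 1.0)
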