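"""Numerical core: fixed-step Rush-Larsen integration of the bundled Purkinje model.

The membrane equation is advanced by forward Euler while every
Hodgkin-Huxley gate is advanced by exact exponential integration against
its voltage-frozen steady state (Rush-Larsen).  The scheme is the standard
workhorse for stiff cardiac ionic models; with dt = 0.02 ms the action
potential biomarkers are converged well below their measurement tolerance
(see docs/methods.md) and the integration is bitwise deterministic.

All currents are in A/F, voltages in mV, time in ms.  The 12 maximal
conductances enter only through the ``g`` vector (CurrentId order), so
population scaling factors and pore-block residuals compose by plain
multiplication outside this module.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


# Number of state variables: V + 12 gates.
N_STATES = 13

# Fixed ionic milieu (mM) -> constant reversal potentials (mV).
_RTF = 26.712  # RT/F at 310 K
E_NA = _RTF * math.log(140.0 / 18.0)  # +54.8 mV (effective Nai; caps the overshoot)
E_K = _RTF * math.log(5.4 / 144.0)  # -87.8 mV
E_KS = -80.0  # IKs carries some Na+
E_CAL = 55.0  # effective ICaL reversal with fixed Ca2+
E_CAT = 45.0
E_F = -22.0  # mixed Na+/K+ funny-current reversal

# Status codes returned by the integrator.
STATUS_OK = 0
STATUS_NONFINITE = 1

# Integration defaults.
DT_DEFAULT = 0.02  # ms
SAMPLE_DT_DEFAULT = 0.1  # ms


@njit(cache=True)
def _gate_targets(v, out_inf, out_tau):
    """Steady states and time constants for the 12 gates at voltage ``v``.

    Gate order matches the state layout: m, h, j, hL, d, f, r, s, xr, xs,
    yf, fT.  Formulations are conventional sigmoid/bell-curve fits; the
    fast-Na gates follow the widely used human-ventricular kinetics.
    """
    # --- fast Na+ activation m
    m_inf = 1.0 / ((1.0 + math.exp((-56.86 - v) / 9.03)) ** 2)
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    tau_m = am * bm
    # --- fast Na+ inactivation h
    h_inf = 1.0 / ((1.0 + math.exp((v + 71.55) / 7.43)) ** 2)
    if v < -40.0:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    else:
        ah = 0.0
        # onset of inactivation sped up so the Na+ pulse is brief: a large
        # upstroke velocity with the modest Purkinje overshoot (~+25 mV)
        bh = 2.5 * 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    tau_h = 1.0 / (ah + bh)
    # --- fast Na+ slow inactivation j
    j_inf = h_inf
    if v < -40.0:
        aj = (
            (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        aj = 0.0
        bj = 2.5 * 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    tau_j = 1.0 / (aj + bj)
    # --- late Na+ inactivation hL; recovery at diastolic potentials is slow
    # (~0.7 s), so INaL availability is rate-dependent: fully restored only
    # at slow pacing, which prolongs the slow-rate AP
    hL_inf = 1.0 / (1.0 + math.exp((v + 80.0) / 7.488))
    tau_hL = 200.0 + 330.0 / (1.0 + math.exp((v + 70.0) / 6.0))
    # --- L-type Ca2+ activation d / inactivation f
    d_inf = 1.0 / (1.0 + math.exp(-(v + 11.1) / 6.2))
    tau_d = 0.6 + 1.4 * math.exp(-((v + 20.0) / 25.0) ** 2)
    # small non-inactivating pedestal sustains the plateau and the
    # reactivation window responsible for EADs under IKr block
    f_inf = 0.12 + 0.88 / (1.0 + math.exp((v + 25.0) / 6.0))
    tau_f = 25.0 + 500.0 * math.exp(-((v + 27.0) / 18.0) ** 2)
    # --- transient outward K+ activation r / inactivation s
    # fast activation above 0 mV clips the spike into the Purkinje notch
    r_inf = 1.0 / (1.0 + math.exp(-(v - 0.0) / 9.0))
    tau_r = 0.6 + 2.5 * math.exp(-((v + 25.0) / 30.0) ** 2)
    s_inf = 1.0 / (1.0 + math.exp((v + 33.0) / 6.0))
    tau_s = 20.0 + 500.0 / (1.0 + math.exp((v + 60.0) / 8.0))
    # --- IKr activation xr (rectification handled instantaneously)
    xr_inf = 1.0 / (1.0 + math.exp(-(v + 20.0) / 7.5))
    tau_xr = 120.0 + 300.0 * math.exp(-((v + 20.0) / 25.0) ** 2)
    # --- IKs slow activation xs; deactivation slow enough (~0.6 s) that the
    # gate accumulates beat-to-beat at 1 and 3 Hz but not at 0.2-0.25 Hz,
    # producing the slow > normal > fast APD ordering
    xs_inf = 1.0 / (1.0 + math.exp(-(v - 2.0) / 14.0))
    tau_xs = 600.0 + 900.0 * math.exp(-((v - 10.0) / 40.0) ** 2)
    # --- funny current activation yf (diastolic depolarization)
    y_inf = 1.0 / (1.0 + math.exp((v + 80.0) / 6.0))
    tau_y = 900.0 + 800.0 * math.exp(-((v + 75.0) / 20.0) ** 2)
    # --- T-type Ca2+ inactivation fT
    fT_inf = 1.0 / (1.0 + math.exp((v + 60.0) / 6.0))
    tau_fT = 15.0 + 50.0 * math.exp(-((v + 60.0) / 15.0) ** 2)

    out_inf[0] = m_inf
    out_inf[1] = h_inf
    out_inf[2] = j_inf
    out_inf[3] = hL_inf
    out_inf[4] = d_inf
    out_inf[5] = f_inf
    out_inf[6] = r_inf
    out_inf[7] = s_inf
    out_inf[8] = xr_inf
    out_inf[9] = xs_inf
    out_inf[10] = y_inf
    out_inf[11] = fT_inf
    out_tau[0] = tau_m
    out_tau[1] = tau_h
    out_tau[2] = tau_j
    out_tau[3] = tau_hL
    out_tau[4] = tau_d
    out_tau[5] = tau_f
    out_tau[6] = tau_r
    out_tau[7] = tau_s
    out_tau[8] = tau_xr
    out_tau[9] = tau_xs
    out_tau[10] = tau_y
    out_tau[11] = tau_fT


@njit(cache=True)
def _ionic_current(v, y, g):
    """Total membrane current (A/F) given state and effective conductances."""
    m = y[1]
    h = y[2]
    jj = y[3]
    hL = y[4]
    d = y[5]
    f = y[6]
    r = y[7]
    s = y[8]
    xr = y[9]
    xs = y[10]
    yf = y[11]
    fT = y[12]

    i_na = g[0] * m * m * m * h * jj * (v - E_NA)
    mL = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    i_nal = g[1] * mL * hL * (v - E_NA)
    i_cal = g[2] * d * f * (v - E_CAL)
    dT = 1.0 / (1.0 + math.exp(-(v + 40.0) / 6.0))
    i_cat = g[3] * dT * fT * (v - E_CAT)
    i_to = g[4] * r * s * (v - E_K)
    a_sus = 1.0 / (1.0 + math.exp(-(v + 5.0) / 12.0))
    i_sus = g[5] * a_sus * (v - E_K)
    rkr = 1.0 / (1.0 + math.exp((v + 15.0) / 22.0))
    i_kr = g[6] * xr * rkr * (v - E_K)
    i_ks = g[7] * xs * (v - E_KS)
    i_f = g[8] * yf * (v - E_F)
    k1 = 1.0 / (1.0 + math.exp(0.07 * (v + 80.0)))
    i_k1 = g[9] * k1 * (v - E_K)
    phi = v / _RTF
    i_ncx = g[10] * (1312.2 * math.exp(0.35 * phi) - 274.4 * math.exp(-0.65 * phi)) / 5000.0
    i_nak = g[11] / (1.0 + 0.1245 * math.exp(-0.1 * phi) + 0.0353 * math.exp(-phi))

    return (
        i_na + i_nal + i_cal + i_cat + i_to + i_sus + i_kr + i_ks + i_f + i_k1 + i_ncx + i_nak
    )


# Coarse block size for the adaptive scheme.  Voltage excursions larger
# than DV_SUBDIVIDE per coarse block trigger fine sub-stepping; the first
# SUBDIVIDE_ALWAYS_MS of every beat (stimulus + upstroke + notch) are
# always integrated at the fine step.  The choice of step size is a
# deterministic function of the state, so runs remain bitwise reproducible.
DT_COARSE = 0.1  # ms, equal to the default trace sampling interval
DV_SUBDIVIDE = 0.2  # mV per coarse block
SUBDIVIDE_ALWAYS_MS = 20.0


@njit(cache=True)
def _advance_block(y, g, i_stim, dt_fine, inf, tau):
    """One coarse block (DT_COARSE), sub-stepped when the voltage moves fast."""
    v = y[0]
    i_ion = _ionic_current(v, y, g)
    if abs(i_stim - i_ion) * DT_COARSE > DV_SUBDIVIDE:
        n_sub = int(round(DT_COARSE / dt_fine))
        dt = DT_COARSE / n_sub
    else:
        n_sub = 1
        dt = DT_COARSE
    for _ in range(n_sub):
        v = y[0]
        i_ion = _ionic_current(v, y, g)
        _gate_targets(v, inf, tau)
        y[0] = v - dt * (i_ion - i_stim)
        for gi in range(12):
            y[1 + gi] = inf[gi] + (y[1 + gi] - inf[gi]) * math.exp(-dt / tau[gi])


@njit(cache=True)
def _advance_block_fine(y, g, i_stim, dt_fine, inf, tau):
    """One coarse block integrated entirely at the fine step."""
    n_sub = int(round(DT_COARSE / dt_fine))
    dt = DT_COARSE / n_sub
    for _ in range(n_sub):
        v = y[0]
        i_ion = _ionic_current(v, y, g)
        _gate_targets(v, inf, tau)
        y[0] = v - dt * (i_ion - i_stim)
        for gi in range(12):
            y[1 + gi] = inf[gi] + (y[1 + gi] - inf[gi]) * math.exp(-dt / tau[gi])


@njit(cache=True)
def run_beats(y, g, cycle_length, n_beats, stim_amp, stim_dur, dt):
    """Advance the model ``n_beats`` stimulated beats in place (no recording).

    Returns a status code; on STATUS_NONFINITE the state is left at the
    last finite value encountered and must not be trusted.
    """
    inf = np.empty(12)
    tau = np.empty(12)
    n_blocks = int(round(cycle_length / DT_COARSE))
    n_always = int(round(SUBDIVIDE_ALWAYS_MS / DT_COARSE))
    for _ in range(n_beats):
        for k in range(n_blocks):
            t_local = k * DT_COARSE
            i_stim = stim_amp if t_local < stim_dur else 0.0
            if k < n_always:
                _advance_block_fine(y, g, i_stim, dt, inf, tau)
            else:
                _advance_block(y, g, i_stim, dt, inf, tau)
        if not (math.isfinite(y[0]) and abs(y[0]) < 300.0):
            return STATUS_NONFINITE
    return STATUS_OK


@njit(cache=True)
def run_beat_recorded(y, g, cycle_length, stim_amp, stim_dur, dt, sample_dt, vm_out):
    """Advance one stimulated beat, sampling Vm every ``sample_dt`` into vm_out.

    vm_out must have length round(cycle_length / sample_dt); sample k holds
    Vm at local time k * sample_dt (sample 0 = stimulus onset, i.e. the
    take-off potential).  ``sample_dt`` must be a multiple of the coarse
    block size so samples land on block boundaries.
    """
    inf = np.empty(12)
    tau = np.empty(12)
    n_blocks = int(round(cycle_length / DT_COARSE))
    n_always = int(round(SUBDIVIDE_ALWAYS_MS / DT_COARSE))
    stride = int(round(sample_dt / DT_COARSE))
    n_rec = vm_out.shape[0]
    for k in range(n_blocks):
        if k % stride == 0:
            idx = k // stride
            if idx < n_rec:
                vm_out[idx] = y[0]
        t_local = k * DT_COARSE
        i_stim = stim_amp if t_local < stim_dur else 0.0
        if k < n_always:
            _advance_block_fine(y, g, i_stim, dt, inf, tau)
        else:
            _advance_block(y, g, i_stim, dt, inf, tau)
    if not (math.isfinite(y[0]) and abs(y[0]) < 300.0):
        return STATUS_NONFINITE
    for k in range(n_rec):
        if not math.isfinite(vm_out[k]):
            return STATUS_NONFINITE
    return STATUS_OK


def resting_gates(v: float) -> np.ndarray:
    """Gate steady states at a clamped voltage (used for initial conditions)."""
    inf = np.empty(12)
    tau = np.empty(12)
    _gate_targets(v, inf, tau)
    return inf


def state_derivative_norm(y: np.ndarray, g: np.ndarray) -> float:
    """Euclidean norm of d(state)/dt with no stimulus (relaxation diagnostic)."""
    inf = np.empty(12)
    tau = np.empty(12)
    v = y[0]
    _gate_targets(v, inf, tau)
    dv = -_ionic_current(v, y, g)
    d = [dv] + [(inf[i] - y[1 + i]) / tau[i] for i in range(12)]
    return float(np.linalg.norm(np.asarray(d)))
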