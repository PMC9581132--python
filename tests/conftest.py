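"""Shared fixtures: session-scoped model, steady states and small populations.

Simulation-backed tests run a reduced profile (tens of pre-pacing beats,
15-30 drug beats, populations of a few dozen candidates); the model's
slowest gate time constants are ~1.5 s, so these short runs sit on the
same limit cycle the full-scale protocol reaches.
"""

import numpy as np
import pytest

from purkinje_trials.biomarkers import APTrace
from purkinje_trials.cell_model import (CurrentId, PacingProtocol,
                                        ReducedPurkinjeModel)
from purkinje_trials.population import (CalibrationRanges, Population,
                                        build_candidates, calibrate)

# Reduced test profile (full-scale protocol: 1000 pre-pacing beats, 150
# drug beats, 1000 initial candidates).
PREPACE_BEATS = 30
CONTROL_BEATS = 15
DRUG_BEATS = 15

#: conductance profile prone to EADs: strong depolarizing (ICaL, INaL),
#: weak repolarization reserve (IK1, INaK)
SUSCEPTIBLE = {CurrentId.ICaL: 2.0, CurrentId.INaL: 2.0,
               CurrentId.IK1: 0.5, CurrentId.INaK: 0.5}

#: profile that is normal at 1 Hz in control but develops an EAD at 0.25 Hz
SLOW_ONLY_ABNORMAL = {CurrentId.ICaL: 2.05, CurrentId.INaL: 2.05,
                      CurrentId.IK1: 0.45, CurrentId.INaK: 0.45,
                      CurrentId.IKr: 0.4}


@pytest.fixture(scope="session")
def model():
    m = ReducedPurkinjeModel()
    m.diastolic_threshold()  # warm the jit + threshold cache once
    return m


@pytest.fixture(scope="session")
def steady_1hz(model):
    return model.prepace_to_steady_state(n_beats=PREPACE_BEATS, frequency_hz=1.0)


@pytest.fixture(scope="session")
def control_traces(model, steady_1hz):
    """Control last-beat traces at the three pacing rates."""
    traces = {}
    for freq in (0.25, 1.0, 3.0):
        _, trace = model.pace(steady_1hz, PacingProtocol(freq, CONTROL_BEATS))
        traces[freq] = trace
    return traces


def wide_ranges() -> CalibrationRanges:
    """Permissive calibration windows (retain everything integrable)."""
    return CalibrationRanges({
        "APD10": (0.0, 5000.0), "APD25": (0.0, 5000.0), "APD50": (0.0, 5000.0),
        "APD75": (0.0, 5000.0), "APD90": (0.0, 5000.0),
        "dVdtMax": (1.0, 2000.0), "APA": (10.0, 300.0),
        "TOP": (-120.0, -60.0), "EOP": (-120.0, -40.0),
    })


def population_from_rows(model, rows, extra_frequencies=(0.25, 3.0),
                         ranges=None) -> Population:
    """Small population built from explicit scaling rows (reduced profile)."""
    candidates = build_candidates(model, np.asarray(rows, dtype=float),
                                  prepace_beats=PREPACE_BEATS)
    return calibrate(model, candidates, ranges or wide_ranges(),
                     extra_frequencies=extra_frequencies, n_beats=CONTROL_BEATS)


def scaling_row(overrides=None) -> np.ndarray:
    row = np.ones(12)
    for cid, val in (overrides or {}).items():
        row[cid.value] = val
    return row


@pytest.fixture(scope="session")
def mixed_population(model):
    """Baseline + moderately perturbed + EAD-prone members, wide windows."""
    rows = [
        scaling_row(),
        scaling_row({CurrentId.IKr: 1.3, CurrentId.ICaL: 0.8}),
        scaling_row({CurrentId.ICaL: 1.4, CurrentId.IK1: 0.8}),
        scaling_row(SUSCEPTIBLE),
    ]
    # slow + normal rates only: the EAD-prone member cannot finish
    # repolarizing inside a 3 Hz cycle even in control, and the trials run
    # on this population pace at 0.25 and 1 Hz
    return population_from_rows(model, rows, extra_frequencies=(0.25,))


def make_ramp_trace(top=-85.0, peak=25.0, rise_ms=2.0, plateau_end_ms=200.0,
                    fall_end_ms=300.0, cycle_length=1000.0, dt=0.5) -> APTrace:
    """Analytic piecewise-linear AP: rest, linear rise, plateau, linear fall."""
    t = np.arange(0.0, cycle_length, dt)
    v = np.full_like(t, top)
    rising = t < rise_ms
    v[rising] = top + (peak - top) * t[rising] / rise_ms
    v[(t >= rise_ms) & (t < plateau_end_ms)] = peak
    falling = (t >= plateau_end_ms) & (t < fall_end_ms)
    v[falling] = peak + (top - peak) * (t[falling] - plateau_end_ms) / (fall_end_ms - plateau_end_ms)
    return APTrace(time=t, vm=v, cycle_length=cycle_length,
                   stimulus_duration=0.0, stimulus_amplitude=0.0)
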