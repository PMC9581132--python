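"""Action-potential biomarkers and repolarization-abnormality detection.

Nine biomarkers are computed from a single-beat voltage trace:

* TOP (mV) - take-off potential, the voltage at stimulus onset;
* APA (mV) - amplitude, peak voltage minus TOP;
* dV/dtMax (V/s) - maximal forward-difference upstroke slope, stimulus
  window excluded;
* APD10/25/50/75/90 (ms) - time from the instant of dV/dtMax to the first
  later downward crossing of peak - x% * APA, linearly interpolated;
* EOP (mV) - voltage at the last sample of the beat window.

Abnormalities are flagged from positive dV/dt late in the beat: an EAD if
the membrane is still above the repolarized level, a DAD if the deflection
occurs after full repolarization.  Biomarkers are not reported for
abnormal beats.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

APD_LEVELS = (10, 25, 50, 75, 90)
BIOMARKER_NAMES = ("APD10", "APD25", "APD50", "APD75", "APD90",
                   "dVdtMax", "APA", "TOP", "EOP")

#: Minimal depolarization (mV) for a beat to count as an elicited AP.
MIN_DEPOLARIZATION = 10.0


class Abnormality(Enum):
    NONE = "none"
    EAD = "EAD"
    DAD = "DAD"


class NoActionPotential(ValueError):
    """Raised when a trace contains no AP (peak - TOP < 10 mV)."""


@dataclass(frozen=True)
class APTrace:
    """One beat's sampled membrane voltage in local time (0 = stimulus onset)."""

    time: np.ndarray  # ms, strictly increasing, time[0] == 0
    vm: np.ndarray  # mV
    cycle_length: float  # ms
    stimulus_duration: float = 0.5  # ms
    stimulus_amplitude: float = 0.0  # A/F; used to cancel the pulse artifact

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.vm, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("time and vm must be 1-D arrays of equal length")
        if t.size < 50:
            raise ValueError("trace needs at least 50 samples")
        if t[0] != 0.0:
            raise ValueError("trace time must start at 0 (stimulus onset)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "vm", v)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ms": self.time, "vm_mV": self.vm}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cycle_length: float, stimulus_duration: float = 0.5) -> "APTrace":
        df = pd.read_csv(path)
        return cls(df["time_ms"].to_numpy(), df["vm_mV"].to_numpy(),
                   cycle_length, stimulus_duration)


@dataclass(frozen=True)
class BiomarkerSet:
    """The nine AP biomarkers for one model/beat, plus the abnormality flag.

    Biomarker fields are ``None`` when the beat is abnormal (EAD/DAD) or no
    AP was elicited: downstream aggregation only uses normal beats.
    """

    APD10: Optional[float] = None
    APD25: Optional[float] = None
    APD50: Optional[float] = None
    APD75: Optional[float] = None
    APD90: Optional[float] = None
    dVdtMax: Optional[float] = None
    APA: Optional[float] = None
    TOP: Optional[float] = None
    EOP: Optional[float] = None
    abnormal: Abnormality = Abnormality.NONE

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in BIOMARKER_NAMES}
        d["abnormal"] = self.abnormal.value
        return d

    @property
    def is_normal(self) -> bool:
        return self.abnormal is Abnormality.NONE and self.APD90 is not None


def _upstroke(trace: APTrace):
    """(dVdtMax in V/s, index of earliest max-slope sample, peak index).

    A rectangular stimulus of amplitude ``a`` A/F inflates dV/dt by exactly
    ``a`` V/s while it is on, so slopes measured inside the stimulus window
    are corrected by that amount instead of being discarded: with a strong
    (suprathreshold) pulse the regenerative upstroke itself can fall inside
    the window.
    """
    t, v = trace.time, trace.vm
    i_peak = int(np.argmax(v))
    slopes = np.diff(v) / np.diff(t)  # mV/ms == V/s
    in_stim = t[1:] <= trace.stimulus_duration
    slopes = np.where(in_stim, slopes - trace.stimulus_amplitude, slopes)
    masked = np.where(np.arange(t.size - 1) < max(i_peak, 1), slopes, -np.inf)
    best = float(masked.max())
    # earliest sample attaining the max slope; ties within float jitter of
    # the max count, so a uniform ramp is referenced to its first sample
    tol = 1e-9 * max(abs(best), 1.0)
    i_up = int(np.nonzero(masked >= best - tol)[0][0])
    return best, i_up, i_peak


def compute_biomarkers(trace: APTrace) -> BiomarkerSet:
    """Compute the nine biomarkers of a normal beat.

    Raises :class:`NoActionPotential` if the trace never depolarizes by at
    least 10 mV above the take-off potential.  Abnormality screening is the
    caller's job (see :func:`analyze_beat`).
    """
    t, v = trace.time, trace.vm
    top = float(v[0])
    peak = float(v.max())
    apa = peak - top
    if apa < MIN_DEPOLARIZATION:
        raise NoActionPotential(f"no AP elicited (peak - TOP = {apa:.1f} mV)")
    dvdt_max, i_up, i_peak = _upstroke(trace)
    t0 = float(t[i_up])

    apds = {}
    for level in APD_LEVELS:
        thr = peak - (level / 100.0) * apa
        below = np.nonzero(v[i_peak + 1:] < thr)[0]
        if below.size == 0:
            apds[level] = None
            continue
        i = i_peak + 1 + int(below[0])
        v0, v1 = v[i - 1], v[i]
        if v0 == v1:  # pragma: no cover - degenerate flat segment
            t_cross = float(t[i])
        else:
            t_cross = float(t[i - 1] + (t[i] - t[i - 1]) * (v0 - thr) / (v0 - v1))
        apds[level] = t_cross - t0
    if any(apds[level] is None for level in APD_LEVELS):
        # repolarization failure: the beat never returned below the APD90
        # level -- treated as abnormal upstream, no biomarkers reported
        return BiomarkerSet(abnormal=Abnormality.EAD)
    return BiomarkerSet(
        APD10=apds[10], APD25=apds[25], APD50=apds[50], APD75=apds[75], APD90=apds[90],
        dVdtMax=dvdt_max, APA=apa, TOP=top, EOP=float(v[-1]),
        abnormal=Abnormality.NONE,
    )


def detect_abnormality(trace: APTrace, window_start: float = 150.0,
                       slope_threshold: float = 0.01,
                       repolarized_level: float = -70.0) -> Abnormality:
    """Screen a beat for EADs/DADs.

    Positive dV/dt exceeding ``slope_threshold`` (V/s) after
    ``window_start`` (ms, measured from stimulus onset so the upstroke is
    excluded) flags the beat: EAD while the membrane is still above
    ``repolarized_level`` (mV), DAD once it has fallen below.  The slope
    threshold sits above the slow diastolic depolarization the funny
    current produces at low pacing rates.
    """
    if window_start >= trace.cycle_length:
        raise ValueError("window_start must fall inside the beat window")
    t, v = trace.time, trace.vm
    slopes = np.diff(v) / np.diff(t)
    late = (t[:-1] > window_start) & (slopes > slope_threshold)
    idx = np.nonzero(late)[0]
    if idx.size == 0:
        return Abnormality.NONE
    first = int(idx[0])
    if v[first] > repolarized_level:
        return Abnormality.EAD
    return Abnormality.DAD


def analyze_beat(trace: APTrace, window_start: float = 150.0,
                 slope_threshold: float = 0.01,
                 repolarized_level: float = -70.0) -> BiomarkerSet:
    """Abnormality screen first; biomarkers only for normal beats.

    Besides the dV/dt screen, a beat that takes off from or ends above the
    repolarized level reflects repolarization failure spilling across the
    beat window; it is counted as an EAD-type abnormality.
    """
    if trace.vm[0] > repolarized_level or trace.vm[-1] > repolarized_level:
        return BiomarkerSet(abnormal=Abnormality.EAD)
    flag = detect_abnormality(trace, window_start, slope_threshold, repolarized_level)
    if flag is not Abnormality.NONE:
        return BiomarkerSet(abnormal=flag)
    return compute_biomarkers(trace)


def percent_change(drug_mean: float, control_mean: float) -> float:
    """100 * (drug - control) / |control|, the drug-effect scale used throughout."""
    if control_mean == 0:
        raise ZeroDivisionError("percent change undefined for zero control mean")
    return 100.0 * (drug_mean - control_mean) / abs(control_mean)
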