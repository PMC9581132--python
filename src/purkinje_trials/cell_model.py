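"""Cell-model contract and the bundled reduced human Purkinje AP model.

The bundled model is a reduced Hodgkin-Huxley formulation carrying the 12
ionic currents that shape the Purkinje action potential: fast and late Na+
(INa, INaL), L- and T-type Ca2+ (ICaL, ICaT), transient and sustained
outward K+ (Ito, Isus), rapid and slow delayed rectifiers (IKr, IKs),
funny current (If), inward rectifier (IK1), Na+/Ca2+ exchanger (INCX) and
Na+/K+ pump (INaK).  Intracellular concentrations are held fixed, so the
slowest time scales are gate kinetics (~1.5 s) and a paced cell reaches
its rate-dependent limit cycle within a few tens of beats.

Each maximal conductance is multiplied by a population scaling factor
(:class:`ScalingVector`) and a drug residual (:class:`BlockSet`); the two
compose commutatively.  Traces are returned one beat at a time in local
time (0 = stimulus onset).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import yaml

from . import _engine
from .biomarkers import APTrace


class CurrentId(Enum):
    """The 12 sampled/blockable ionic currents, in stable serialization order."""

    INa = 0
    INaL = 1
    ICaL = 2
    ICaT = 3
    Ito = 4
    Isus = 5
    IKr = 6
    IKs = 7
    If = 8
    IK1 = 9
    INCX = 10
    INaK = 11


CURRENT_ORDER: Tuple[CurrentId, ...] = tuple(CurrentId)


class SolverFailure(RuntimeError):
    """Raised when integration produces a non-finite state (never silent NaN)."""


def _vector_from_mapping(values, default: float, name: str) -> np.ndarray:
    arr = np.full(12, default, dtype=float)
    if values:
        for key, val in values.items():
            cid = key if isinstance(key, CurrentId) else CurrentId[str(key)]
            arr[cid.value] = float(val)
    return arr


@dataclass(frozen=True)
class ScalingVector:
    """Multiplicative conductance factors defining one population member."""

    factors: np.ndarray  # length 12, CurrentId order

    def __post_init__(self):
        arr = np.asarray(self.factors, dtype=float)
        if arr.shape != (12,):
            raise ValueError("ScalingVector needs exactly 12 factors")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("scaling factors must be finite and > 0")
        object.__setattr__(self, "factors", arr)
        self.factors.setflags(write=False)

    @classmethod
    def ones(cls) -> "ScalingVector":
        return cls(np.ones(12))

    @classmethod
    def from_dict(cls, values: Mapping) -> "ScalingVector":
        return cls(_vector_from_mapping(values, 1.0, "scaling"))

    def __getitem__(self, cid: CurrentId) -> float:
        return float(self.factors[cid.value])

    def as_dict(self) -> Dict[str, float]:
        return {c.name: float(self.factors[c.value]) for c in CURRENT_ORDER}


@dataclass(frozen=True)
class BlockSet:
    """Residual current fraction per channel after pore block (1.0 = no block)."""

    residuals: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.residuals, dtype=float)
        if arr.shape != (12,):
            raise ValueError("BlockSet needs exactly 12 residuals")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("residual fractions must lie in [0, 1]")
        object.__setattr__(self, "residuals", arr)
        self.residuals.setflags(write=False)

    @classmethod
    def none(cls) -> "BlockSet":
        return cls(np.ones(12))

    @classmethod
    def from_dict(cls, values: Mapping) -> "BlockSet":
        return cls(_vector_from_mapping(values, 1.0, "residual"))

    def __getitem__(self, cid: CurrentId) -> float:
        return float(self.residuals[cid.value])

    def as_dict(self) -> Dict[str, float]:
        return {c.name: float(self.residuals[c.value]) for c in CURRENT_ORDER}


@dataclass(frozen=True)
class PacingProtocol:
    """Rectangular-pulse pacing protocol.

    ``stimulus_amplitude`` is in A/F; ``None`` selects twice the bundled
    model's diastolic threshold (found once by bisection and cached).
    """

    frequency_hz: float
    n_beats: int
    stimulus_amplitude: Optional[float] = None
    stimulus_duration: float = 0.5  # ms
    sample_interval: float = 0.1  # ms

    def __post_init__(self):
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.stimulus_duration >= self.cycle_length:
            raise ValueError("stimulus_duration must be shorter than the cycle length")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")

    @property
    def cycle_length(self) -> float:
        return 1000.0 / self.frequency_hz


@dataclass
class CellState:
    """Opaque model state: membrane voltage plus gating variables."""

    vector: np.ndarray  # length model.n_states; vector[0] = Vm (mV)
    time: float = 0.0  # ms of simulated history
    model_name: str = "reduced-purkinje"

    @property
    def membrane_voltage(self) -> float:
        return float(self.vector[0])

    def copy(self) -> "CellState":
        return CellState(self.vector.copy(), self.time, self.model_name)


# Baseline maximal conductances (A/F scale factors), tuned so the control
# biomarkers of the bundled model sit inside the healthy human Purkinje
# calibration windows at 0.25, 1 and 3 Hz (see docs/methods.md).
BASELINE_CONDUCTANCES: Dict[CurrentId, float] = {
    CurrentId.INa: 38.0,
    CurrentId.INaL: 0.11,
    CurrentId.ICaL: 0.2,
    CurrentId.ICaT: 0.04,
    CurrentId.Ito: 0.45,
    CurrentId.Isus: 0.012,
    CurrentId.IKr: 0.057,
    CurrentId.IKs: 0.032,
    CurrentId.If: 0.033,
    CurrentId.IK1: 0.73,
    CurrentId.INCX: 0.5,
    CurrentId.INaK: 0.75,
}

RESTING_VM = -87.5  # mV, diastolic potential the initial condition is built at


class ReducedPurkinjeModel:
    """The bundled reduced human-Purkinje-like AP model.

    Parameters
    ----------
    conductances:
        Optional override of the baseline maximal conductances.
    dt:
        Integration step (ms).  0.02 ms is the converged default.
    """

    name = "reduced-purkinje"
    n_states = _engine.N_STATES

    def __init__(self, conductances: Optional[Mapping[CurrentId, float]] = None,
                 dt: float = _engine.DT_DEFAULT):
        table = dict(BASELINE_CONDUCTANCES)
        if conductances:
            table.update(conductances)
        self.conductances = table
        self.dt = float(dt)
        self._g_base = np.array([table[c] for c in CURRENT_ORDER], dtype=float)
        self._threshold_cache: Optional[float] = None
        self._prepace_cache: Dict[Tuple, CellState] = {}

    # ------------------------------------------------------------------ utils
    def effective_conductances(self, scalings: ScalingVector, block: BlockSet) -> np.ndarray:
        return self._g_base * scalings.factors * block.residuals

    def parameter_hash(self) -> str:
        payload = ",".join(f"{c.name}={self.conductances[c]:.12g}" for c in CURRENT_ORDER)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # ------------------------------------------------------- state management
    def initial_state(self) -> CellState:
        vec = np.empty(self.n_states)
        vec[0] = RESTING_VM
        vec[1:] = _engine.resting_gates(RESTING_VM)
        return CellState(vec, 0.0, self.name)

    # ------------------------------------------------------------ stimulation
    def diastolic_threshold(self) -> float:
        """Minimal 0.5 ms stimulus amplitude (A/F) eliciting an AP, by bisection."""
        if self._threshold_cache is not None:
            return self._threshold_cache
        ones = ScalingVector.ones()
        none = BlockSet.none()

        def fires(amp: float) -> bool:
            y = self.initial_state().vector.copy()
            g = self.effective_conductances(ones, none)
            n_rec = int(round(200.0 / 0.5))
            vm = np.empty(n_rec)
            status = _engine.run_beat_recorded(y, g, 200.0, amp, 0.5, self.dt, 0.5, vm)
            return status == _engine.STATUS_OK and vm.max() > -20.0

        lo, hi = 1.0, 128.0
        while not fires(hi):  # pragma: no cover - defensive
            hi *= 2.0
            if hi > 4096.0:
                raise SolverFailure("model is inexcitable: no stimulus elicits an AP")
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            if fires(mid):
                hi = mid
            else:
                lo = mid
        self._threshold_cache = hi
        return hi

    def default_stimulus_amplitude(self) -> float:
        return 2.0 * self.diastolic_threshold()

    def _resolve_amplitude(self, protocol: PacingProtocol) -> float:
        if protocol.stimulus_amplitude is not None:
            return float(protocol.stimulus_amplitude)
        return self.default_stimulus_amplitude()

    # ----------------------------------------------------------------- pacing
    def pace(self, state: CellState, protocol: PacingProtocol,
             scalings: Optional[ScalingVector] = None,
             block: Optional[BlockSet] = None) -> Tuple[CellState, APTrace]:
        """Pace ``n_beats`` beats; return the final state and the last beat's trace."""
        scalings = scalings or ScalingVector.ones()
        block = block or BlockSet.none()
        if state.model_name != self.name:
            raise ValueError(f"state belongs to model {state.model_name!r}, not {self.name!r}")
        g = self.effective_conductances(scalings, block)
        amp = self._resolve_amplitude(protocol)
        cl = protocol.cycle_length
        y = state.vector.copy()
        if protocol.n_beats > 1:
            status = _engine.run_beats(y, g, cl, protocol.n_beats - 1, amp,
                                       protocol.stimulus_duration, self.dt)
            if status != _engine.STATUS_OK:
                raise SolverFailure(
                    f"non-finite state while pacing at {protocol.frequency_hz} Hz")
        n_rec = int(round(cl / protocol.sample_interval))
        vm = np.empty(n_rec)
        status = _engine.run_beat_recorded(y, g, cl, amp, protocol.stimulus_duration,
                                           self.dt, protocol.sample_interval, vm)
        if status != _engine.STATUS_OK:
            raise SolverFailure(
                f"non-finite state on recorded beat at {protocol.frequency_hz} Hz")
        t = np.arange(n_rec) * protocol.sample_interval
        trace = APTrace(time=t, vm=vm, cycle_length=cl,
                        stimulus_duration=protocol.stimulus_duration,
                        stimulus_amplitude=amp)
        new_state = CellState(y, state.time + protocol.n_beats * cl, self.name)
        return new_state, trace

    def prepace_to_steady_state(self, scalings: Optional[ScalingVector] = None,
                                n_beats: int = 1000, frequency_hz: float = 1.0,
                                stimulus_amplitude: Optional[float] = None,
                                stimulus_duration: float = 0.5) -> CellState:
        """Pace from the resting initial condition to the rate's limit cycle.

        Results are cached per (scalings, frequency, n_beats, stimulus) so
        that drug trials restart from each member's control steady state.
        """
        if n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        scalings = scalings or ScalingVector.ones()
        amp = (stimulus_amplitude if stimulus_amplitude is not None
               else self.default_stimulus_amplitude())
        key = (scalings.factors.tobytes(), float(frequency_hz), int(n_beats),
               float(amp), float(stimulus_duration))
        cached = self._prepace_cache.get(key)
        if cached is not None:
            return cached.copy()
        g = self.effective_conductances(scalings, BlockSet.none())
        y = self.initial_state().vector.copy()
        cl = 1000.0 / frequency_hz
        status = _engine.run_beats(y, g, cl, n_beats, amp, stimulus_duration, self.dt)
        if status != _engine.STATUS_OK:
            raise SolverFailure(f"non-finite state during pre-pacing at {frequency_hz} Hz")
        state = CellState(y, n_beats * cl, self.name)
        self._prepace_cache[key] = state.copy()
        return state

    # ------------------------------------------------------------ diagnostics
    def relaxation_norms(self, n_points: int = 10, horizon_ms: float = 2000.0) -> np.ndarray:
        """||d state/dt|| sampled along an unstimulated relaxation from rest."""
        g = self.effective_conductances(ScalingVector.ones(), BlockSet.none())
        y = self.initial_state().vector.copy()
        chunk = horizon_ms / n_points
        norms = [_engine.state_derivative_norm(y, g)]
        for _ in range(n_points):
            status = _engine.run_beats(y, g, chunk, 1, 0.0, 0.5, self.dt)
            if status != _engine.STATUS_OK:
                raise SolverFailure("non-finite state during relaxation run")
            norms.append(_engine.state_derivative_norm(y, g))
        return np.asarray(norms)

    # ---------------------------------------------------------- serialization
    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "dt_ms": self.dt,
            "conductances": {c.name: float(self.conductances[c]) for c in CURRENT_ORDER},
            "initial_state": {
                "vm_mV": RESTING_VM,
                "gates": [float(x) for x in _engine.resting_gates(RESTING_VM)],
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReducedPurkinjeModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cond = {CurrentId[k]: float(v) for k, v in doc.get("conductances", {}).items()}
        return cls(conductances=cond, dt=float(doc.get("dt_ms", _engine.DT_DEFAULT)))


# --------------------------------------------------------- module-level API


def initialize_state(model: ReducedPurkinjeModel, scalings: ScalingVector) -> CellState:
    """The model's bundled resting initial condition.

    Scalings are validated here but affect only subsequent dynamics, never
    the stored initial condition itself.
    """
    if not isinstance(scalings, ScalingVector):
        scalings = ScalingVector.from_dict(scalings)
    return model.initial_state()


def pace(model: ReducedPurkinjeModel, state: CellState, protocol: PacingProtocol,
         scalings: Optional[ScalingVector] = None,
         block: Optional[BlockSet] = None) -> Tuple[CellState, APTrace]:
    return model.pace(state, protocol, scalings, block)


def prepace_to_steady_state(model: ReducedPurkinjeModel,
                            scalings: Optional[ScalingVector] = None,
                            n_beats: int = 1000, frequency_hz: float = 1.0,
                            **kwargs) -> CellState:
    return model.prepace_to_steady_state(scalings, n_beats, frequency_hz, **kwargs)
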