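"""Experimentally-calibrated population of Purkinje models.

The population-of-models approach captures cell-to-cell variability by
sampling the 12 maximal ionic conductances in [50, 200]% of baseline with
Latin hypercube sampling, pacing every candidate to steady state at 1 Hz,
and retaining only members whose nine control biomarkers fall inside
healthy human Purkinje calibration ranges and that show no repolarization
abnormality at any of the control pacing rates.  Drug trials then run on
one frozen population, identified by a content hash that downstream
aggregation checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .biomarkers import Abnormality, BiomarkerSet, BIOMARKER_NAMES, analyze_beat
from .cell_model import (CellState, PacingProtocol, ReducedPurkinjeModel,
                         ScalingVector, SolverFailure)

DEFAULT_FREQUENCIES = (0.25, 1.0, 3.0)


@dataclass(frozen=True)
class SamplingConfig:
    """Latin hypercube design over the 12 conductance factors."""

    n_initial: int = 1000
    low: float = 0.5
    high: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")


def lhs_sample(config: SamplingConfig) -> np.ndarray:
    """(n_initial x 12) scaling factors, one sample per equal bin per dimension.

    Stratification is per dimension (each dimension's n bins each receive
    exactly one sample); the pairing across dimensions is random but seeded.
    """
    sampler = qmc.LatinHypercube(d=12, seed=config.seed)
    unit = sampler.random(config.n_initial)
    return qmc.scale(unit, config.low, config.high)


class CalibrationRanges:
    """Acceptance window [min, max] for each of the nine control biomarkers."""

    def __init__(self, ranges: Dict[str, Tuple[float, float]]):
        missing = set(BIOMARKER_NAMES) - set(ranges)
        if missing:
            raise ValueError(f"missing calibration ranges for {sorted(missing)}")
        for name, (lo, hi) in ranges.items():
            if not lo < hi:
                raise ValueError(f"{name}: range min must be < max")
        self.ranges = {name: (float(lo), float(hi)) for name, (lo, hi) in ranges.items()}

    def __getitem__(self, name: str) -> Tuple[float, float]:
        return self.ranges[name]

    def check(self, biomarkers: BiomarkerSet) -> Optional[str]:
        """None if all nine biomarkers fall inside their windows, else a reason."""
        if not biomarkers.is_normal:
            return f"control abnormality ({biomarkers.abnormal.value})"
        for name in BIOMARKER_NAMES:
            lo, hi = self.ranges[name]
            value = getattr(biomarkers, name)
            if not lo <= value <= hi:
                return f"{name} out of range ({value:.1f} not in [{lo:.1f}, {hi:.1f}])"
        return None

    @classmethod
    def default(cls, model: Optional[ReducedPurkinjeModel] = None,
                baseline: Optional[BiomarkerSet] = None,
                prepace_beats: int = 100) -> "CalibrationRanges":
        """Default windows: published healthy human Purkinje mean +/- 2 SD at
        1 Hz for APD50/APD90/dVdtMax/APA/TOP; baseline model value +/- 50%
        for the biomarkers without a published range (APD10/25/75, EOP).
        """
        text = resources.files("purkinje_trials").joinpath(
            "data/biomarker_reference.yaml").read_text()
        human = yaml.safe_load(text)["human_insilico"][1.0]
        ranges: Dict[str, Tuple[float, float]] = {}
        for name, (mean, sd) in human.items():
            ranges[name] = (mean - 2 * sd, mean + 2 * sd)
        if baseline is None:
            model = model or ReducedPurkinjeModel()
            state = model.prepace_to_steady_state(n_beats=prepace_beats, frequency_hz=1.0)
            _, trace = model.pace(state, PacingProtocol(1.0, 1))
            baseline = analyze_beat(trace)
        for name in ("APD75", "EOP"):
            value = getattr(baseline, name)
            lo, hi = sorted((0.5 * value, 1.5 * value))
            ranges[name] = (lo - 1e-9, hi + 1e-9)
        # early-repolarization durations are bimodal across conductance
        # variants (the notch may or may not dip below the 10/25% level),
        # so their windows span from half the baseline value up to 1.5x the
        # baseline APD50 rather than a narrow band around the baseline
        for name in ("APD10", "APD25"):
            ranges[name] = (0.5 * getattr(baseline, name) - 1e-9,
                            1.5 * baseline.APD50 + 1e-9)
        return cls(ranges)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in self.ranges.items()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationRanges":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls({k: tuple(v) for k, v in doc.items()})


@dataclass
class PopulationMember:
    """One calibrated model variant with its cached control data per rate."""

    index: int
    scalings: ScalingVector
    control_states: Dict[float, CellState] = field(default_factory=dict)
    control_biomarkers: Dict[float, BiomarkerSet] = field(default_factory=dict)


@dataclass
class Candidate:
    index: int
    scalings: ScalingVector
    state_1hz: Optional[CellState] = None
    biomarkers_1hz: Optional[BiomarkerSet] = None
    failure: Optional[str] = None


@dataclass
class Population:
    """A frozen, calibrated population; all drug trials run on exactly one."""

    members: List[PopulationMember]
    model_hash: str
    seed: Optional[int] = None
    exclusions: List[Tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def scaling_matrix(self) -> np.ndarray:
        return np.vstack([m.scalings.factors for m in self.members]) if self.members \
            else np.empty((0, 12))

    def population_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.model_hash.encode())
        h.update(self.scaling_matrix().tobytes())
        return h.hexdigest()[:16]

    def to_csv(self, path) -> None:
        rows = [{"index": m.index, **m.scalings.as_dict()} for m in self.members]
        pd.DataFrame(rows).to_csv(path, index=False)

    def write_manifest(self, path) -> None:
        doc = {"seed": self.seed, "model_hash": self.model_hash,
               "population_hash": self.population_hash(), "n_members": len(self),
               "exclusions": [{"index": i, "reason": r} for i, r in self.exclusions]}
        Path(path).write_text(json.dumps(doc, indent=2))


def build_candidates(model: ReducedPurkinjeModel, samples: np.ndarray,
                     prepace_beats: int = 1000, frequency_hz: float = 1.0) -> List[Candidate]:
    """Pace every sampled variant to 1 Hz steady state and score its control beat.

    Integration failures are recorded on the candidate (non-fatal); they are
    excluded downstream, not raised.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    candidates: List[Candidate] = []
    protocol = PacingProtocol(frequency_hz, 1)
    for idx, row in enumerate(samples):
        scalings = ScalingVector(row)
        try:
            state = model.prepace_to_steady_state(scalings, prepace_beats, frequency_hz)
            state, trace = model.pace(state, protocol, scalings)
            bm = analyze_beat(trace)
            candidates.append(Candidate(idx, scalings, state, bm))
        except SolverFailure as exc:
            candidates.append(Candidate(idx, scalings, failure=str(exc)))
    return candidates


def calibrate(model: ReducedPurkinjeModel, candidates: Sequence[Candidate],
              ranges: CalibrationRanges,
              extra_frequencies: Sequence[float] = (0.25, 3.0),
              n_beats: int = 150) -> Population:
    """Filter candidates into the calibrated population.

    Retains members whose nine 1 Hz control biomarkers sit inside
    ``ranges`` and that stay free of EADs/DADs in control at 1 Hz and at
    every extra pacing rate; control steady states and biomarkers per rate
    are cached on the member for reuse by drug trials.  Pure filter:
    retained members are a subset of candidates, order preserved.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    members: List[PopulationMember] = []
    exclusions: List[Tuple[int, str]] = []
    for cand in candidates:
        if cand.failure is not None:
            exclusions.append((cand.index, f"integration failure: {cand.failure}"))
            continue
        reason = ranges.check(cand.biomarkers_1hz)
        if reason is not None:
            exclusions.append((cand.index, reason))
            continue
        member = PopulationMember(cand.index, cand.scalings)
        member.control_states[1.0] = cand.state_1hz
        member.control_biomarkers[1.0] = cand.biomarkers_1hz
        ok = True
        for freq in extra_frequencies:
            try:
                state, trace = model.pace(cand.state_1hz,
                                          PacingProtocol(freq, n_beats), cand.scalings)
            except SolverFailure:
                exclusions.append((cand.index, f"integration failure at {freq} Hz"))
                ok = False
                break
            bm = analyze_beat(trace)
            if bm.abnormal is not Abnormality.NONE:
                exclusions.append(
                    (cand.index, f"control abnormality at {freq} Hz ({bm.abnormal.value})"))
                ok = False
                break
            member.control_states[freq] = state
            member.control_biomarkers[freq] = bm
        if ok:
            members.append(member)
    return Population(members, model.parameter_hash(), exclusions=exclusions)


def build_population(model: ReducedPurkinjeModel, config: SamplingConfig,
                     ranges: Optional[CalibrationRanges] = None,
                     prepace_beats: int = 1000,
                     extra_frequencies: Sequence[float] = (0.25, 3.0),
                     control_beats: int = 150) -> Population:
    """End-to-end: LHS sample, pace, calibrate; returns the frozen population."""
    ranges = ranges or CalibrationRanges.default(model, prepace_beats=min(prepace_beats, 100))
    samples = lhs_sample(config)
    candidates = build_candidates(model, samples, prepace_beats)
    population = calibrate(model, candidates, ranges, extra_frequencies, control_beats)
    population.seed = config.seed
    return population
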