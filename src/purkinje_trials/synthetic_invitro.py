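"""Synthetic rabbit-Purkinje assay data and bundled reference fixtures.

Real preclinical Purkinje-fiber assays superfuse a handful of fibers
(4-7 per compound) with ascending drug concentrations and report AP
biomarkers per fiber, pacing rate and concentration, plus whether EADs
appeared at slow pacing.  This module emulates that output so every
downstream stage (aggregation, consistency scoring, classification) is
testable without animal data:

* control cohorts - per-fiber biomarkers drawn from truncated normals
  around published rabbit control means/SDs;
* dose effects - configurable Emax-style percent changes plus fiber-level
  noise and Bernoulli EAD flags (it *emulates*, never estimates, a real
  dose-response);
* stylized voltage traces - piecewise-smooth APs hitting requested
  biomarker targets, optionally with an inserted EAD deflection (fixture
  generator for the biomarker extractors).

Biomarkers are drawn independently across columns; within-fiber
correlation structure is not modeled.  Carry-over between sequentially
applied concentrations is also not modeled: each concentration is treated
as an independent equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from .biomarkers import APTrace, BIOMARKER_NAMES
from .drug_block import DrugSpec, load_drug_library

ASSAY_COLUMNS = ("fiber_id", "drug", "concentration_um", "frequency_hz",
                 *BIOMARKER_NAMES, "ead_flag")

#: physiological truncation bounds per biomarker (lower, upper)
_BOUNDS: Dict[str, Tuple[float, float]] = {
    "APD10": (0.5, np.inf), "APD25": (1.0, np.inf), "APD50": (10.0, np.inf),
    "APD75": (10.0, np.inf), "APD90": (10.0, np.inf),
    "dVdtMax": (50.0, np.inf), "APA": (50.0, np.inf),
    "TOP": (-100.0, -60.0), "EOP": (-100.0, -60.0),
}

# Synthetic defaults for the biomarkers the published control table does not
# report (per frequency: mean, sd); chosen to sit consistently inside the
# published APD50/APD90 envelope of rabbit fibers.
_EXTRA_DEFAULTS: Dict[float, Dict[str, Tuple[float, float]]] = {
    0.25: {"APD10": (8, 3), "APD25": (60, 25), "APD75": (400, 110), "EOP": (-89, 1)},
    1.0: {"APD10": (8, 3), "APD25": (50, 20), "APD75": (290, 50), "EOP": (-91, 1)},
    3.0: {"APD10": (7, 3), "APD25": (40, 15), "APD75": (200, 23), "EOP": (-92, 1)},
}


def load_biomarker_reference() -> Dict:
    """Published control biomarker means/SDs for both species, by frequency."""
    text = resources.files("purkinje_trials").joinpath(
        "data/biomarker_reference.yaml").read_text()
    return yaml.safe_load(text)


def default_rabbit_profile() -> Dict[float, Dict[str, Tuple[float, float]]]:
    ref = load_biomarker_reference()["rabbit_invitro"]
    profile: Dict[float, Dict[str, Tuple[float, float]]] = {}
    for freq, stats in ref.items():
        freq = float(freq)
        profile[freq] = {k: (float(m), float(s)) for k, (m, s) in stats.items()}
        profile[freq].update({k: (float(m), float(s))
                              for k, (m, s) in _EXTRA_DEFAULTS[freq].items()})
    return profile


@dataclass(frozen=True)
class FiberCohortConfig:
    """Design of a synthetic control cohort."""

    n_fibers: int = 6
    seed: int = 0
    frequencies_hz: Tuple[float, ...] = (0.25, 1.0, 3.0)
    profile: Optional[Dict[float, Dict[str, Tuple[float, float]]]] = None

    def __post_init__(self):
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        prof = self.profile if self.profile is not None else default_rabbit_profile()
        for freq in self.frequencies_hz:
            if freq not in prof:
                raise ValueError(f"no biomarker profile for {freq} Hz")
            for name, (mean, sd) in prof[freq].items():
                if sd < 0:
                    raise ValueError(f"{name} at {freq} Hz: sd must be >= 0")
        object.__setattr__(self, "profile", prof)


def _draw(rng, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_fiber_cohort(config: FiberCohortConfig) -> pd.DataFrame:
    """Control biomarker table: one row per fiber per pacing rate."""
    rng = np.random.default_rng(config.seed)
    records: List[Dict] = []
    for freq in config.frequencies_hz:
        stats = config.profile[freq]
        draws = {}
        for name in BIOMARKER_NAMES:
            mean, sd = stats[name]
            lo, hi = _BOUNDS[name]
            draws[name] = _draw(rng, mean, sd, lo, hi, config.n_fibers)
        for i in range(config.n_fibers):
            records.append({"fiber_id": i, "drug": "control", "concentration_um": 0.0,
                            "frequency_hz": freq,
                            **{name: float(draws[name][i]) for name in BIOMARKER_NAMES},
                            "ead_flag": False})
    return pd.DataFrame.from_records(records, columns=list(ASSAY_COLUMNS))


@dataclass(frozen=True)
class EmaxEffect:
    """Saturating percent change: emax_pct * C^h / (C^h + EC50^h)."""

    emax_pct: float
    ec50_um: float
    hill: float = 1.0

    def __post_init__(self):
        if self.ec50_um <= 0 or self.hill <= 0:
            raise ValueError("EC50 and Hill must be > 0")

    def pct_at(self, concentration_um: float) -> float:
        c = concentration_um ** self.hill
        return self.emax_pct * c / (c + self.ec50_um ** self.hill)


@dataclass(frozen=True)
class SyntheticDoseEffect:
    """Configured (not estimated) dose effects for the synthetic assay."""

    effects: Dict[str, EmaxEffect] = field(default_factory=dict)
    ead_probability: Dict[float, float] = field(default_factory=dict)
    noise_sd_frac: float = 0.05

    def __post_init__(self):
        for conc, p in self.ead_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"EAD probability at {conc} uM must be in [0, 1]")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")


def apply_dose_effects(cohort: pd.DataFrame, drug_name: str,
                       concentrations_um: Sequence[float],
                       effect: SyntheticDoseEffect, seed: int,
                       slow_rate_hz: Optional[float] = None) -> pd.DataFrame:
    """Dosed biomarker table plus EAD flags for a synthetic drug assay.

    Each biomarker value is its control value scaled by the configured Emax
    percent change, with multiplicative fiber-level noise; EAD flags are
    drawn per configured probability at the slow pacing rate only.
    """
    concs = [float(c) for c in concentrations_um]
    if concs != sorted(concs) or any(c <= 0 for c in concs):
        raise ValueError("concentrations must be positive and ascending")
    rng = np.random.default_rng(seed)
    slow = slow_rate_hz if slow_rate_hz is not None \
        else float(cohort.frequency_hz.min())
    records: List[Dict] = []
    for conc in concs:
        for _, row in cohort.iterrows():
            rec = {"fiber_id": int(row.fiber_id), "drug": drug_name,
                   "concentration_um": conc,
                   "frequency_hz": float(row.frequency_hz)}
            for name in BIOMARKER_NAMES:
                value = float(row[name])
                eff = effect.effects.get(name)
                pct = eff.pct_at(conc) if eff is not None else 0.0
                noise = rng.normal(0.0, effect.noise_sd_frac) \
                    if effect.noise_sd_frac > 0 and eff is not None else 0.0
                rec[name] = value * (1.0 + pct / 100.0) * (1.0 + noise)
            is_slow = np.isclose(float(row.frequency_hz), slow)
            p = effect.ead_probability.get(conc, 0.0) if is_slow else 0.0
            rec["ead_flag"] = bool(rng.random() < p) if p > 0 else False
            records.append(rec)
    return pd.DataFrame.from_records(records, columns=list(ASSAY_COLUMNS))


def summarize_assay(control: pd.DataFrame, dosed: pd.DataFrame) -> pd.DataFrame:
    """Mean percent change vs same-fiber control and EAD incidence per cell."""
    ctrl = control.set_index(["fiber_id", "frequency_hz"])
    records = []
    for (conc, freq), cell in dosed.groupby(["concentration_um", "frequency_hz"]):
        rec = {"concentration_um": conc, "frequency_hz": freq,
               "incidence_pct": 100.0 * cell.ead_flag.mean(),
               "n_evaluable": int((~cell.ead_flag).sum())}
        normal = cell[~cell.ead_flag]
        for name in BIOMARKER_NAMES:
            if normal.empty:
                rec[f"pct_{name}"] = None
                continue
            base = ctrl.loc[list(zip(normal.fiber_id, normal.frequency_hz)), name].to_numpy()
            rec[f"pct_{name}"] = float(np.mean(
                100.0 * (normal[name].to_numpy() - base) / np.abs(base)))
        records.append(rec)
    return pd.DataFrame.from_records(records).sort_values(
        ["frequency_hz", "concentration_um"]).reset_index(drop=True)


def validate_assay_table(df: pd.DataFrame) -> None:
    """Schema check shared by synthetic and imported assay tables."""
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("assay table is empty")
    if (df.concentration_um < 0).any():
        raise ValueError("negative concentrations")
    if not df.ead_flag.isin([True, False]).all():
        raise ValueError("ead_flag must be boolean")
    top = df.TOP.dropna()
    if ((top < -110) | (top > -40)).any():
        raise ValueError("take-off potentials outside plausible range")


# ----------------------------------------------------------- trace synthesis


@dataclass(frozen=True)
class EadSpec:
    """A positive deflection to superimpose during repolarization."""

    time_ms: float
    amplitude_mv: float = 15.0
    width_ms: float = 30.0


def synthesize_trace(targets: Mapping[str, float], cycle_length: float = 1000.0,
                     ead_spec: Optional[EadSpec] = None,
                     sample_interval: float = 0.1) -> APTrace:
    """A piecewise-smooth AP whose computed biomarkers hit the targets.

    ``targets`` may contain TOP, APA, dVdtMax, EOP and any subset of
    APD10/25/50/75/90 (at least one APD); the repolarization ramp is a
    monotone cubic through the exact (time, voltage) anchor points of each
    requested APD level, so the biomarker extractor recovers the targets to
    well within 1%.  Raises ValueError on unsatisfiable targets.
    """
    top = float(targets.get("TOP", -85.0))
    apa = float(targets.get("APA", 110.0))
    dvdt = float(targets.get("dVdtMax", 400.0))
    eop = float(targets.get("EOP", top))
    if apa <= 0 or dvdt <= 0:
        raise ValueError("APA and dVdtMax targets must be > 0")
    levels = [lv for lv in (10, 25, 50, 75, 90) if f"APD{lv}" in targets]
    if not levels:
        raise ValueError("at least one APD target is required")
    apds = [float(targets[f"APD{lv}"]) for lv in levels]
    if apds != sorted(apds) or len(set(apds)) != len(apds):
        raise ValueError("APD targets must be strictly increasing with level")
    t0 = 1.0  # upstroke start, aligned to the sample grid
    ramp = apa / dvdt
    t_peak = t0 + ramp
    peak = top + apa
    if t0 + apds[-1] >= cycle_length - 20.0:
        raise ValueError("APD targets do not fit inside the beat window")
    if t0 + apds[0] <= t_peak:
        raise ValueError("smallest APD target collides with the upstroke")

    anchors_t = [t_peak]
    anchors_v = [peak]
    for lv, apd in zip(levels, apds):
        anchors_t.append(t0 + apd)
        anchors_v.append(peak - lv / 100.0 * apa)
    # settle to the end-of-beat potential shortly after the last APD anchor
    t_settle = min(t0 + apds[-1] + 60.0, cycle_length - 5.0)
    v_floor = min(eop, anchors_v[-1] - 1.0)
    anchors_t.append(t_settle)
    anchors_v.append(v_floor)
    if any(np.diff(anchors_t) <= 0) or any(np.diff(anchors_v) >= 0):
        raise ValueError("targets do not describe a monotone repolarization")
    decay = PchipInterpolator(anchors_t, anchors_v)

    t = np.arange(0.0, cycle_length, sample_interval)
    v = np.empty_like(t)
    v[t < t0] = top
    on_ramp = (t >= t0) & (t < t_peak)
    v[on_ramp] = top + dvdt * (t[on_ramp] - t0)
    mid = (t >= t_peak) & (t < t_settle)
    v[mid] = decay(t[mid])
    v[t >= t_settle] = v_floor
    if eop > v_floor:
        # lift the very end so the final sample equals the EOP target
        tail = t >= t_settle
        v[tail] = v_floor + (eop - v_floor) * (t[tail] - t_settle) / (
            cycle_length - sample_interval - t_settle)
    if ead_spec is not None:
        sigma = ead_spec.width_ms / 2.355  # width as FWHM
        v = v + ead_spec.amplitude_mv * np.exp(-0.5 * ((t - ead_spec.time_ms) / sigma) ** 2)
    return APTrace(time=t, vm=v, cycle_length=cycle_length,
                   stimulus_duration=0.0, stimulus_amplitude=0.0)


# ----------------------------------------------------------- bundled fixtures


@dataclass(frozen=True)
class ReferenceFixtures:
    """Bundled desk-scale fixtures: drug library, control biomarker stats and
    the per-compound categorical outcomes of the reference characterization."""

    drugs: Tuple[DrugSpec, ...]
    biomarker_reference: Dict
    outcomes: pd.DataFrame  # index: drug; columns: tdp_class + 4 boolean flags


def load_reference_fixtures() -> ReferenceFixtures:
    drugs = tuple(load_drug_library())
    text = resources.files("purkinje_trials").joinpath(
        "data/reference_outcomes.yaml").read_text()
    doc = yaml.safe_load(text)
    outcomes = pd.DataFrame.from_dict(doc["drugs"], orient="index")
    outcomes.index.name = "drug"
    return ReferenceFixtures(drugs, load_biomarker_reference(), outcomes)
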