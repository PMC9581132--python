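"""In silico drug trials: dosed pacing across the population and aggregation.

For every member x concentration x frequency cell of a trial design, the
member is paced from its cached control steady state at that frequency
with the drug's pore-block residuals applied, the last beat is screened
for repolarization abnormalities, and biomarkers are computed only for
normal beats.  Summaries report, per concentration and frequency, the mean
percent biomarker change against each member's own control and the
EAD/DAD incidence across the population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import (Abnormality, BIOMARKER_NAMES, analyze_beat, percent_change)
from .cell_model import PacingProtocol, ReducedPurkinjeModel, SolverFailure
from .drug_block import DoseRequest, DrugSpec, block_set
from .population import Population

PCT_BIOMARKERS = ("APD10", "APD25", "APD50", "APD75", "APD90", "dVdtMax", "APA")


@dataclass
class TrialResult:
    """Per-member biomarker table for one drug over the full trial design."""

    drug: str
    population_hash: str
    rows: pd.DataFrame  # member, concentration_um, frequency_hz, biomarkers, abnormal
    manifest: Dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def write_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=2))


@dataclass
class TrialSummary:
    """Population-level mean percent changes and abnormality incidence."""

    drug: str
    population_hash: str
    table: pd.DataFrame  # concentration_um, frequency_hz, pct_*, incidence_pct, n_evaluable

    def incidence(self, concentration_um: float, frequency_hz: float) -> float:
        t = self.table
        row = t[(t.concentration_um == concentration_um) & (t.frequency_hz == frequency_hz)]
        return float(row.incidence_pct.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _biomarker_row(bm) -> Dict:
    row = bm.as_dict()
    row["abnormal"] = bm.abnormal.value
    return row


def run_drug_trial(model: ReducedPurkinjeModel, population: Population, drug: DrugSpec,
                   n_beats: int = 150,
                   concentrations_um: Optional[Sequence[float]] = None,
                   frequencies_hz: Optional[Sequence[float]] = None,
                   abnormality_beats: int = 1,
                   detector_kwargs: Optional[Dict] = None) -> TrialResult:
    """Run one compound's trial on a frozen calibrated population.

    Parameters
    ----------
    n_beats:
        Drug-exposure beats per cell of the design (150 at full scale; the
        reduced test profile uses 30).
    abnormality_beats:
        How many of the final beats are screened for abnormalities (1 =
        last beat only; >1 guards against alternans artifacts).
    """
    if not population.members:
        raise ValueError("population is empty")
    concs = tuple(concentrations_um if concentrations_um is not None
                  else drug.concentrations_um)
    freqs = tuple(frequencies_hz if frequencies_hz is not None else drug.frequencies_hz)
    missing = [f for f in freqs
               if any(f not in m.control_states for m in population.members)]
    if missing:
        raise ValueError(f"population lacks control steady states at {missing} Hz; "
                         "calibrate with these extra_frequencies first")
    det = detector_kwargs or {}
    records: List[Dict] = []
    for member in population.members:
        for freq in freqs:
            # concentration 0 = the member's cached control biomarkers
            control_bm = member.control_biomarkers[freq]
            records.append({"member": member.index, "concentration_um": 0.0,
                            "frequency_hz": freq, **_biomarker_row(control_bm)})
            for conc in concs:
                blk = block_set(DoseRequest(drug, conc))
                try:
                    state = member.control_states[freq]
                    protocol = PacingProtocol(freq, n_beats)
                    if abnormality_beats <= 1:
                        _, trace = model.pace(state, protocol, member.scalings, blk)
                        bm = analyze_beat(trace, **det)
                    else:
                        lead = max(n_beats - abnormality_beats + 1, 1)
                        state, trace = model.pace(
                            state, PacingProtocol(freq, lead), member.scalings, blk)
                        bm = analyze_beat(trace, **det)
                        for _ in range(abnormality_beats - 1):
                            state, trace = model.pace(
                                state, PacingProtocol(freq, 1), member.scalings, blk)
                            extra = analyze_beat(trace, **det)
                            if extra.abnormal is not Abnormality.NONE:
                                bm = extra
                        # biomarkers reported for the final beat when normal
                        if bm.abnormal is Abnormality.NONE:
                            bm = analyze_beat(trace, **det)
                except SolverFailure as exc:
                    records.append({"member": member.index, "concentration_um": conc,
                                    "frequency_hz": freq,
                                    **{k: None for k in BIOMARKER_NAMES},
                                    "abnormal": "failed", "failure": str(exc)})
                    continue
                records.append({"member": member.index, "concentration_um": conc,
                                "frequency_hz": freq, **_biomarker_row(bm)})
    rows = pd.DataFrame.from_records(records)
    manifest = {
        "drug": drug.name,
        "population_hash": population.population_hash(),
        "n_members": len(population),
        "n_beats": n_beats,
        "concentrations_um": list(concs),
        "frequencies_hz": list(freqs),
        "abnormality_beats": abnormality_beats,
        "detector": {"window_start_ms": det.get("window_start", 150.0),
                     "slope_threshold_V_per_s": det.get("slope_threshold", 0.01),
                     "repolarized_level_mV": det.get("repolarized_level", -70.0)},
    }
    return TrialResult(drug.name, population.population_hash(), rows, manifest)


def summarize(result: TrialResult,
              expected_population_hash: Optional[str] = None) -> TrialSummary:
    """Aggregate a TrialResult into per-cell means and incidences.

    Percent changes are averaged over members that are normal in both the
    dosed and the control cell; incidence is the percentage of the
    population flagged EAD/DAD.  Mixing results from different populations
    is refused via the population hash.
    """
    if expected_population_hash is not None \
            and result.population_hash != expected_population_hash:
        raise ValueError("result was produced on a different population "
                         f"({result.population_hash} != {expected_population_hash})")
    rows = result.rows
    n_members = rows.member.nunique()
    control = rows[rows.concentration_um == 0.0].set_index(["member", "frequency_hz"])
    records = []
    dosed = rows[rows.concentration_um > 0.0]
    for (conc, freq), cell in dosed.groupby(["concentration_um", "frequency_hz"]):
        abnormal = cell[cell.abnormal.isin(("EAD", "DAD"))]
        incidence = 100.0 * len(abnormal) / n_members
        rec = {"concentration_um": conc, "frequency_hz": freq,
               "incidence_pct": incidence}
        changes: Dict[str, List[float]] = {name: [] for name in PCT_BIOMARKERS}
        n_eval = 0
        for _, row in cell.iterrows():
            if row.abnormal != "none" or row.APD90 is None:
                continue
            ctrl = control.loc[(row.member, freq)]
            if ctrl.abnormal != "none":
                continue
            n_eval += 1
            for name in PCT_BIOMARKERS:
                changes[name].append(percent_change(row[name], ctrl[name]))
        rec["n_evaluable"] = n_eval
        for name in PCT_BIOMARKERS:
            rec[f"pct_{name}"] = float(np.mean(changes[name])) if changes[name] else None
        records.append(rec)
    table = pd.DataFrame.from_records(records).sort_values(
        ["frequency_hz", "concentration_um"]).reset_index(drop=True)
    return TrialSummary(result.drug, result.population_hash, table)


def apd90_changes_at(summary: TrialSummary, frequency_hz: float) -> Dict[float, float]:
    """Mean APD90 percent change per concentration at one pacing rate."""
    t = summary.table
    sel = t[t.frequency_hz == frequency_hz]
    return {float(r.concentration_um): (float(r.pct_APD90) if r.pct_APD90 is not None else np.nan)
            for r in sel.itertuples()}


def incidence_at(summary: TrialSummary, frequency_hz: float) -> Dict[float, float]:
    """EAD/DAD incidence (%) per concentration at one pacing rate."""
    t = summary.table
    sel = t[t.frequency_hz == frequency_hz]
    return {float(r.concentration_um): float(r.incidence_pct) for r in sel.itertuples()}
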