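"""Proarrhythmia risk classification and cross-assay consistency scoring.

Two binary classifiers translate trial outcomes into risky/safe calls:

* abnormality metric - a compound is risky if it induced an EAD or DAD in
  at least one model (or one in vitro fiber) at its slow pacing rate, at
  any tested concentration;
* APD90 metric - a compound is risky if its mean APD90 prolongation at
  1 Hz exceeds +10% at some concentration.

Calls are scored against the clinical torsade-de-pointes classes
(1/2 risky, NC safe) as a confusion matrix with integer-percent accuracy.
A three-level score rates the consistency of paired percent changes from
the two assay arms: strong agreement (same trend, difference <= 15 points),
qualitative agreement (same trend, larger difference), or disagreement
(opposite trend).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

RISKY, SAFE = "risky", "safe"


@dataclass(frozen=True)
class RiskConfig:
    apd90_threshold_pct: float = 10.0
    apd90_frequency_hz: float = 1.0
    consistency_tolerance_pct: float = 15.0

    def __post_init__(self):
        if self.apd90_threshold_pct <= 0 or self.consistency_tolerance_pct <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass(frozen=True)
class RiskCall:
    drug: str
    metric: str  # "EAD" or "APD90"
    prediction: str  # risky / safe
    truth: str  # risky / safe

    def __post_init__(self):
        if self.prediction not in (RISKY, SAFE) or self.truth not in (RISKY, SAFE):
            raise ValueError("prediction and truth must be 'risky' or 'safe'")

    @property
    def correct(self) -> bool:
        return self.prediction == self.truth


def truth_from_tdp_class(tdp_class: str) -> str:
    """CredibleMeds mapping: classes 1 and 2 are risky, NC is safe."""
    if str(tdp_class) in ("1", "2"):
        return RISKY
    if str(tdp_class) == "NC":
        return SAFE
    raise ValueError(f"unknown TdP class {tdp_class!r}")


def classify_by_abnormality(incidence_by_concentration: Mapping[float, float],
                            drug: str = "", truth: str = SAFE) -> RiskCall:
    """Risky iff any concentration shows non-zero EAD/DAD incidence at slow rate.

    ``incidence_by_concentration`` maps each tested concentration (uM) to
    the abnormality incidence (percent, or any count-like value) observed
    at the compound's slow pacing rate.
    """
    if not incidence_by_concentration:
        raise ValueError("no slow-rate incidence data")
    risky = any(v > 0 for v in incidence_by_concentration.values())
    return RiskCall(drug, "EAD", RISKY if risky else SAFE, truth)


def classify_by_apd90(apd90_change_by_concentration: Mapping[float, float],
                      config: RiskConfig = RiskConfig(),
                      drug: str = "", truth: str = SAFE) -> RiskCall:
    """Risky iff the max mean APD90 change strictly exceeds the threshold."""
    if not apd90_change_by_concentration:
        raise ValueError("no 1 Hz APD90 data")
    values = [v for v in apd90_change_by_concentration.values()
              if v is not None and not math.isnan(v)]
    if not values:
        raise ValueError("no evaluable APD90 changes")
    risky = max(values) > config.apd90_threshold_pct
    return RiskCall(drug, "APD90", RISKY if risky else SAFE, truth)


def confusion_and_accuracy(calls: Iterable[RiskCall]) -> Dict:
    """{TP, FP, TN, FN, accuracy_pct}; accuracy rounded half-up to integer."""
    calls = list(calls)
    if not calls:
        raise ValueError("empty call list")
    tp = sum(1 for c in calls if c.prediction == RISKY and c.truth == RISKY)
    fp = sum(1 for c in calls if c.prediction == RISKY and c.truth == SAFE)
    tn = sum(1 for c in calls if c.prediction == SAFE and c.truth == SAFE)
    fn = sum(1 for c in calls if c.prediction == SAFE and c.truth == RISKY)
    accuracy = 100.0 * (tp + tn) / len(calls)
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn,
            "accuracy_pct": int(math.floor(accuracy + 0.5))}


def consistency_category(insilico_pct: float, invitro_pct: float,
                         tolerance_pct: float = 15.0) -> str:
    """Three-level agreement of paired percent changes.

    Same trend (a value of exactly 0 agrees with either sign) and absolute
    difference <= tolerance -> "strong"; same trend but larger difference
    -> "qualitative"; opposite trend -> "disagreement".
    """
    if not (math.isfinite(insilico_pct) and math.isfinite(invitro_pct)):
        raise ValueError("percent changes must be finite")
    same_trend = (insilico_pct == 0 or invitro_pct == 0
                  or (insilico_pct > 0) == (invitro_pct > 0))
    if not same_trend:
        return "disagreement"
    if abs(invitro_pct - insilico_pct) <= tolerance_pct:
        return "strong"
    return "qualitative"
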