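"""Crystalluria risk assessment and prediction-performance metrics.

Crystalluria risk is judged against the drug's aqueous solubility window
(for ganciclovir 2600-6000 mg/L) rather than a single threshold: a median
luminal Cmax above the lower bound flags risk, above the upper bound flags
high risk.  Prediction performance uses the three standard base-10 fold /
error metrics:

    AFE  = 10 ** mean(log10(pred / obs))
    GMFE = 10 ** mean(|log10(pred / obs)|)
    RMSE = sqrt(mean((pred - obs) ** 2))
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

AFE_GATE = 1.25      # bioequivalence-style limit
GMFE_GATE = 2.0      # conventional twofold prediction limit


class MetricError(ValueError):
    pass


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise MetricError("expected a non-empty list of (predicted, observed)")
    return arr[:, 0], arr[:, 1]


def afe(pairs) -> float:
    """Average fold error; 1 means unbiased, >1 over-prediction."""
    pred, obs = _as_pairs(pairs)
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise MetricError("AFE requires strictly positive values")
    return float(10.0 ** np.mean(np.log10(pred / obs)))


def gmfe(pairs) -> float:
    """Geometric mean fold error (absolute average fold error); >= 1."""
    pred, obs = _as_pairs(pairs)
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise MetricError("GMFE requires strictly positive values")
    return float(10.0 ** np.mean(np.abs(np.log10(pred / obs))))


def rmse(pairs) -> float:
    pred, obs = _as_pairs(pairs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def validation_gate(metrics: dict, study_within_ci: Iterable[bool] = ()) -> dict:
    """Apply the model-acceptance rules to computed fold-error metrics.

    Flags AFE and GMFE against the 1.25-fold (bioequivalence) and twofold
    limits separately, and reports per-study confidence-interval coverage.
    """
    out = {}
    for name in ("afe", "gmfe"):
        if name in metrics:
            v = metrics[name]
            # bioequivalence-style bound is two-sided (0.8 - 1.25); the
            # conventional twofold criterion caps the reported fold error
            out[f"{name}_within_1.25"] = bool(max(v, 1.0 / v) <= AFE_GATE)
            out[f"{name}_within_2.0"] = bool(v <= GMFE_GATE)
    within = list(study_within_ci)
    if within:
        out["studies_within_99ci"] = int(sum(within))
        out["studies_total"] = len(within)
        out["all_studies_within_99ci"] = bool(all(within))
    out["pass"] = all(v for k, v in out.items()
                      if isinstance(v, bool))
    return out


@dataclass(frozen=True)
class CrystalluriaAssessment:
    segment: str
    cmax_values: np.ndarray            # mg/L per subject
    solubility_low: float
    solubility_high: float
    fraction_exceeding_low: float
    fraction_exceeding_high: float
    median_margin: float               # median Cmax / solubility_high

    @property
    def risk_flagged(self) -> bool:
        """Median luminal Cmax above the lower solubility bound."""
        return bool(np.median(self.cmax_values) > self.solubility_low)

    @property
    def high_risk(self) -> bool:
        """Median luminal Cmax above the upper solubility bound."""
        return bool(np.median(self.cmax_values) > self.solubility_high)


def assess_crystalluria(result, drug, segment: str = "MCD",
                        window: str = "last") -> CrystalluriaAssessment:
    """Compare per-subject luminal Cmax in a segment to the solubility window.

    ``result`` is a :class:`~renalpbpk.trial_engine.TrialResult`; ``window``
    selects the first-dose, last-dose or overall Cmax column.
    """
    col = {"first": f"{segment.lower()}_cmax_first",
           "last": f"{segment.lower()}_cmax_last",
           "overall": f"{segment.lower()}_cmax"}[window]
    if col not in result.metrics.columns:
        raise MetricError(f"segment '{segment}' not present in trial result")
    cmax = result.metrics[col].to_numpy()
    return CrystalluriaAssessment(
        segment=segment, cmax_values=cmax,
        solubility_low=drug.solubility_low,
        solubility_high=drug.solubility_high,
        fraction_exceeding_low=float(np.mean(cmax > drug.solubility_low)),
        fraction_exceeding_high=float(np.mean(cmax > drug.solubility_high)),
        median_margin=float(np.median(cmax) / drug.solubility_high))
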