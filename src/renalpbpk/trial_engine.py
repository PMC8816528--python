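"""Virtual trial orchestration.

Runs n subjects x n trials for a population spec, disease scenario, dosing
regimen and urine-flow setting; collects per-subject noncompartmental
metrics and per-segment luminal Cmax (first dose, last dose, overall), plus
trial-level percentile summaries.

Flow modes
----------
``scaled`` builds each subject's nephron flow profile from their own GFR
(urine flow fixed at the scenario value) — the physiologically natural mode.
``fixed`` applies one common filtrate flow profile, including its GFR, to
every subject; this mirrors simulator configurations in which altered
urine-flow runs cannot carry inter-individual variability in filtrate flows.
``auto`` selects ``fixed`` whenever the requested urine flow deviates from
the default 1 mL/min.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import mech_kidney, pbpk_core, virtual_population as vpop
from .mech_kidney import SEGMENTS
from .pbpk_core import DoseRegimen, SimulationError

#: GFR (mL/min) of the common filtrate-flow profile in fixed-flows mode.
FIXED_FLOW_GFR = 120.0

#: Fraction of failed subjects beyond which a trial aborts.
MAX_FAILURE_FRACTION = 0.10


class TrialError(RuntimeError):
    pass


@dataclass
class TrialResult:
    scenario: dict
    metrics: pd.DataFrame        # one row per (trial, subject)
    seg_cmax: pd.DataFrame       # long: trial, subject, segment, window, cmax
    failures: list
    regimen: DoseRegimen

    def median(self, column: str) -> float:
        return float(self.metrics[column].median())

    def summarize(self, column: str) -> dict:
        """Median and 5th/95th percentiles of individuals and trial means."""
        x = self.metrics[column]
        trial_means = self.metrics.groupby("trial")[column].mean()
        return {
            "individual": {"median": float(x.median()),
                           "p05": float(x.quantile(0.05)),
                           "p95": float(x.quantile(0.95))},
            "trial_mean": {"median": float(trial_means.median()),
                           "p05": float(trial_means.quantile(0.05)),
                           "p95": float(trial_means.quantile(0.95))},
        }


def _default_duration(regimen: DoseRegimen) -> float:
    if regimen.n_doses > 1:
        return float(regimen.dose_times[-1]) + regimen.interval
    return float(regimen.start_time) + 48.0


def run_trial(spec: vpop.PopulationSpec,
              scenario: vpop.CkdScenario | None,
              drug,
              regimen: DoseRegimen,
              urine_flow: float = 1.0,
              n_subjects: int = 200,
              n_trials: int = 1,
              seed: int = 0,
              flows_mode: str = "auto",
              fixed_gfr: float | None = None,
              secretion_scale: float = 1.0,
              duration: float | None = None,
              h: float = 0.05) -> TrialResult:
    """Simulate a virtual trial; fully deterministic per seed.

    ``secretion_scale`` uniformly rescales transporter activity (used by the
    reduced-secretion preset); sub-seeds are derived per (seed, trial index)
    so trial blocks are stable under reordering.
    """
    if n_subjects < 1:
        raise TrialError("n_subjects must be >= 1")
    if flows_mode == "auto":
        flows_mode = "fixed" if (urine_flow != 1.0 or fixed_gfr is not None) \
            else "scaled"
    if flows_mode not in ("fixed", "scaled"):
        raise TrialError(f"unknown flows_mode '{flows_mode}'")

    duration = duration if duration is not None else _default_duration(regimen)
    store_every = max(1, int(round(0.25 / h))) if duration > 100.0 else 1

    common_flows = None
    if flows_mode == "fixed":
        gfr_fixed = fixed_gfr if fixed_gfr is not None else FIXED_FLOW_GFR
        common_flows = mech_kidney.build_flow_profile(gfr_fixed, urine_flow)

    rows, cmax_rows, failures = [], [], []
    for trial in range(n_trials):
        ss = np.random.SeedSequence([int(seed), trial])
        subjects = vpop.sample_population(spec, n_subjects, ss)
        for i, subject in enumerate(subjects):
            if scenario is not None:
                subject = vpop.apply_ckd_scenario(subject, scenario)
            if secretion_scale != 1.0:
                subject = dataclasses.replace(
                    subject,
                    oat1_activity_scale=subject.oat1_activity_scale
                    * secretion_scale)
            if flows_mode == "fixed":
                flows = common_flows
                subject = dataclasses.replace(
                    subject, gfr=flows.gfr, urine_flow=urine_flow)
            else:
                flows = mech_kidney.build_flow_profile(subject.gfr, urine_flow)
                subject = dataclasses.replace(subject, urine_flow=urine_flow)
            try:
                res = pbpk_core.simulate_subject(
                    subject, drug, regimen, flows, duration,
                    h=h, store_every=store_every)
                met = pbpk_core.nca(res, regimen)
            except (SimulationError, ValueError) as exc:
                failures.append({"trial": trial, "subject": i,
                                 "error": str(exc)})
                continue
            row = {"trial": trial, "subject": i,
                   "gfr": subject.gfr, "gfr_bsa": subject.gfr_bsa,
                   "body_weight": subject.body_weight, "age": subject.age,
                   **dataclasses.asdict(met)}
            for j, seg in enumerate(SEGMENTS):
                row[f"{seg.lower()}_cmax"] = float(res.seg_cmax[:, j].max())
                row[f"{seg.lower()}_cmax_first"] = float(res.seg_cmax[0, j])
                row[f"{seg.lower()}_cmax_last"] = float(res.seg_cmax[-1, j])
            rows.append(row)
            for j, seg in enumerate(SEGMENTS):
                for w in range(res.seg_cmax.shape[0]):
                    cmax_rows.append({"trial": trial, "subject": i,
                                      "segment": seg, "dose_index": w,
                                      "cmax": float(res.seg_cmax[w, j])})
    n_total = n_trials * n_subjects
    if len(failures) > MAX_FAILURE_FRACTION * n_total:
        raise TrialError(f"{len(failures)} of {n_total} subjects failed")

    return TrialResult(
        scenario={"population": spec.name,
                  "scenario": scenario.name if scenario else None,
                  "severity": scenario.severity if scenario else None,
                  "urine_flow": urine_flow, "flows_mode": flows_mode,
                  "secretion_scale": secretion_scale,
                  "n_subjects": n_subjects, "n_trials": n_trials,
                  "seed": int(seed)},
        metrics=pd.DataFrame(rows), seg_cmax=pd.DataFrame(cmax_rows),
        failures=failures, regimen=regimen)


def accumulation_ratio(result: TrialResult, segment: str = "MCD") -> pd.Series:
    """Per-subject Cmax(last dose) / Cmax(first dose) for a segment."""
    if result.regimen.n_doses < 2:
        raise TrialError("accumulation ratio needs a multi-dose regimen")
    seg = segment.lower()
    return result.metrics[f"{seg}_cmax_last"] / result.metrics[f"{seg}_cmax_first"]


def clearance_shift(ckd_result: TrialResult, healthy_result: TrialResult,
                    metric: str) -> float:
    """Percent change of population medians: 100 * (1 - CKD / healthy)."""
    for r in (ckd_result, healthy_result):
        if metric not in r.metrics.columns:
            raise TrialError(f"metric '{metric}' not present in trial result")
    return 100.0 * (1.0 - ckd_result.median(metric)
                    / healthy_result.median(metric))


def severe_ckd_gfr50_preset() -> dict:
    """Named preset: CKD with GFR 40% of the fixed-flow healthy value and
    tubular secretion reduced by 60%, for altered-urine-flow simulations
    (the fixed-flows machinery caps how far GFR can be reduced once urine
    flow is changed, so this preset stands in for severe disease there)."""
    return {"spec": vpop.healthy_spec(), "scenario": None,
            "flows_mode": "fixed", "fixed_gfr": 0.4 * FIXED_FLOW_GFR,
            "secretion_scale": 0.4}
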