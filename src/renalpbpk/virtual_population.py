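"""Virtual subject sampling for healthy, ageing and CKD populations.

Populations are defined by distribution tables (log-normal for positive
physiological quantities, truncated normal for albumin, haematocrit and the
anthropometrics) plus covariate relations: body surface area by Du Bois,
cardiac output and kidney weight by allometry on body weight, and a linear
renal/cardiac ageing decline starting at age 40.  CKD severity classes are
defined on the BSA-normalised GFR scale (moderate 30-60, severe 15-30
mL/min/1.73 m^2) and de-normalised by each subject's BSA.

The five chronic-kidney-disease hypotheses about tubular secretion (no
change; proportional loss of proximal-tubule cellularity; proportional loss
of OAT1 abundance; proportional loss of OAT1+MATE; cellularity loss plus
uremic-solute inhibition of OAT1) are applied as multiplicative scenario
factors on top of a sampled subject, so two scenarios with the same seed
share every random draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pbpk_core import VirtualSubject

# covariate model constants
CO_COEF = 14.4          # L/h per kg^0.75 cardiac output allometry
KW_COEF = 4.3           # g kidney (both) per kg body weight
SCR_COEF = 90.0         # mg/dL * mL/min/1.73m2 inverse GFR relation
GFR_AGE_ONSET = 40.0    # years; decline is linear beyond this age
GFR_AGE_SLOPE = 0.01125  # fractional loss per year beyond onset
CO_AGE_SLOPE = 0.00475
BSA_REF = 1.73          # m^2

VOLUME_FRACTIONS = {"blood": 0.071, "liver": 0.026, "kidney": 0.0042,
                    "muscle": 0.40, "adipose": 0.21, "rest": 0.2488}
FLOW_FRACTIONS = {"liver": 0.245, "kidney": 0.19, "muscle": 0.17,
                  "adipose": 0.05, "rest": 0.345}


class PopulationError(ValueError):
    pass


def gfr_age_factor(age: float) -> float:
    return max(1.0 - GFR_AGE_SLOPE * max(age - GFR_AGE_ONSET, 0.0), 0.25)


def co_age_factor(age: float) -> float:
    return max(1.0 - CO_AGE_SLOPE * max(age - GFR_AGE_ONSET, 0.0), 0.50)


def du_bois_bsa(weight: float, height: float) -> float:
    return 0.007184 * weight ** 0.425 * height ** 0.725


@dataclass(frozen=True)
class PopulationSpec:
    """Distribution table and covariate switches for one virtual population."""

    name: str
    age_range: tuple[float, float]
    sex_ratio: float = 0.5                  # fraction male
    gfr_bsa_median: float = 107.0           # mL/min/1.73 m^2 before ageing
    gfr_bsa_cv: float = 0.15
    gfr_bsa_bounds: tuple[float, float] = (90.0, 170.0)
    age_decline: bool = True                # apply renal/cardiac ageing
    weight_median: Mapping[str, float] = field(
        default_factory=lambda: {"M": 81.0, "F": 66.0})
    weight_cv: float = 0.15
    height_mean: Mapping[str, float] = field(
        default_factory=lambda: {"M": 176.0, "F": 163.0})
    height_sd: Mapping[str, float] = field(
        default_factory=lambda: {"M": 6.5, "F": 6.0})
    hsa_mean: float = 46.4
    hsa_sd: float = 4.8
    hct_mean: float = 0.43
    hct_sd: float = 0.035
    ptcpgk_mean: float = 60.0               # 10^6 cells / g kidney
    ptcpgk_cv: float = 0.30
    oat1_mean: float = 1.0
    oat1_cv: float = 0.60
    mate_mean: float = 1.0
    mate_cv: float = 0.60
    oat1_activity: float = 1.0
    kidney_weight_scale: float = 1.0        # disease atrophy multiplier
    kidney_weight_cv: float = 0.20
    co_cv: float = 0.10
    urine_flow_mean: float = 1.0            # mL/min
    urine_flow_cv: float = 0.0


def healthy_spec() -> PopulationSpec:
    """Healthy volunteers, 18-65 y, GFR above 90 mL/min/1.73 m^2."""
    return PopulationSpec(name="healthy", age_range=(18.0, 65.0))


def neur_caucasian_spec() -> PopulationSpec:
    """General North-European-Caucasian adults, 18-95 y."""
    return PopulationSpec(name="neur_caucasian", age_range=(18.0, 95.0),
                          gfr_bsa_bounds=(25.0, 170.0))


def geriatric_spec() -> PopulationSpec:
    """Geriatric subset (65-95 y) of the general adult population."""
    return PopulationSpec(name="geriatric", age_range=(65.0, 95.0),
                          gfr_bsa_bounds=(15.0, 170.0))


def ckd_spec(severity: str) -> PopulationSpec:
    """Moderate (GFR 30-60) or severe (GFR 15-30) CKD population.

    Ages skew older, serum albumin and haematocrit are reduced, and kidneys
    are atrophied; proximal-tubule cellularity and transporter abundances
    stay at healthy means until a disease scenario rescales them.
    """
    if severity == "moderate":
        return PopulationSpec(
            name="ckd_moderate", age_range=(40.0, 90.0), age_decline=False,
            gfr_bsa_median=42.0, gfr_bsa_cv=0.16, gfr_bsa_bounds=(30.0, 60.0),
            hsa_mean=42.0, hsa_sd=4.8, hct_mean=0.39, hct_sd=0.04,
            kidney_weight_scale=0.85)
    if severity == "severe":
        return PopulationSpec(
            name="ckd_severe", age_range=(40.0, 90.0), age_decline=False,
            gfr_bsa_median=19.6, gfr_bsa_cv=0.12, gfr_bsa_bounds=(15.0, 30.0),
            hsa_mean=36.7, hsa_sd=4.6, hct_mean=0.33, hct_sd=0.04,
            kidney_weight_scale=0.75)
    raise PopulationError(f"unknown CKD severity '{severity}'")


@dataclass(frozen=True)
class CkdScenario:
    """One of the five disease hypotheses for tubular secretion in CKD."""

    name: str        # default | inh_ptcpgk | inh_oat1 | inh_oat1_mate |
                     # inh_ptcpgk_uremic
    severity: str    # moderate | severe

    _FACTORS = {
        # name -> (ptcpgk scale, oat1 scale, mate scale, activity value)
        # per severity, applied as mean rescalings.
        "default":           {"moderate": (1.0, 1.0, 1.0, 1.0),
                              "severe":   (1.0, 1.0, 1.0, 1.0)},
        "inh_ptcpgk":        {"moderate": (21.0 / 60.0, 1.0, 1.0, 1.0),
                              "severe":   (10.2 / 60.0, 1.0, 1.0, 1.0)},
        "inh_oat1":          {"moderate": (1.0, 0.35, 1.0, 1.0),
                              "severe":   (1.0, 0.17, 1.0, 1.0)},
        "inh_oat1_mate":     {"moderate": (1.0, 0.35, 0.35, 1.0),
                              "severe":   (1.0, 0.17, 0.17, 1.0)},
        "inh_ptcpgk_uremic": {"moderate": (21.0 / 60.0, 1.0, 1.0, 0.73),
                              "severe":   (10.2 / 60.0, 1.0, 1.0, 0.41)},
    }

    def __post_init__(self) -> None:
        if self.name not in self._FACTORS:
            raise PopulationError(f"unknown CKD scenario '{self.name}'")
        if self.severity not in ("moderate", "severe"):
            raise PopulationError(f"unknown severity '{self.severity}'")

    @property
    def factors(self) -> tuple[float, float, float, float]:
        return self._FACTORS[self.name][self.severity]


def apply_ckd_scenario(subject: VirtualSubject,
                       scenario: CkdScenario) -> VirtualSubject:
    """Rescale a sampled subject's secretion machinery for a CKD scenario.

    Because the underlying distributions are log-normal, rescaling the mean
    is identical to rescaling each sampled value, so scenarios sharing a
    seed share all random variability.
    """
    p, o, m, act = scenario.factors
    return replace(subject, ptcpgk=subject.ptcpgk * p,
                   oat1_rel=subject.oat1_rel * o,
                   mate_rel=subject.mate_rel * m,
                   oat1_activity_scale=subject.oat1_activity_scale * act)


# ---------------------------------------------------------------------------
# sampling

def _lognorm(rng, centre: float, cv: float, median: bool = False) -> float:
    if cv <= 0.0:
        # consume a draw so variance settings do not shift the stream
        rng.standard_normal()
        return centre
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = math.log(centre) if median else math.log(centre) - 0.5 * sigma * sigma
    return float(np.exp(mu + sigma * rng.standard_normal()))


def _trunc_normal(rng, mean: float, sd: float, lo: float, hi: float,
                  max_tries: int = 1000) -> float:
    if sd <= 0.0:
        rng.standard_normal()
        return mean
    for _ in range(max_tries):
        x = mean + sd * rng.standard_normal()
        if lo <= x <= hi:
            return x
    raise PopulationError(
        f"unsatisfiable truncation [{lo}, {hi}] for N({mean}, {sd})")


def sample_subject(spec: PopulationSpec, rng_seed) -> VirtualSubject:
    """Draw one virtual subject; deterministic given the seed.

    ``rng_seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)

    sex = "M" if rng.random() < spec.sex_ratio else "F"
    lo, hi = spec.age_range
    age = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    height = _trunc_normal(rng, spec.height_mean[sex], spec.height_sd[sex],
                           140.0, 210.0)
    weight = _lognorm(rng, spec.weight_median[sex], spec.weight_cv,
                      median=True)
    weight = min(max(weight, 35.0), 160.0)
    bsa = du_bois_bsa(weight, height)

    co = CO_COEF * weight ** 0.75 * _lognorm(rng, 1.0, spec.co_cv, median=True)
    if spec.age_decline:
        co *= co_age_factor(age)

    glo, ghi = spec.gfr_bsa_bounds
    for attempt in range(1000):
        gfr_bsa = _lognorm(rng, spec.gfr_bsa_median, spec.gfr_bsa_cv,
                           median=True)
        if spec.age_decline:
            gfr_bsa *= gfr_age_factor(age)
        if glo <= gfr_bsa <= ghi:
            break
    else:
        raise PopulationError(
            f"unsatisfiable GFR truncation {spec.gfr_bsa_bounds} "
            f"for population '{spec.name}'")
    gfr = gfr_bsa * bsa / BSA_REF

    kidney_weight = KW_COEF * weight * spec.kidney_weight_scale \
        * _lognorm(rng, 1.0, spec.kidney_weight_cv, median=True)
    kidney_weight = min(max(kidney_weight, 60.0), 800.0)
    ptcpgk = _lognorm(rng, spec.ptcpgk_mean, spec.ptcpgk_cv, median=True)
    oat1_rel = _lognorm(rng, spec.oat1_mean, spec.oat1_cv, median=True)
    mate_rel = _lognorm(rng, spec.mate_mean, spec.mate_cv, median=True)
    hsa = _trunc_normal(rng, spec.hsa_mean, spec.hsa_sd, 20.0, 65.0)
    hct = _trunc_normal(rng, spec.hct_mean, spec.hct_sd, 0.18, 0.58)
    urine_flow = _lognorm(rng, spec.urine_flow_mean, spec.urine_flow_cv,
                          median=True)

    volumes = {k: f * weight for k, f in VOLUME_FRACTIONS.items()}
    flows = {k: f * co for k, f in FLOW_FRACTIONS.items()}

    return VirtualSubject(
        age=age, sex=sex, body_weight=weight, body_surface_area=bsa,
        cardiac_output=co, tissue_volumes=volumes, tissue_flows=flows,
        kidney_weight=kidney_weight, gfr=gfr, gfr_bsa=gfr_bsa,
        ptcpgk=ptcpgk, oat1_rel=oat1_rel, mate_rel=mate_rel,
        oat1_activity_scale=spec.oat1_activity, hsa=hsa, haematocrit=hct,
        serum_creatinine=SCR_COEF / gfr_bsa, urine_flow=urine_flow)


def sample_population(spec: PopulationSpec, n: int, seed) -> list[VirtualSubject]:
    """Sample ``n`` subjects with per-subject child seeds (order-stable)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    return [sample_subject(spec, np.random.default_rng(child))
            for child in ss.spawn(n)]


def reference_subject() -> VirtualSubject:
    """Population-median healthy male (30 y, 81 kg, GFR 114 mL/min).

    Used as the anchor for elimination calibration.
    """
    weight, height, age = 81.0, 178.0, 30.0
    bsa = du_bois_bsa(weight, height)
    co = CO_COEF * weight ** 0.75
    return VirtualSubject(
        age=age, sex="M", body_weight=weight, body_surface_area=bsa,
        cardiac_output=co,
        tissue_volumes={k: f * weight for k, f in VOLUME_FRACTIONS.items()},
        tissue_flows={k: f * co for k, f in FLOW_FRACTIONS.items()},
        kidney_weight=KW_COEF * weight, gfr=114.0,
        gfr_bsa=114.0 * BSA_REF / bsa, ptcpgk=60.0,
        hsa=46.4, haematocrit=0.43,
        serum_creatinine=SCR_COEF / (114.0 * BSA_REF / bsa), urine_flow=1.0)


def geriatric_covariates(age: float, base: VirtualSubject) -> VirtualSubject:
    """Re-age a subject, applying renal and cardiac decline only.

    Cardiac output and GFR decline linearly beyond age 40 (calibrated so the
    65-95 y population medians fall about 19% and 45% below the 18-65 y
    medians); kidney weight, cellularity, transporter abundances and urine
    flow are left unchanged.
    """
    if not (65.0 <= age <= 95.0):
        raise PopulationError("geriatric age must lie in [65, 95]")
    g = gfr_age_factor(age) / gfr_age_factor(base.age)
    c = co_age_factor(age) / co_age_factor(base.age)
    gfr = base.gfr * g
    co = base.cardiac_output * c
    return replace(base, age=age, gfr=gfr, gfr_bsa=base.gfr_bsa * g,
                   cardiac_output=co,
                   tissue_flows={k: f * c for k, f in base.tissue_flows.items()},
                   serum_creatinine=SCR_COEF / (base.gfr_bsa * g))


# ---------------------------------------------------------------------------
# diagnostics

_DIAG_COLS = ("age", "body_weight", "kidney_weight", "gfr", "gfr_bsa",
              "ptcpgk", "oat1_capacity", "haematocrit", "hsa",
              "serum_creatinine")


def subjects_to_frame(subjects: Iterable[VirtualSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append({
            "age": s.age, "sex": s.sex, "body_weight": s.body_weight,
            "bsa": s.body_surface_area, "kidney_weight": s.kidney_weight,
            "gfr": s.gfr, "gfr_bsa": s.gfr_bsa, "ptcpgk": s.ptcpgk,
            "oat1_rel": s.oat1_rel, "mate_rel": s.mate_rel,
            "oat1_capacity": s.ptcpgk * s.oat1_rel * s.oat1_activity_scale
            * s.kidney_weight,
            "haematocrit": s.haematocrit, "hsa": s.hsa,
            "serum_creatinine": s.serum_creatinine,
            "cardiac_output": s.cardiac_output, "urine_flow": s.urine_flow,
        })
    return pd.DataFrame(rows)


def population_diagnostics(subjects: Sequence[VirtualSubject],
                           gap_bin_width: float = 5.0,
                           gap_min_bins: int = 2) -> dict:
    """Univariate summaries, pairwise correlations, and GFR gap report.

    The gap report flags contiguous empty bands of the pooled BSA-normalised
    GFR histogram lying strictly inside the observed range — the signature
    of stitching discrete severity classes together instead of a continuous
    disease axis.
    """
    if len(subjects) < 2:
        raise PopulationError("diagnostics require at least two subjects")
    df = subjects_to_frame(subjects)
    summary = pd.DataFrame({
        "median": df[list(_DIAG_COLS)].median(),
        "p05": df[list(_DIAG_COLS)].quantile(0.05),
        "p95": df[list(_DIAG_COLS)].quantile(0.95),
    })
    summary["p90_range"] = summary["p95"] - summary["p05"]
    zero_var = [c for c in _DIAG_COLS if df[c].nunique() == 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = df[list(_DIAG_COLS)].corr(method="spearman")
    for c in zero_var:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan

    x = df["gfr_bsa"].to_numpy()
    lo, hi = float(x.min()), float(x.max())
    gaps: list[tuple[float, float]] = []
    if hi - lo > gap_bin_width:
        edges = np.arange(math.floor(lo / gap_bin_width) * gap_bin_width,
                          hi + gap_bin_width, gap_bin_width)
        counts, _ = np.histogram(x, bins=edges)
        run_start = None
        for i, c in enumerate(counts):
            if c == 0 and run_start is None:
                run_start = i
            elif c > 0 and run_start is not None:
                if i - run_start >= gap_min_bins and edges[run_start] > lo:
                    gaps.append((float(edges[run_start]), float(edges[i])))
                run_start = None
    return {"summary": summary, "correlations": corr,
            "zero_variance": zero_var, "gaps": gaps}
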