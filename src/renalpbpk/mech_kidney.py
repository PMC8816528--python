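"""Mechanistic nephron: luminal filtrate compartments and tubular secretion.

The kidney is permeability-limited.  Filtrate enters the first proximal
tubule segment at GFR, water is progressively reabsorbed along the ordered
segments (PT1, PT2, PT3, loop of Henle, distal tubule, cortical and medullary
collecting duct) while the drug — poorly permeant, with negligible tubular
reabsorption — stays behind, so its luminal concentration rises toward the
terminal urine flow.  Active secretion is restricted to the proximal tubule:
basolateral uptake into a single proximal-tubule cell pool scaled by
cellularity (PTCPGK) and relative transporter abundance, followed by apical
MATE-mediated efflux into the proximal segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

SEGMENTS: tuple[str, ...] = ("PT1", "PT2", "PT3", "LoH", "DT", "CCD", "MCD")

#: Exit flow of each segment as a fraction of GFR — a canonical renal
#: water-reabsorption profile (about two thirds of filtrate reclaimed in the
#: proximal tubule, most of the rest in the loop and distal nephron).  The
#: medullary collecting duct exit equals the urine flow and is set per
#: scenario, not by a fraction.
DEFAULT_EXIT_FRACTIONS: Mapping[str, float] = {
    "PT1": 0.75, "PT2": 0.55, "PT3": 0.33, "LoH": 0.20, "DT": 0.10, "CCD": 0.05,
}

#: Luminal volumes (mL).  Small enough that luminal residence is
#: flow-dominated in every scenario (worst case: MCD at 0.1 mL/min gives a
#: 12 min residence time, short against the drug's plasma half-life).
DEFAULT_LUMINAL_VOLUMES_ML: Mapping[str, float] = {
    "PT1": 6.0, "PT2": 6.0, "PT3": 4.0, "LoH": 4.0, "DT": 2.0,
    "CCD": 1.5, "MCD": 1.2,
}

#: Fraction of apical efflux delivered to each proximal segment.  Organic
#: anion secretion is weighted to the S2/S3 portions of the proximal tubule,
#: where OAT expression is highest; the S1 lumen is dominated by freshly
#: filtered, still-dilute filtrate.
SECRETION_SPLIT: Mapping[str, float] = {"PT1": 0.10, "PT2": 0.50, "PT3": 0.40}

#: Proximal tubule cell volume, uL per 10^6 cells.
CELL_VOLUME_UL_PER_1E6 = 4.0

#: uL/min -> L/h
_CLINT_TO_L_PER_H = 60.0 / 1.0e6


class FlowProfileError(ValueError):
    pass


@dataclass(frozen=True)
class NephronFlowProfile:
    """Filtrate flow entering/leaving each tubular segment, down to urine.

    ``q_in``/``q_out`` are mL/min per segment; ``q_in`` of PT1 is the GFR and
    ``q_out`` of MCD is the urine flow.
    """

    segments: tuple[str, ...]
    q_in: Mapping[str, float]
    q_out: Mapping[str, float]
    luminal_volume: Mapping[str, float]  # mL
    urine_flow: float                    # mL/min

    @property
    def gfr(self) -> float:
        return self.q_in[self.segments[0]]


def build_flow_profile(gfr: float, urine_flow: float,
                       fractions: Mapping[str, float] | None = None,
                       luminal_volumes: Mapping[str, float] | None = None,
                       floor_to_urine_flow: bool = True,
                       ) -> NephronFlowProfile:
    """Build a nephron flow profile from GFR and urine flow (both mL/min).

    Intermediate exit flows are ``gfr * fraction(segment)``; the MCD exit is
    the urine flow regardless of fractions.  Monotonicity of exit flows along
    the nephron is enforced.

    Urine production is preserved at near-normal levels until renal failure,
    so at low GFR the fractional profile can undershoot the urine flow; with
    ``floor_to_urine_flow`` (default) distal exit flows are floored at the
    urine flow, i.e. distal water reabsorption shrinks rather than turning
    negative.  With the floor disabled, an inconsistent profile raises.
    """
    if not (0.0 < urine_flow < gfr):
        raise FlowProfileError(
            f"urine_flow must lie in (0, gfr): got {urine_flow} vs GFR {gfr}")
    fr = dict(DEFAULT_EXIT_FRACTIONS if fractions is None else fractions)
    vol = dict(DEFAULT_LUMINAL_VOLUMES_ML if luminal_volumes is None else luminal_volumes)
    q_out: dict[str, float] = {}
    prev = gfr
    for seg in SEGMENTS[:-1]:
        q = gfr * fr[seg]
        if floor_to_urine_flow:
            q = max(q, urine_flow)
        if q > prev + 1e-12:
            raise FlowProfileError(f"exit flow increases at segment {seg}")
        q_out[seg] = q
        prev = q
    if urine_flow > q_out["CCD"] + 1e-12:
        raise FlowProfileError(
            "urine_flow must not exceed the collecting-duct inflow "
            f"({q_out['CCD']:.2f} mL/min): water reabsorption cannot be negative")
    q_out["MCD"] = urine_flow
    q_in = {"PT1": gfr}
    for up, down in zip(SEGMENTS[:-1], SEGMENTS[1:]):
        q_in[down] = q_out[up]
    missing = [s for s in SEGMENTS if s not in vol or vol[s] <= 0]
    if missing:
        raise FlowProfileError(f"positive luminal volume required for {missing}")
    return NephronFlowProfile(segments=SEGMENTS, q_in=q_in, q_out=q_out,
                              luminal_volume=vol, urine_flow=urine_flow)


# ---------------------------------------------------------------------------
# whole-kidney clearance scalars

def uptake_clearance(subject, drug) -> float:
    """Whole-kidney basolateral uptake clearance of unbound drug, L/h.

    CLu = clint_oat1 x OAT1 abundance x uremic activity scale x PTCPGK x
    kidney weight, converted from uL/min to L/h.
    """
    return (drug.clint_oat1 * subject.oat1_rel * subject.oat1_activity_scale
            * subject.ptcpgk * subject.kidney_weight * _CLINT_TO_L_PER_H)


def efflux_clearance(subject, drug) -> float:
    """Whole-kidney apical (cell -> lumen) efflux clearance, L/h."""
    return (drug.clint_mate * subject.mate_rel
            * subject.ptcpgk * subject.kidney_weight * _CLINT_TO_L_PER_H)


def cell_volume_l(subject) -> float:
    """Aggregate proximal-tubule cell volume, L."""
    n_million = subject.ptcpgk * subject.kidney_weight  # 10^6 cells
    return n_million * CELL_VOLUME_UL_PER_1E6 * 1e-9 * 1e3  # uL -> L


def kidney_fluxes(state: Mapping[str, float], subject, drug,
                  flows: NephronFlowProfile) -> dict[str, float]:
    """Per-compartment rates (mg/h) of the mechanistic kidney block.

    ``state`` holds luminal amounts per segment (mg), the proximal cell
    amount under ``cell`` (mg), arterial plasma concentration ``c_plasma``
    and kidney-tissue plasma-equivalent concentration ``c_kidney_plasma``
    (mg/L).  Rates implement glomerular filtration of unbound drug into the
    PT1 lumen, transporter uptake into the cell pool, apical efflux
    distributed over the proximal segments, flow-driven luminal transfer and
    terminal outflow into urine.  Used directly by the ODE cross-check and
    unit tests; the production integrator assembles the same terms into its
    system matrix.
    """
    for seg in flows.segments:
        if state[seg] < 0:
            raise ValueError(f"negative luminal amount in {seg}")
    if state["cell"] < 0:
        raise ValueError("negative cell amount")

    fu = drug.fu_plasma
    cl_up = uptake_clearance(subject, drug)
    cl_ex = efflux_clearance(subject, drug)
    v_cell = cell_volume_l(subject)
    c_cell = state["cell"] / v_cell

    filtration = fu * flows.gfr * 0.06 * state["c_plasma"]
    uptake = cl_up * fu * state["c_kidney_plasma"]
    efflux = cl_ex * c_cell

    rates: dict[str, float] = {"cell": uptake - efflux}
    conc = {seg: state[seg] / (flows.luminal_volume[seg] * 1e-3)
            for seg in flows.segments}
    prev_seg = None
    for seg in flows.segments:
        inflow = filtration if prev_seg is None else \
            flows.q_out[prev_seg] * 0.06 * conc[prev_seg]
        outflow = flows.q_out[seg] * 0.06 * conc[seg]
        secretion = SECRETION_SPLIT.get(seg, 0.0) * efflux
        if drug.passive_perm_clearance > 0.0:
            secretion += drug.passive_perm_clearance * (
                fu * state["c_kidney_plasma"] - conc[seg])
        rates[seg] = inflow - outflow + secretion
        prev_seg = seg
    rates["urine"] = flows.q_out["MCD"] * 0.06 * conc["MCD"]
    rates["kidney_blood"] = -uptake
    rates["plasma"] = -filtration
    return rates


def steady_state_luminal_oracle(excretion_rate: float,
                                flows: NephronFlowProfile,
                                entry_rates: Mapping[str, float] | None = None,
                                ) -> dict[str, float]:
    """Closed-form steady-state luminal concentrations (mg/L).

    Solves the linear chain ``C_i = (q_in_i * C_{i-1} + entry_i) / q_out_i``
    directly, where the PT1 entry defaults to the whole excretion rate.  This
    is the independent oracle used to validate the ODE kidney at steady state
    under constant-rate input.

    Parameters are in mg/h (rates) and mL/min (flows).
    """
    entries = dict(entry_rates or {})
    if not entries:
        entries = {"PT1": excretion_rate}
    conc: dict[str, float] = {}
    prev = None
    for seg in flows.segments:
        q_out = flows.q_out[seg] * 0.06  # L/h
        if q_out <= 0.0:
            raise FlowProfileError(f"zero exit flow at segment {seg}")
        carried = 0.0 if prev is None else flows.q_out[prev] * 0.06 * conc[prev]
        conc[seg] = (carried + entries.get(seg, 0.0)) / q_out
        prev = seg
    return conc
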