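import dataclasses

import pytest

import renalpbpk as rp


@pytest.fixture(scope="session")
def drug():
    """Shipped ganciclovir parameters (calibrated elimination split)."""
    return rp.load_default_drug()


@pytest.fixture(scope="session")
def reference():
    return rp.reference_subject()


@pytest.fixture(scope="session")
def ref_flows(reference):
    return rp.build_flow_profile(reference.gfr, reference.urine_flow)


@pytest.fixture(scope="session")
def one_compartment():
    """Degenerate one-compartment setup: V = 10 L, CL = 1 L/h.

    The blood pool is the single compartment; the liver is a fast-
    equilibrating sliver carrying the whole clearance, and all other tissues
    and the kidney are shrunk to negligible volume and flow so the analytic
    bolus solution C(t) = (D/V) exp(-CL t / V) applies.
    """
    drug = rp.DrugParameters(
        molecular_weight=250.0, fu_plasma=1.0, blood_plasma_ratio=1.0,
        ka=1.0, f_abs=1.0, clint_met=1.0, clint_oat1=0.0, clint_mate=0.0,
        passive_perm_clearance=0.0, fe_target=0.5,
        solubility_low=1.0, solubility_high=2.0,
        kp={"liver": 1.0, "kidney": 1.0, "muscle": 1.0, "adipose": 1.0,
            "rest": 1.0})
    subject = rp.VirtualSubject(
        age=30.0, sex="M", body_weight=70.0, body_surface_area=1.8,
        cardiac_output=300.0,
        tissue_volumes={"blood": 10.0, "liver": 0.01, "kidney": 0.01,
                        "muscle": 1e-4, "adipose": 1e-4, "rest": 1e-4},
        tissue_flows={"liver": 1e4, "kidney": 1e-3, "muscle": 1e-6,
                      "adipose": 1e-6, "rest": 1e-6},
        kidney_weight=1.0, gfr=0.01, gfr_bsa=0.01, ptcpgk=1.0)
    flows = rp.build_flow_profile(subject.gfr, 0.005)
    return drug, subject, flows
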