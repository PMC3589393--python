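import numpy as np
import pytest

from liganddyn import (RelaxationSet, SpinConstants, make_params,
                       relaxation_observables)

TAU_M = 11.5e-9


@pytest.fixture(scope="session")
def constants() -> SpinConstants:
    return SpinConstants(field_1H=600.0)


@pytest.fixture(scope="session")
def tau_m() -> float:
    return TAU_M


#: accepted per-site model-free parameter sets for the ligand series
#: (model id, free parameters); used throughout for round-trip tests
ACCEPTED_PARAMS = {
    "n1_model2": (2, dict(s2=0.49, tau_e=90e-12)),
    "n1_model4": (4, dict(s2=0.35, tau_e=123e-12, rex=2.3)),
    "n2_model2": (2, dict(s2=0.72, tau_e=510e-12)),
    "n2_model5": (5, dict(sf2=0.97, ss2=0.71, tau_e=550e-12)),
    "n3_model5": (5, dict(sf2=0.92, ss2=0.79, tau_e=490e-12)),
    "n4_model5": (5, dict(sf2=0.95, ss2=0.76, tau_e=750e-12)),
    "n5_model5": (5, dict(sf2=0.96, ss2=0.78, tau_e=670e-12)),
}


def noiseless_observed(model_id, free, constants, tau_m=TAU_M,
                       rel_sigma=0.02, sigma_noe=0.05) -> RelaxationSet:
    """Forward-calculate a triple and package it with nominal sigmas."""
    params = make_params(model_id, tau_m, **free)
    pred = relaxation_observables(params, constants)
    return RelaxationSet(
        T1=pred.T1, sigma_T1=rel_sigma * pred.T1,
        T2=pred.T2, sigma_T2=rel_sigma * pred.T2,
        NOE=pred.NOE, sigma_NOE=sigma_noe,
        field_1H=constants.field_1H,
    )
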