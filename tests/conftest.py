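import numpy as np
import pandas as pd
import pytest

from ftdnorm import (CohortSpec, GroupSpec, ROIParams, default_genfi_spec,
                     fit_normative_models, generate_carriers,
                     generate_controls)
from ftdnorm.cohort import SCANNERS


def small_roi_model(sigma: float = 200.0) -> dict:
    """Two-ROI generative model, cheap enough for repeated simulation."""
    offsets = (0.0, 30.0, -20.0, 40.0, -30.0)
    return {
        ("hippocampus", "volume"): ROIParams(
            intercept=7400.0, beta_age=-20.0, beta_sex=150.0,
            beta_tiv=0.003, scanner_offsets=offsets, sigma=sigma),
        ("uf", "FA"): ROIParams(
            intercept=0.48, beta_age=-8e-4, beta_sex=0.004, beta_tiv=0.0,
            scanner_offsets=(0.0, 0.004, -0.003, 0.005, -0.004), sigma=0.025),
        ("uf", "MD"): ROIParams(
            intercept=7.8e-4, beta_age=1.5e-6, beta_sex=-2e-6, beta_tiv=0.0,
            scanner_offsets=(0.0, 4e-6, -3e-6, 5e-6, -4e-6), sigma=3e-5),
    }


def controls_only_spec(n: int = 240, seed: int = 0) -> CohortSpec:
    return CohortSpec(controls=GroupSpec(n, 44.8, 12.2, 0.429),
                      carriers={}, seed=seed)


@pytest.fixture(scope="session")
def genfi_spec():
    return default_genfi_spec()


@pytest.fixture(scope="session")
def control_tables():
    """240 controls with the two-ROI model, fixed seed."""
    spec = controls_only_spec(240)
    return generate_controls(spec, small_roi_model(), seed=11)


@pytest.fixture(scope="session")
def fitted_models(control_tables):
    controls, measures = control_tables
    return fit_normative_models(controls, measures)


@pytest.fixture(scope="session")
def carrier_tables(genfi_spec):
    effects = {("C9orf72", "presymptomatic"): {("hippocampus", "volume"): -1.5,
                                               ("uf", "MD"): 1.2}}
    return generate_carriers(genfi_spec, small_roi_model(), effects, seed=13)
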