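"""Shared fixtures: small, fast synthetic ground truths and cohorts."""

import numpy as np
import pandas as pd
import pytest

from ceranet.preprocess import log_z_transform
from ceranet.synth_cohort import (default_ground_truth, draw_case_cohort,
                                  generate_ground_truth, simulate_cohort)


@pytest.fixture(scope="session")
def null_truth():
    """3+3 elongation-chain panel, no hazard effects anywhere."""
    return generate_ground_truth(
        p_cer=3, p_dhcer=3, topology="elongation_chain",
        edge_weight_range=(0.4, 0.6),
        effect_spec={"direct_log_hr": {"t2d": {}}}, seed=7)


@pytest.fixture(scope="session")
def effect_truth():
    """Chain panel with one strong direct effector (Cer16:0, logHR 0.4/SD)
    flanked by network-confounded nulls."""
    return generate_ground_truth(
        p_cer=3, p_dhcer=3, topology="elongation_chain",
        edge_weight_range=(0.4, 0.6),
        effect_spec={"direct_log_hr": {"t2d": {"Cer16:0": 0.4}}}, seed=7)


@pytest.fixture(scope="session")
def effect_cohort(effect_truth):
    return simulate_cohort(effect_truth, 4000, seed=11, case_fraction=0.15)


@pytest.fixture(scope="session")
def effect_sample(effect_cohort):
    return draw_case_cohort(effect_cohort, 0.3, "t2d", seed=12)


@pytest.fixture(scope="session")
def effect_panel(effect_cohort):
    return log_z_transform(effect_cohort.data[list(effect_cohort.metabolites)])


@pytest.fixture(scope="session")
def study_truth():
    """The full 25-metabolite reference study conditions."""
    return default_ground_truth(0)
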