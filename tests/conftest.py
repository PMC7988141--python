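"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from rarewas import simulate as sim


@pytest.fixture(scope="session")
def small_null_cohort():
    """Small cohort with no embedded effects."""
    cfg = sim.SimConfig(n_cases=120, n_controls=480, n_variants=200,
                        n_genes=20, seed=101)
    truth = sim.TrueArchitecture()
    return sim.generate_cohort(cfg, truth), cfg, truth


@pytest.fixture(scope="session")
def effect_cohort():
    """Mid-sized cohort carrying the default embedded architecture."""
    cfg = sim.SimConfig(n_cases=300, n_controls=3000, n_variants=400,
                        n_genes=40, seed=202)
    truth = sim.default_truth()
    gm, ann, man = sim.generate_cohort(cfg, truth)
    man = sim.attach_clinical(man, truth, seed=203)
    return (gm, ann, man), cfg, truth
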