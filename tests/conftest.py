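"""Shared fixtures: a small synthetic case-control study with known truth."""

import numpy as np
import pytest

import pbastand as pb


def make_study(seed: int, n_population: int = 80_000, target_risk: float = 4e-3,
               exposure_rr: float = 2.0, se: float = 0.79, sp: float = 0.84):
    """Generate a compact study: population, oracle, misclassified sample.

    Returns (dataset DataFrame with reported `exposure`, realized sampling
    fractions, oracle effects, population).
    """
    coefs = dict(pb.synthetic_data.DEFAULT_OUTCOME_COEFS)
    coefs["exposure"] = float(np.log(exposure_rr))
    cfg = pb.PopulationConfig(
        n_population=n_population,
        target_risk=target_risk,
        outcome_coefs=coefs,
        sf_case=0.9,
        sf_control=700 / n_population,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pop = pb.generate_population(cfg, rng)
    oracle = pb.oracle_effects(pop)
    cc = pb.sample_case_control(pop, rng=rng)
    data = pb.apply_misclassification(cc.data, pb.SensSpec(se, sp), rng)
    return data, cc.sf, oracle, pop


@pytest.fixture(scope="session")
def small_study():
    """A ~1000-record misclassified case-control sample with ground truth."""
    return make_study(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
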