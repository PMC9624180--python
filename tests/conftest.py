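"""Shared fixtures: synthetic crystals and (expensive) full pipeline
solutions reused across test modules."""

import numpy as np
import pytest

import sadsmar as s
from sadsmar import pipeline, smar_engine, synthetic_data


@pytest.fixture(scope="session")
def tiny_bundle():
    return synthetic_data.make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def se_small_clean():
    return synthetic_data.make_fixture("se_like_small", noise_fraction=0.0, seed=2022)


@pytest.fixture(scope="session")
def se_small_noisy():
    return synthetic_data.make_fixture("se_like_small", noise_fraction=0.05, seed=2022)


@pytest.fixture(scope="session")
def oracle50():
    """A 50-atom random model with a moderate anomalous substructure."""
    spec = synthetic_data.FixtureSpec(
        cell=(22.0, 24.0, 26.0, 90.0, 90.0, 90.0), n_light=46, n_anom=4,
        anom_element="S", anom_f0=16.0, anom_f_dprime=4.0, dmin=2.5,
        noise_fraction=0.0, min_as_separation=6.0, b_range=(5.0, 5.0), seed=5,
    )
    return synthetic_data.generate_crystal(spec)


SOLVE_OPTIONS = smar_engine.SmarOptions(max_cycles=150)


@pytest.fixture(scope="session")
def clean_solution(se_small_clean):
    model, refs, truth = se_small_clean
    return s.solve(refs, np.ones(8), n_expected_sites=8, n_trials=25,
                   base_seed=1, options=SOLVE_OPTIONS, reference=truth)


@pytest.fixture(scope="session")
def noisy_solution(se_small_noisy):
    model, refs, truth = se_small_noisy
    return s.solve(refs, np.ones(8), n_expected_sites=8, n_trials=25,
                   base_seed=1, options=SOLVE_OPTIONS, reference=truth)


@pytest.fixture(scope="session")
def shuffled_control(se_small_noisy, noisy_solution):
    """SMAR trials on signal-destroyed data (|D| shuffled across hkl),
    classified against the intact-data CC_h level."""
    model, refs, truth = se_small_noisy
    dset, _, _ = pipeline.build_dset(refs, np.ones(8))
    rng = np.random.default_rng(7)
    dset.x = dset.x[rng.permutation(len(dset.x))]
    level = float(np.nanmax(noisy_solution.trials.final_cc))
    return smar_engine.run_trials(dset, n_trials=10, base_seed=1,
                                  options=SOLVE_OPTIONS, reference_cc=level)
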