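import pandas as pd
import pytest

import socialstate as ss


def bundle_dict(bundle: ss.SimBundle) -> dict:
    return {
        "males": bundle.males,
        "events": bundle.events,
        "states": bundle.states,
        "weights": bundle.weights,
        "paternity": bundle.paternity,
        "weight_change": bundle.weight_change,
    }


@pytest.fixture(scope="session")
def small_bundle() -> ss.SimBundle:
    """A compact simulated cohort shared by read-only tests."""
    cfg = ss.SimConfig(n_groups=4, years=4.0, mean_adult_males_per_group=8.0, seed=11)
    return ss.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_designs(small_bundle) -> dict:
    return ss.build_design_tables(bundle_dict(small_bundle))


@pytest.fixture(scope="session")
def study_scale_designs() -> tuple:
    """One study-scale dataset (quadratic-age generative law) plus its config."""
    cfg = ss.SimConfig(seed=2024, true_params=ss.TrueParams(variant="quadratic_age"))
    bundle = ss.simulate_population(cfg)
    designs = ss.build_design_tables(bundle_dict(bundle))
    return cfg, designs
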