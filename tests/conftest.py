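import numpy as np
import pytest

from catbank import (
    ItemBank,
    ItemParameters,
    estimate_person_locations,
)
from catbank.synthetic import GeneratorSpec, generate_item_bank, simulate_responses


def make_item(item_id="it", n_categories=5, location=0.0, thresholds=None):
    if thresholds is None:
        m = n_categories - 1
        thresholds = np.linspace(-1.5, 1.5, m) if m > 1 else [0.0]
        thresholds = np.asarray(thresholds) - np.mean(thresholds)
    return ItemParameters(
        item_id=item_id,
        n_categories=n_categories,
        location=location,
        thresholds=tuple(thresholds),
    )


@pytest.fixture(scope="session")
def dich_item():
    return make_item("dich", 2, 0.0)


@pytest.fixture(scope="session")
def bank12():
    """12 well-behaved five-category items, the clean calibration bank."""
    return generate_item_bank(GeneratorSpec(seed=42), n_items=12)


@pytest.fixture(scope="session")
def clean_responses(bank12):
    """Model-true responses from 500 standard-normal persons."""
    rng = np.random.default_rng(1)
    thetas = rng.standard_normal(500)
    resp = simulate_responses(bank12, thetas, seed=2)
    return resp, thetas


@pytest.fixture(scope="session")
def clean_abilities(bank12, clean_responses):
    resp, _ = clean_responses
    return estimate_person_locations(resp, bank12, "WL")


@pytest.fixture(scope="session")
def cat_bank():
    """11-item five-category bank emulating a calibrated QoL CAT bank:
    locations uniform over [-2, 2], wide thresholds so reliability .90
    requires nearly the full bank (as observed for real QoL item banks)."""
    spec = GeneratorSpec(seed=42, threshold_spread=3.0)
    return generate_item_bank(spec, n_items=11)
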