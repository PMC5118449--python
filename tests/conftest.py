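"""Shared fixtures: bundled rules and small synthetic datasets."""

import pytest

import liversar as lv


@pytest.fixture(scope="session")
def table1_rules():
    return lv.load_table1_alerts()


@pytest.fixture(scope="session")
def sulfonamide_fixture():
    """50+50 molecules with a planted benzenesulfonamide alert."""
    spec = lv.FixtureSpec(
        n_pos=50,
        n_neg=50,
        seed=11,
        planted_alerts=[lv.PlantedAlert("NS(=O)(=O)c1ccccc1", 0.9, 0.05)],
    )
    return lv.generate(spec)


@pytest.fixture()
def tiny_dataset():
    return lv.dataset_from_smiles(
        [
            ("m1", "CCO", lv.Activity.NON_HEPATOTOXIC),
            ("m2", "NS(=O)(=O)c1ccccc1", lv.Activity.HEPATOTOXIC),
            ("m3", "c1ccncc1", lv.Activity.HEPATOTOXIC),
            ("m4", "CCCCCC", lv.Activity.NON_HEPATOTOXIC),
            ("m5", "Nc1ccccc1", lv.Activity.HEPATOTOXIC),
            ("m6", "C1CCCCC1", lv.Activity.NON_HEPATOTOXIC),
        ]
    )
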