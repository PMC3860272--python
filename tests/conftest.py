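import pytest

from alkox import scenario_paper_defaults, simulate_incubation

# Published study values used as fixed inputs across tests:
# consumption rates (mean, sd) and total SRRs (mean, sd), nmol mL-1 day-1.
PAPER_RATES = {
    "methane": (263.0, 68.0),
    "ethane": (168.0, 5.0),
    "propane": (354.0, 37.0),
    "butane": (125.0, 16.0),
}
PAPER_SRRS = {
    "N2": (94.0, 0.0),
    "methane": (297.0, 33.0),
    "ethane": (330.0, 121.0),
    "propane": (246.0, 44.0),
    "butane": (220.0, 38.0),
}
PAPER_INHIBITED = {
    "methane": (29.0, 1.0),
    "ethane": (12.0, 4.0),
    "propane": (10.0, 5.0),
    "butane": (14.0, 2.0),
}


@pytest.fixture(scope="session")
def paper_rates():
    return dict(PAPER_RATES)


@pytest.fixture(scope="session")
def paper_srrs():
    return dict(PAPER_SRRS)


@pytest.fixture(scope="session")
def paper_inhibited():
    return dict(PAPER_INHIBITED)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Study-condition scenario with measurement noise switched off."""
    return simulate_incubation(scenario_paper_defaults(seed=7, noise_cv=0.0))
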