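import pytest

from sgltsim import (build_geometry, inhibitor_params, physiology_defaults,
                     transporter_params)


@pytest.fixture(scope="session")
def phys():
    return physiology_defaults()


@pytest.fixture(scope="session")
def healthy():
    return transporter_params("healthy")


@pytest.fixture(scope="session")
def t2dm():
    return transporter_params("t2dm")


@pytest.fixture(scope="session")
def dapa():
    return inhibitor_params("dapagliflozin")


@pytest.fixture(scope="session")
def healthy_geom(phys, healthy):
    return build_geometry(phys, healthy)


@pytest.fixture(scope="session")
def healthy_drug_geom(phys, healthy, dapa):
    return build_geometry(phys, healthy, dapa)
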