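import pytest

from clonalkit import synthetic_data as sd


@pytest.fixture(scope="session")
def library():
    """11-barcode whitelist labelled to match the default clone mixture."""
    return sd.default_library(seed=0)


@pytest.fixture(scope="session")
def config():
    return sd.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def clone_tree():
    """Six-clone topology: the two tumorigenic clones form one cherry."""
    return (("CL31", "CL49"), (("CL17", "CL46"), ("CL09", "CL44")))


@pytest.fixture(scope="session")
def parent_mixture():
    """Parental mixture dominated by the CL31/CL49 common ancestor."""
    return {
        "CL31": 0.45,
        "CL49": 0.35,
        "CL17": 0.05,
        "CL46": 0.05,
        "CL09": 0.05,
        "CL44": 0.05,
    }
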