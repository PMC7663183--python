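import numpy as np
import pytest

from fabqsar import synthetic
from fabqsar.germline import HEAVY_FRAMEWORKS, KAPPA_FRAMEWORKS


def build_v_domain(kind: str, cdr1: str, cdr2: str, cdr3: str) -> str:
    fw = HEAVY_FRAMEWORKS if kind == "heavy" else KAPPA_FRAMEWORKS
    return (fw["FR1"] + cdr1 + fw["FR2"] + cdr2 + fw["FR3"] + cdr3
            + fw["FR4"])


@pytest.fixture(scope="session")
def kappa_v():
    """Kappa V-domain with known CDR lengths 6 / 3 / 9."""
    return build_v_domain("kappa", "QSISSY", "AAS", "QQSYSTPLT")


@pytest.fixture(scope="session")
def heavy_v():
    """Heavy V-domain with known CDR lengths 8 / 8 / 12."""
    return build_v_domain("heavy", "GGTISDYA", "ISGSGGST",
                          "AKDLRYYGMDVH")


@pytest.fixture(scope="session")
def fab_annotations():
    spec = synthetic.FixtureSpec(n_samples=4, seed=11)
    return synthetic.make_fab_annotations(spec)


@pytest.fixture(scope="session")
def toy_structure():
    return synthetic.make_toy_structure("GASTVLIKDERNQHYPMGSA",
                                        geometry="sphere_cluster")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
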