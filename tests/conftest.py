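import numpy as np
import pandas as pd
import pytest

from buteo.pedigree import Pedigree
from buteo.simulate import (
    PedigreeSimConfig,
    PolygenicSimConfig,
    simulate_pedigree,
    simulate_polygenic,
)


@pytest.fixture
def nuclear_pedigree() -> Pedigree:
    """Two founders and three joint offspring."""
    return Pedigree(
        pd.DataFrame(
            {
                "id": ["S1", "D1", "O1", "O2", "O3"],
                "sire": [None, None, "S1", "S1", "S1"],
                "dam": [None, None, "D1", "D1", "D1"],
                "sex": ["M", "F", "F", "M", "F"],
                "morph7": [3, 4, 3, 2, 6],
            }
        )
    )


@pytest.fixture
def three_generation_pedigree() -> Pedigree:
    """Grandparents, parents (one full-sib mating) and grandchildren."""
    rows = [
        ("G1", None, None, "M"),
        ("G2", None, None, "F"),
        ("P1", "G1", "G2", "M"),
        ("P2", "G1", "G2", "F"),
        ("X1", "P1", "P2", "F"),  # offspring of full sibs: inbred
        ("U1", None, None, "M"),
        ("X2", "U1", "P2", "M"),
    ]
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))


def random_pedigree(seed: int, n: int = 18) -> Pedigree:
    """Random multi-generation pedigree (possibly inbred) for oracle checks."""
    rng = np.random.default_rng(seed)
    rows = []
    males, females = [], []
    for k in range(n):
        iid = f"I{k:02d}"
        sex = "M" if rng.random() < 0.5 else "F"
        sire = dam = None
        if males and females and rng.random() < 0.75:
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
        (males if sex == "M" else females).append(iid)
        rows.append((iid, sire, dam, sex))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))


@pytest.fixture(scope="session")
def study_polygenic() -> Pedigree:
    """Study-scale pedigree with polygenic phenotypes at the default truth."""
    ped = simulate_pedigree(PedigreeSimConfig(seed=101))
    return simulate_polygenic(ped, PolygenicSimConfig(seed=102))


@pytest.fixture(scope="session")
def small_polygenic() -> Pedigree:
    """Reduced-scale polygenic dataset for fast sampler tests."""
    ped = simulate_pedigree(PedigreeSimConfig(n_pairs=60, seed=201))
    return simulate_polygenic(ped, PolygenicSimConfig(seed=202))
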