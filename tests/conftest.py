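import numpy as np
import pandas as pd
import pytest

from rumigen.pedigree import build_A, read_pedigree
from rumigen.simulate import half_sib_pedigree


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def trio_pedigree():
    """Two founder parents and one offspring."""
    return read_pedigree(
        pd.DataFrame(
            {"animal": ["P1", "P2", "O"], "sire": ["0", "0", "P1"], "dam": ["0", "0", "P2"]}
        )
    )


@pytest.fixture()
def fullsib_mating_pedigree():
    """Founders P1 x P2, full sibs B and C, inbred offspring O of B x C."""
    return read_pedigree(
        pd.DataFrame(
            {
                "animal": ["P1", "P2", "B", "C", "O"],
                "sire": ["0", "0", "P1", "P1", "B"],
                "dam": ["0", "0", "P2", "P2", "C"],
            }
        )
    )


def random_pedigree(n, rng, n_founders=10):
    """Random acyclic pedigree with inbreeding (parents drawn from earlier animals)."""
    rows = [{"animal": f"A{i}", "sire": "0", "dam": "0"} for i in range(n_founders)]
    for i in range(n_founders, n):
        s, d = rng.integers(0, i, size=2)
        rows.append({"animal": f"A{i}", "sire": f"A{s}", "dam": f"A{d}"})
    return read_pedigree(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def half_sib_design():
    """Shared balanced half-sib design (100 sires x 10 progeny) with its A."""
    ped = half_sib_pedigree(100, 10)
    A = build_A(ped)
    pos = {a: i for i, a in enumerate(A.ids)}
    return ped, A, pos
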