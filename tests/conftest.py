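import numpy as np
import pytest

from ecomorph import datasets, prey


@pytest.fixture(scope="session")
def prey_matrix():
    return datasets.load_prey_traits()


@pytest.fixture(scope="session")
def diet_table():
    return datasets.load_diet_importance()


@pytest.fixture(scope="session")
def block_matrix():
    """Three perfectly separated blocks of 5 items (zero within-block noise)."""
    vals = np.zeros((15, 30))
    for b in range(3):
        vals[b * 5 : (b + 1) * 5, b * 10 : (b + 1) * 10] = 1
    return prey.PreyTraitMatrix(
        items=tuple(f"i{b}_{j}" for b in range(3) for j in range(5)),
        traits=tuple(f"t{j}" for j in range(30)),
        values=vals,
    )


def star_newick(n: int, length: float = 1.0) -> str:
    return "(" + ",".join(f"sp{i:02d}:{length}" for i in range(1, n + 1)) + ");"
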