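import numpy as np
import pytest

from cyanodelim.core_io import Alignment, UltrametricTree

# a 6-tip ultrametric tree with hand-checkable node heights:
# (A,B) at 1, (E,F) at 1.5, (C,D) at 2, (CD,EF) at 5, root at 10
SIX_TIP_NEWICK = "((A:1,B:1):9,((C:2,D:2):3,(E:1.5,F:1.5):3.5):5);"


@pytest.fixture
def six_tip_tree() -> UltrametricTree:
    return UltrametricTree.from_newick(SIX_TIP_NEWICK)


@pytest.fixture
def small_alignment() -> Alignment:
    return Alignment(["s1", "s2", "s3", "s4", "s5"],
                     ["ACGT", "ACGT", "ACGA", "ACTA", "ACGA"])


def random_coassignment(rng: np.random.Generator, n: int) -> np.ndarray:
    """Noisy block-structured matrix, the shape real co-assignments take."""
    base = rng.integers(0, 3, n)
    P = (base[:, None] == base[None, :]).astype(float)
    noise = rng.uniform(0, 0.5, (n, n))
    noise = (noise + noise.T) / 2
    P = np.clip(P * 0.7 + 0.3 * (1 - noise), 0, 1)
    P = (P + P.T) / 2
    np.fill_diagonal(P, 1.0)
    return P
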