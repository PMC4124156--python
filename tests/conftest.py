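import numpy as np
import pytest

from helixcov.detector import StrengthDistributions, build_pattern_template
from helixcov.synth import default_seven_helix_topology, gen_coupling_matrix

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def default_dists():
    """Detector distributions matching the synthetic generator defaults."""
    return StrengthDistributions(
        fg_shape=4.0, fg_scale=0.1, bg_shape=1.0, bg_scale=0.05, prior=0.3
    )


@pytest.fixture
def default_template():
    return build_pattern_template()


@pytest.fixture
def seven_helix_case():
    """Planted seven-helix topology and its coupling matrix (default seed)."""
    pt = default_seven_helix_topology(seed=1234)
    return pt, gen_coupling_matrix(pt)


def random_msa(rng: np.random.Generator, n: int, L: int):
    """Alignment of independent uniformly random columns."""
    from helixcov.msa import Msa

    cols = rng.integers(0, 20, size=(n, L))
    seqs = ["".join(AA20[c] for c in row) for row in cols]
    return Msa(seqs, [f"s{i}" for i in range(n)]), cols
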