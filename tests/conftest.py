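import numpy as np
import pandas as pd
import pytest

from pcnfold.structure_io import (
    STANDARD_AA,
    PotentialMatrix,
    WeightedContactNetwork,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20160728)


@pytest.fixture
def synthetic_potentials(rng):
    """Random symmetric 20x20 potential table (values in [-6, 0])."""
    raw = -6.0 * rng.random((20, 20))
    sym = 0.5 * (raw + raw.T)
    df = pd.DataFrame(sym, index=list(STANDARD_AA), columns=list(STANDARD_AA))
    return PotentialMatrix(df, name="synthetic")


def random_weighted_network(rng, n, p=0.5, wmax=4.0):
    """Random symmetric weighted network with link weights in [1, 1 + wmax].

    Returns None when a node ends up isolated (callers skip those draws).
    """
    adj = np.triu((rng.random((n, n)) < p).astype(float), 1)
    adj += adj.T
    if adj.sum(axis=1).min() == 0:
        return None
    w = np.triu(adj * (1.0 + rng.random((n, n)) * wmax), 1)
    w += w.T
    return WeightedContactNetwork(w)


#: hand-written PDB snippet: 3 CA records, chain A (3-4-5 triangle in x-y)
PDB_THREE_RESIDUES = """\
HEADER    TEST PROTEIN
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.000   4.000   0.000  1.00  0.00           C
ATOM      4  CA  TRP A   3       6.000   8.000   0.000  1.00  0.00           C
TER
END
"""

#: same chain with an altLoc B duplicate for residue 2 (lower occupancy)
PDB_ALTLOC = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA AGLY A   2       3.000   4.000   0.000  0.60  0.00           C
ATOM      3  CA BGLY A   2       3.500   4.500   0.000  0.40  0.00           C
ATOM      4  CA  TRP A   3       6.000   8.000   0.000  1.00  0.00           C
END
"""
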