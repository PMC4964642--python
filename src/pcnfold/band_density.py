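"""d-diagonal occupancy of the PCN and the inter-residue link density R_0.

The adjacency matrix of a chain-ordered contact network decomposes into
d-diagonals: the entries with sequence separation ``|i - j| = d``,
``d = 1 .. N_C - 1``.  ``R_0`` is the fraction (over the number of
residues ``N_C``) of separations carrying no contact at all.  A low
``R_0`` means residues interact at many levels of sequence separation —
diffuse, cooperative contact structure; a high ``R_0`` means the
interactions are localised in a few bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import ContactNetwork


@dataclass(frozen=True)
class DiagonalProfile:
    """Link counts per sequence separation d = 1 .. N_C - 1."""

    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "counts",
                           np.asarray(self.counts, dtype=int))

    @property
    def n_links(self) -> int:
        return int(self.counts.sum())


def diagonal_profile(net: ContactNetwork) -> DiagonalProfile:
    """Number of links at each separation d (counts[0] is d = 1)."""
    adj = net.adjacency
    n = net.n_residues
    counts = np.array([int(np.diagonal(adj, offset=d).sum())
                       for d in range(1, n)])
    return DiagonalProfile(counts)


def link_density_R0(net: ContactNetwork) -> float:
    """Fraction of empty d-diagonals over the residue count N_C.

    The denominator is N_C (not the N_C - 1 possible separations), so the
    maximum attainable value is (N_C - 1) / N_C < 1.
    """
    profile = diagonal_profile(net)
    return float((profile.counts == 0).sum()) / net.n_residues
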