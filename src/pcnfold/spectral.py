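"""Backbone reduction and Laplacian eigenvalue features of the PCN.

The combinatorial Laplacian ``L = D - A`` of the contact network is a
positive semi-definite operator whose eigenvalues play the role of
squared vibrational frequencies of the network (membrane analogy); the
largest eigenvalues correspond to the fastest, most localised modes.

To emphasise long-range contacts, the backbone is partially removed in a
protein-specific way: ``b`` is the smallest number of leading
``d``-diagonals (links between residues at chain separation ``|i-j| = d``)
whose removal disconnects the PCN, and the reduced network keeps the PCN
minus the first ``b - 1`` diagonals — the largest backbone-stripped
network that is still a single connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import PcnfoldError, TooShortError, ValidationError
from .structure_io import ContactNetwork


@dataclass(frozen=True)
class SpectralSummary:
    """Backbone-reduction order, reduced network and rescaled eigenvalues."""

    b: int
    reduced: ContactNetwork
    eigenvalues: np.ndarray
    lambda_features: tuple  # (lambda_N, lambda_N1, lambda_N2), each eig / N_C


def _n_components(adjacency: np.ndarray) -> int:
    return connected_components(csr_matrix(adjacency), directed=False)[0]


def _strip_diagonals(adjacency: np.ndarray, max_sep: int) -> np.ndarray:
    """Zero all links with chain separation |i - j| <= max_sep."""
    n = adjacency.shape[0]
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    out = adjacency.copy()
    out[sep <= max_sep] = 0
    return out


def backbone_break_order(pcn: ContactNetwork) -> int:
    """Smallest b such that removing diagonals d = 1..b disconnects the PCN."""
    adj = pcn.adjacency
    if _n_components(adj) != 1:
        raise ValidationError("PCN must be connected to define the break order")
    for b in range(1, pcn.n_residues):
        if _n_components(_strip_diagonals(adj, b)) > 1:
            return b
    raise PcnfoldError("network never disconnected; malformed adjacency")


def remove_backbone_diagonals(pcn: ContactNetwork, b: int) -> ContactNetwork:
    """Drop the first b - 1 diagonals; by construction the result is connected."""
    if b < 1:
        raise ValidationError("b must be >= 1")
    if b == 1:
        return pcn
    reduced = ContactNetwork(_strip_diagonals(pcn.adjacency, b - 1))
    if _n_components(reduced.adjacency) != 1:
        raise PcnfoldError(
            f"removing {b - 1} diagonals disconnected the network, "
            "contradicting the definition of b"
        )
    return reduced


def laplacian_spectrum(net: ContactNetwork) -> np.ndarray:
    """Ascending eigenvalues of L = D - A (dense symmetric solver)."""
    adj = net.adjacency.astype(float)
    lap = np.diag(adj.sum(axis=1)) - adj
    return eigh(lap, eigvals_only=True)


def lambda_features(spectrum: np.ndarray, n_residues: int) -> tuple:
    """Three largest Laplacian eigenvalues rescaled by chain length N_C."""
    spectrum = np.asarray(spectrum, dtype=float)
    if len(spectrum) != n_residues:
        raise ValidationError("spectrum length must equal n_residues")
    if n_residues < 3:
        raise TooShortError("lambda features need at least 3 residues")
    top = np.sort(spectrum)[-3:][::-1]
    return tuple(top / n_residues)


def spectral_summary(pcn: ContactNetwork) -> SpectralSummary:
    """Full pipeline: b, reduced network, spectrum, rescaled top eigenvalues."""
    b = backbone_break_order(pcn)
    reduced = remove_backbone_diagonals(pcn, b)
    spectrum = laplacian_spectrum(reduced)
    return SpectralSummary(
        b=b,
        reduced=reduced,
        eigenvalues=spectrum,
        lambda_features=lambda_features(spectrum, pcn.n_residues),
    )
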