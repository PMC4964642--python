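"""End-to-end feature extraction: one structure -> one observable row."""

from __future__ import annotations

import math
from typing import Optional

from . import band_density, classical, network_entropy, spectral, structure_io
from .structure_io import (
    CaTrace,
    ContactNetwork,
    DEFAULT_CONTACT_THRESHOLD,
    PotentialMatrix,
    WeightedContactNetwork,
)

#: column order of the feature table written by the CLI
FEATURE_COLUMNS = (
    "id", "chain", "N_C", "b",
    "lambda_N", "lambda_N1", "lambda_N2",
    "R0", "S_s", "S_ks", "S_R",
    "h_mean", "CO", "LRCO",
)


def protein_features(trace: CaTrace,
                     potentials: Optional[PotentialMatrix] = None,
                     hydropathy: Optional[classical.HydropathyScale] = None,
                     threshold: float = DEFAULT_CONTACT_THRESHOLD,
                     min_sep: int = classical.DEFAULT_MIN_SEP,
                     tolerance: float = 1e-8,
                     max_iter: int = 1000) -> dict:
    """Compute every observable for one C-alpha trace.

    Returns a dict keyed by :data:`FEATURE_COLUMNS`.
    """
    potentials = potentials or structure_io.load_contact_potentials()
    hydropathy = hydropathy or classical.load_kyte_doolittle()
    dist = structure_io.distance_matrix(trace)
    pcn = structure_io.build_pcn(dist, threshold=threshold)
    wnet = structure_io.apply_contact_potentials(pcn, trace, potentials)
    row = network_features(pcn, wnet=wnet, min_sep=min_sep,
                           tolerance=tolerance, max_iter=max_iter)
    row["id"] = trace.source_id
    row["chain"] = trace.chain_id
    row["h_mean"] = classical.mean_hydropathy(trace.residues, hydropathy)
    return {c: row[c] for c in FEATURE_COLUMNS}


def network_features(pcn: ContactNetwork,
                     wnet: Optional[WeightedContactNetwork] = None,
                     min_sep: int = classical.DEFAULT_MIN_SEP,
                     tolerance: float = 1e-8,
                     max_iter: int = 1000) -> dict:
    """Observables computable from a contact network alone.

    Without a weighted network, entropies use unit link weights; the
    sequence-dependent ``h_mean`` is NaN.
    """
    if wnet is None:
        wnet = WeightedContactNetwork(pcn.adjacency.astype(float))
    summary = spectral.spectral_summary(pcn)
    S_s, S_ks, S_R = network_entropy.entropy_features(
        wnet, tolerance=tolerance, max_iter=max_iter)
    lam_N, lam_N1, lam_N2 = summary.lambda_features
    return {
        "id": "", "chain": "",
        "N_C": pcn.n_residues,
        "b": summary.b,
        "lambda_N": lam_N, "lambda_N1": lam_N1, "lambda_N2": lam_N2,
        "R0": band_density.link_density_R0(pcn),
        "S_s": S_s, "S_ks": S_ks, "S_R": S_R,
        "h_mean": math.nan,
        "CO": classical.contact_order(pcn),
        "LRCO": classical.long_range_contact_order(pcn, min_sep=min_sep),
    }
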