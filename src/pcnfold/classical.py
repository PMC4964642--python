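"""Classical comparator observables: mean hydropathy, CO and LRCO.

These are the standard sequence/topology predictors the network
observables are benchmarked against: the Kyte-Doolittle mean hydropathy
``<h>``, the relative contact order

    CO = 1 / (L_C * N_C) * sum over contacts (i < j) of |i - j|,

with ``L_C`` the number of contacts, and the long-range order

    LRCO = |{contacts with |i - j| > min_sep}| / N_C,   min_sep = 12.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MappingError, PcnfoldError, ValidationError
from .structure_io import STANDARD_AA, ContactNetwork

DEFAULT_MIN_SEP = 12


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue hydropathy indices keyed by one-letter code."""

    values: Mapping[str, float]
    name: str = ""

    def __post_init__(self):
        vals = {str(k): float(v) for k, v in dict(self.values).items()}
        missing = set(STANDARD_AA) - set(vals)
        if missing:
            raise ValidationError(f"hydropathy scale missing: {sorted(missing)}")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise MappingError(f"residue {residue!r} not in hydropathy scale")


def load_kyte_doolittle(path=None) -> HydropathyScale:
    """Load a hydropathy TSV (residue, index); default is the shipped KD scale."""
    if path is None:
        ref = resources.files("pcnfold.data").joinpath("kd_hydropathy.tsv")
        with ref.open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
        name = "kyte-doolittle"
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        name = str(path)
    return HydropathyScale(dict(zip(df["residue"], df["index"])), name=name)


def mean_hydropathy(residues: Sequence[str], scale: HydropathyScale) -> float:
    """Arithmetic mean of the per-residue hydropathy indices."""
    if not residues:
        raise ValidationError("empty residue sequence")
    return float(np.mean([scale[r] for r in residues]))


def _separations(net: ContactNetwork) -> np.ndarray:
    ii, jj = np.nonzero(np.triu(net.adjacency, k=1))
    return jj - ii


def contact_order(pcn: ContactNetwork) -> float:
    """Relative contact order: mean contact separation over chain length."""
    sep = _separations(pcn)
    if sep.size == 0:
        raise PcnfoldError("contact order is undefined for a network without links")
    return float(sep.sum()) / (sep.size * pcn.n_residues)


def long_range_contact_order(pcn: ContactNetwork,
                             min_sep: int = DEFAULT_MIN_SEP) -> float:
    """Long-range contacts (separation > min_sep) per residue."""
    sep = _separations(pcn)
    return float((sep > min_sep).sum()) / pcn.n_residues
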