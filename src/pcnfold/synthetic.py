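"""Deterministic synthetic fixtures: banded networks, toy C-alpha traces
and labelled two-class feature clouds.

These generators let every stage of the pipeline run without any
structure download: banded networks exercise the diagonal/break-order
machinery exactly, helix and random-globule traces exercise the full
structure -> feature path with protein-like geometry (3.8 A consecutive
C-alpha spacing, compact packing), and Gaussian feature clouds with a
known Bayes error exercise the grouped-CV classifier.  All generators
are pure functions of their arguments, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classification import LabeledDataset
from .errors import PcnfoldError, ValidationError
from .structure_io import STANDARD_AA, CaTrace, ContactNetwork


@dataclass(frozen=True)
class GeneratorSpec:
    """A reproducible recipe: generator kind, parameters, seed."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to its generator."""
    table = {
        "banded_network": lambda p: make_banded_network(**p),
        "helix_trace": lambda p: make_helix_trace(**p, sequence_seed=spec.seed),
        "random_globule": lambda p: make_random_globule(**p, seed=spec.seed),
        "two_class_features": lambda p: make_two_class_features(**p,
                                                               seed=spec.seed),
    }
    if spec.kind not in table:
        raise ValidationError(f"unknown generator kind {spec.kind!r}")
    return table[spec.kind](dict(spec.parameters))


def make_banded_network(n: int, occupied) -> ContactNetwork:
    """Network whose links are exactly the pairs with |i - j| in ``occupied``."""
    occupied = set(int(d) for d in occupied)
    bad = [d for d in occupied if not 1 <= d <= n - 1]
    if bad:
        raise ValidationError(f"separations {sorted(bad)} outside 1..{n - 1}")
    idx = np.arange(n)
    sep = np.abs(np.subtract.outer(idx, idx))
    adj = np.isin(sep, list(occupied)).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return ContactNetwork(adj)


def _random_sequence(n: int, rng) -> tuple:
    return tuple(rng.choice(list(STANDARD_AA), size=n))


def make_helix_trace(n: int, rise: float = 1.5, radius: float = 2.3,
                     turn: float = math.radians(100.0),
                     sequence_seed: int = 0) -> CaTrace:
    """Idealised alpha-helix C-alpha trace.

    With the canonical parameters (rise 1.5 A, radius 2.3 A, turn 100
    degrees) the 8 A contact pattern is a fixed band set {1, 2, 3, 4}
    independent of n.
    """
    if n < 4:
        raise ValidationError("helix trace needs n >= 4")
    i = np.arange(n)
    coords = np.column_stack([radius * np.cos(i * turn),
                              radius * np.sin(i * turn),
                              rise * i])
    rng = np.random.default_rng(sequence_seed)
    return CaTrace(residues=_random_sequence(n, rng), coords=coords,
                   chain_id="A", source_id=f"helix{n}")


def make_random_globule(n: int, seed: int = 0, c: float = 3.0,
                        bond_length: float = 3.8,
                        min_clash: float = 3.5,
                        max_restarts: int = 200) -> CaTrace:
    """Self-avoiding random chain confined to a sphere of radius c * n^(1/3).

    Consecutive C-alphas sit exactly ``bond_length`` apart (so every
    |i - j| = 1 pair is an 8 A contact and the PCN is connected);
    non-consecutive residues keep at least ``min_clash`` A apart.  The
    default confinement constant reproduces protein-like packing density
    (~0.009 residues per cubic Angstrom).
    """
    if n < 10:
        raise ValidationError("globule needs n >= 10")
    rng = np.random.default_rng(seed)
    radius = c * n ** (1.0 / 3.0)
    for _ in range(max_restarts):
        coords = _grow_chain(n, rng, radius, bond_length, min_clash)
        if coords is not None:
            return CaTrace(residues=_random_sequence(n, rng), coords=coords,
                           chain_id="A", source_id=f"globule{n}s{seed}")
    raise PcnfoldError(
        f"could not place a self-avoiding chain of {n} residues in a "
        f"sphere of radius {radius:.1f} A after {max_restarts} restarts"
    )


def _grow_chain(n, rng, radius, bond, clash, tries_per_step=60):
    coords = np.empty((n, 3))
    coords[0] = rng.normal(scale=radius / 4.0, size=3)
    for i in range(1, n):
        for _ in range(tries_per_step):
            step = rng.normal(size=3)
            step *= bond / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if np.linalg.norm(cand) > radius:
                continue
            if i > 1 and (np.linalg.norm(coords[:i - 1] - cand, axis=1)
                          < clash).any():
                continue
            coords[i] = cand
            break
        else:
            return None
    return coords


def make_two_class_features(n_per_class: int = 50,
                            means=((0.0, 0.0), (4.0, 4.0)),
                            covariances=None,
                            group_size: int = 2,
                            seed: int = 0,
                            labels=("MS", "TS")) -> LabeledDataset:
    """Two Gaussian clouds with homology groups of fixed size.

    The Bayes-optimal error follows from the class means/covariances,
    so classifier recovery can be asserted against a known target.
    """
    import pandas as pd

    means = [np.asarray(m, dtype=float) for m in means]
    dim = means[0].size
    if covariances is None:
        covariances = [np.eye(dim), np.eye(dim)]
    covariances = [np.atleast_2d(np.asarray(cv, dtype=float))
                   for cv in covariances]
    rng = np.random.default_rng(seed)
    rows, ids, labs, groups = [], [], [], []
    gidx = 0
    for cls, mu, cov in zip(labels, means, covariances):
        pts = rng.multivariate_normal(mu, cov, size=n_per_class)
        for j in range(n_per_class):
            if j % group_size == 0:
                gidx += 1
            rows.append(pts[j])
            ids.append(f"{cls.lower()}{j:04d}")
            labs.append(cls)
            groups.append(f"g{gidx:04d}")
    feats = pd.DataFrame(np.array(rows),
                         columns=[f"f{d + 1}" for d in range(dim)])
    return LabeledDataset(ids=ids, features=feats, labels=labs, groups=groups)
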