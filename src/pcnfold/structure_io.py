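"""Parse PDB structures into C-alpha traces and build protein contact networks.

A protein is modelled by its C-alpha trace: the ordered residue sequence
together with one 3D coordinate per residue.  The protein contact network
(PCN) links every residue pair whose C-alpha distance does not exceed a
threshold (8 A by default, inclusive).  The weighted PCN carries a
statistical contact potential on every link, shifted per protein so that
the smallest link weight equals one (network-entropy calculations require
strictly positive weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .errors import (
    ChainNotFoundError,
    MappingError,
    ParseError,
    TooShortError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes, alphabetical by code.
STANDARD_AA = tuple("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # tolerated substitutions: selenomethionine and selenocysteine
    "MSE": "M", "SEC": "C",
}

DEFAULT_CONTACT_THRESHOLD = 8.0


@dataclass(frozen=True)
class CaTrace:
    """Ordered C-alpha trace of one chain.

    Attributes
    ----------
    residues : tuple of str
        One-letter amino-acid codes, in chain order.
    coords : ndarray, shape (N_C, 3)
        C-alpha coordinates in Angstrom.
    chain_id, source_id : str
        Chain label and structure identifier (file stem or PDB id).
    """

    residues: tuple
    coords: np.ndarray
    chain_id: str = ""
    source_id: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residues", tuple(self.residues))
        if len(self.residues) != len(coords):
            raise ValidationError(
                f"{len(self.residues)} residues but {len(coords)} coordinates"
            )
        if len(self.residues) < 2:
            raise TooShortError("a C-alpha trace needs at least 2 residues")
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError("coords must have shape (N_C, 3)")
        if not np.isfinite(coords).all():
            raise ValidationError("non-finite coordinate in trace")
        bad = set(self.residues) - set(STANDARD_AA)
        if bad:
            raise MappingError(f"non-standard residue codes: {sorted(bad)}")

    def __len__(self):
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ContactNetwork:
    """Binary symmetric residue contact network (the PCN)."""

    adjacency: np.ndarray

    def __post_init__(self):
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.isin(adj, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0/1")
        adj = adj.astype(np.uint8)
        if (adj != adj.T).any():
            raise ValidationError("adjacency must be symmetric")
        if np.diagonal(adj).any():
            raise ValidationError("adjacency must have a zero diagonal")
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_residues(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass(frozen=True)
class PotentialMatrix:
    """20x20 symmetric contact-potential table keyed by one-letter codes."""

    values: pd.DataFrame
    name: str = ""

    def __post_init__(self):
        df = pd.DataFrame(self.values).astype(float)
        missing = set(STANDARD_AA) - set(df.index) | set(STANDARD_AA) - set(df.columns)
        if missing:
            raise ValidationError(f"potential matrix missing residues: {sorted(missing)}")
        df = df.loc[list(STANDARD_AA), list(STANDARD_AA)]
        if not np.allclose(df.values, df.values.T, atol=1e-12):
            raise ValidationError("potential matrix must be symmetric under pair exchange")
        object.__setattr__(self, "values", df)

    def lookup(self, res_a: str, res_b: str) -> float:
        try:
            return float(self.values.at[res_a, res_b])
        except KeyError as exc:
            raise MappingError(f"residue {exc.args[0]!r} not in potential matrix") from exc


@dataclass(frozen=True)
class WeightedContactNetwork:
    """PCN with shifted contact-potential weights on its links.

    Weights live only on PCN links (Hadamard-product semantics) and are
    shifted per protein so the smallest link weight equals one.
    """

    weights: np.ndarray
    shift: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValidationError("weights must be symmetric")
        if np.diagonal(w).any():
            raise ValidationError("weights must have a zero diagonal")
        if (w < 0).any():
            raise ValidationError("weights must be nonnegative")
        w = 0.5 * (w + w.T)  # exact symmetry
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_residues(self) -> int:
        return self.weights.shape[0]

    def support(self) -> ContactNetwork:
        return ContactNetwork((self.weights > 0).astype(np.uint8))


# ---------------------------------------------------------------------------
# PDB parsing


def _collapse_altlocs(atoms):
    """Pick one CA among altLoc duplicates: highest occupancy, ties by letter."""
    return max(atoms, key=lambda a: (a.occ, _neg_ord(a.altloc)))


def _neg_ord(altloc: str):
    # empty altloc ranks first; otherwise earlier letters win ties
    return -ord(altloc) if altloc else 1


def read_ca_trace(pdb_text: str, chain_selector: str = "first",
                  source_id: str = "") -> CaTrace:
    """Extract the C-alpha trace of one chain from PDB-format text.

    Parameters
    ----------
    pdb_text : str
        Content of a PDB file (ATOM records; HETATM honoured for MSE).
    chain_selector : str
        A chain id, or ``"first"`` for the first polymer chain that
        contains C-alpha atoms.  Only the first model of multi-model
        files is read.

    Raises
    ------
    ParseError, ChainNotFoundError, TooShortError, MappingError
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise ParseError("no model in structure")
    model = st[0]

    chain_ids = [ch.name for ch in model]
    candidates = chain_ids if chain_selector == "first" else [chain_selector]
    if chain_selector != "first" and chain_selector not in chain_ids:
        raise ChainNotFoundError(
            f"chain {chain_selector!r} not found; available: {chain_ids}"
        )

    for cid in candidates:
        trace = _chain_to_trace(model[cid], cid, source_id or st.name)
        if trace is not None:
            return trace
    raise ParseError("no C-alpha records in the selected chain(s)")


def _chain_to_trace(chain, chain_id, source_id):
    entries = []  # (seqnum, icode, one_letter, xyz)
    for residue in chain:
        name = residue.name.upper()
        if residue.het_flag == "H" and name not in ("MSE", "SEC"):
            continue  # ligands/waters are not part of the trace
        cas = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
        if not cas:
            continue
        if name not in _THREE_TO_ONE:
            raise MappingError(
                f"residue {residue.name!r} {residue.seqid.num} in chain "
                f"{chain_id!r} has no one-letter mapping"
            )
        atom = _collapse_altlocs(cas)
        entries.append((
            residue.seqid.num,
            residue.seqid.icode or " ",
            _THREE_TO_ONE[name],
            (atom.pos.x, atom.pos.y, atom.pos.z),
        ))
    if not entries:
        return None
    entries.sort(key=lambda e: (e[0], e[1]))
    seqnums = [e[0] for e in entries]
    gaps = sum(1 for a, b in zip(seqnums, seqnums[1:]) if b > a + 1)
    if gaps:
        logger.warning(
            "chain %s of %s: %d sequence-number gap(s); residues renumbered "
            "consecutively in order of appearance", chain_id, source_id, gaps
        )
    residues = [e[2] for e in entries]
    coords = np.array([e[3] for e in entries], dtype=float)
    if len(residues) < 2:
        raise TooShortError(
            f"chain {chain_id!r} has only {len(residues)} C-alpha record(s)"
        )
    return CaTrace(residues=tuple(residues), coords=coords,
                   chain_id=chain_id, source_id=source_id)


# ---------------------------------------------------------------------------
# Network construction


def distance_matrix(trace: CaTrace) -> np.ndarray:
    """All-pairs Euclidean C-alpha distance matrix in Angstrom."""
    return squareform(pdist(trace.coords))


def build_pcn(distances: np.ndarray,
              threshold: float = DEFAULT_CONTACT_THRESHOLD) -> ContactNetwork:
    """Threshold a distance matrix into the binary PCN.

    A pair (i, j), i != j, is a contact iff 0 < d_ij <= threshold
    (inclusive threshold).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    adj = ((d > 0) & (d <= threshold)).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return ContactNetwork(adj)


def apply_contact_potentials(pcn: ContactNetwork, trace: CaTrace,
                             potentials: PotentialMatrix) -> WeightedContactNetwork:
    """Weight PCN links by the contact potential of their residue pair.

    Raw potentials can be negative; each protein's link weights are
    shifted by a constant so the minimum link weight equals exactly one.
    Non-links keep weight zero (Hadamard product of PCN and potential
    matrix).
    """
    if pcn.n_residues != trace.n_residues:
        raise ValidationError(
            f"network has {pcn.n_residues} nodes but trace has "
            f"{trace.n_residues} residues"
        )
    idx = []
    for r in trace.residues:
        if r not in potentials.values.index:
            raise MappingError(f"residue {r!r} not in potential matrix")
        idx.append(r)
    per_residue = potentials.values.loc[idx, idx].to_numpy()
    adj = pcn.adjacency.astype(bool)
    if not adj.any():
        return WeightedContactNetwork(np.zeros_like(per_residue), shift=0.0)
    shift = 1.0 - per_residue[adj].min()
    weights = np.where(adj, per_residue + shift, 0.0)
    return WeightedContactNetwork(weights, shift=float(shift))


# ---------------------------------------------------------------------------
# Table I/O (plain-text formats)


def load_contact_potentials(path=None, name: str = "") -> PotentialMatrix:
    """Load a 20x20 potential TSV; default is the shipped contact-energy table."""
    if path is None:
        ref = resources.files("pcnfold.data").joinpath("mj_contact_potentials.tsv")
        with ref.open() as fh:
            df = pd.read_csv(fh, sep="\t", index_col=0, comment="#")
        return PotentialMatrix(df, name=name or "miyazawa-jernigan-1996")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return PotentialMatrix(df, name=name or str(path))


def write_potentials(potentials: PotentialMatrix, path) -> None:
    potentials.values.to_csv(path, sep="\t")


def write_network_matrix(net, path) -> None:
    """Write adjacency (0/1) or weights as a whitespace-separated dense matrix."""
    mat = net.adjacency if isinstance(net, ContactNetwork) else net.weights
    fmt = "%d" if isinstance(net, ContactNetwork) else "%.17g"
    np.savetxt(path, mat, fmt=fmt)


def read_network_matrix(path, weighted: bool = False):
    mat = np.loadtxt(path)
    if weighted:
        return WeightedContactNetwork(mat)
    return ContactNetwork(mat.astype(np.uint8))


def write_edge_list(net, path) -> None:
    """Write links as ``i j weight`` with 1-based residue indices, i < j."""
    if isinstance(net, ContactNetwork):
        mat = net.adjacency.astype(float)
    else:
        mat = net.weights
    ii, jj = np.nonzero(np.triu(mat, k=1))
    with open(path, "w") as fh:
        fh.write(f"# n_residues {mat.shape[0]}\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i + 1} {j + 1} {mat[i, j]:.17g}\n")


def read_edge_list(path, weighted: bool = False):
    n = None
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "n_residues" in line:
                    n = int(line.split()[-1])
                continue
            if not line:
                continue
            i, j, w = line.split()
            edges.append((int(i) - 1, int(j) - 1, float(w)))
    if n is None:
        n = 1 + max(max(i, j) for i, j, _ in edges)
    mat = np.zeros((n, n))
    for i, j, w in edges:
        mat[i, j] = mat[j, i] = w
    if weighted:
        return WeightedContactNetwork(mat)
    return ContactNetwork((mat > 0).astype(np.uint8))


def trace_to_pdb(trace: CaTrace) -> str:
    """Render a C-alpha-only PDB text for a trace (used by the simulator)."""
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items() if k not in ("MSE", "SEC")}
    lines = []
    cid = trace.chain_id or "A"
    for i, (res, (x, y, z)) in enumerate(zip(trace.residues, trace.coords), start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  {one_to_three[res]} {cid}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
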