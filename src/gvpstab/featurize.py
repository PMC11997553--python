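"""Geometric protein graphs and the amino-acid encoder stack.

A backbone structure (N, CA, C, O coordinates per residue) becomes a
directed k-nearest-neighbor residue graph with four feature blocks:

* node scalars ``Sv`` — concatenation of up to six per-residue encoder
  families: one-hot identity (20), Atchley physicochemical factors (5),
  PSSM evolutionary profile (20), a structure-derived contact potential
  (1), per-residue energy-term scores (20), and backbone-dihedral
  sin/cos pairs (6);
* node vectors ``Vv`` — three unit vectors per residue: direction to the
  previous CA, direction to the next CA, and an imputed side-chain
  direction from local backbone geometry;
* edge scalars ``Se`` — Gaussian radial-basis expansion of the CA–CA
  distance;
* edge vectors ``Ve`` — the unit displacement between the linked CAs.

Scalar features are invariant under rigid motion of the input coordinates;
vector features transform exactly with the applied orthogonal matrix.  All
vector features are built from coordinate *differences* (never cross
products), so equivariance holds for improper rotations (reflections) too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._tables import ATCHLEY_FACTORS, RESIDUE_SCORE_COLUMNS
from .data_model import CANONICAL_AA, ValidationError

#: Squashing transform applied to raw PSSM log-odds (recorded for manifests).
PSSM_SQUASH = "sigmoid(x/2)"

#: Saturation constant for the contact-count structure potential.
MAX_CONTACTS = 24

#: CA–CA distance window for bonded neighbors; outside it is a chain break.
CA_CA_WINDOW = (2.5, 4.5)

_AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}


# ---------------------------------------------------------------------------
# Backbone structures

@dataclass
class BackboneStructure:
    """Per-residue backbone heavy-atom coordinates (Å) for one chain."""

    sequence: str
    n: np.ndarray    # (L, 3)
    ca: np.ndarray   # (L, 3)
    c: np.ndarray    # (L, 3)
    o: np.ndarray | None = None   # (L, 3); unused by graphs/dihedrals
    chain_id: str = "A"

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name in ("n", "ca", "c"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (L, 3):
                raise ValidationError(
                    f"{name} coordinates must have shape ({L}, 3), "
                    f"got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite {name} coordinates")
            setattr(self, name, arr)
        if self.o is not None:
            self.o = np.asarray(self.o, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.sequence)

    def chain_break_after(self) -> np.ndarray:
        """Boolean (L-1,): True where the i→i+1 CA–CA step is not bonded."""
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        lo, hi = CA_CA_WINDOW
        return (d < lo) | (d > hi)

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "BackboneStructure":
        """Apply x → x @ Rᵀ + t to every atom (R orthogonal)."""
        R = np.asarray(rotation, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64)
        return BackboneStructure(
            sequence=self.sequence,
            n=self.n @ R.T + t,
            ca=self.ca @ R.T + t,
            c=self.c @ R.T + t,
            o=None if self.o is None else self.o @ R.T + t,
            chain_id=self.chain_id,
        )


def read_pdb(path: str | Path, chain_id: str | None = None) -> BackboneStructure:
    """Read a single-chain backbone from a PDB file (ATOM records, altloc A)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValidationError(f"{path}: no amino-acid ATOM records")
    if chain_id is None:
        chain_id = str(atoms.chain_id[0])
    atoms = atoms[atoms.chain_id == chain_id]

    seq: list[str] = []
    coords = {"N": [], "CA": [], "C": [], "O": []}
    for res in struc.residue_iter(atoms):
        names = list(res.atom_name)
        if not all(a in names for a in ("N", "CA", "C")):
            continue   # incomplete backbone: residue bridged as a break
        res3 = str(res.res_name[0])
        if res3 not in _AA3_TO_1:
            continue
        seq.append(_AA3_TO_1[res3])
        for a in ("N", "CA", "C"):
            coords[a].append(res.coord[names.index(a)])
        coords["O"].append(
            res.coord[names.index("O")] if "O" in names else [np.nan] * 3
        )
    if not seq:
        raise ValidationError(f"{path}: chain {chain_id} has no usable residues")
    o = np.asarray(coords["O"], dtype=np.float64)
    return BackboneStructure(
        sequence="".join(seq),
        n=np.asarray(coords["N"]),
        ca=np.asarray(coords["CA"]),
        c=np.asarray(coords["C"]),
        o=None if np.isnan(o).all() else o,
        chain_id=chain_id,
    )


def write_pdb(structure: BackboneStructure, path: str | Path) -> None:
    """Write the backbone as a standard PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    L = len(structure)
    has_o = structure.o is not None
    per_res = 4 if has_o else 3
    atoms = struc.AtomArray(L * per_res)
    names = ["N", "CA", "C"] + (["O"] if has_o else [])
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    i = 0
    for ri in range(L):
        for name in names:
            arr = getattr(structure, name.lower() if name != "CA" else "ca")
            atoms.coord[i] = arr[ri]
            atoms.chain_id[i] = structure.chain_id
            atoms.res_id[i] = ri + 1
            atoms.res_name[i] = _AA1_TO_3[structure.sequence[ri]]
            atoms.atom_name[i] = name
            atoms.element[i] = elements[name]
            atoms.hetero[i] = False
            i += 1
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Per-residue encoders

def one_hot_encode(residue: str) -> np.ndarray:
    """20-dim indicator by alphabetical one-letter ordering."""
    idx = CANONICAL_AA.find(residue)
    if idx < 0:
        raise ValidationError(f"non-canonical residue {residue!r}")
    vec = np.zeros(20)
    vec[idx] = 1.0
    return vec


def atchley_encode(residue: str) -> np.ndarray:
    """The five standardized Atchley physicochemical factors."""
    if residue not in ATCHLEY_FACTORS:
        raise ValidationError(f"non-canonical residue {residue!r}")
    return np.asarray(ATCHLEY_FACTORS[residue], dtype=np.float64)


def load_pssm(path_or_matrix, sequence: str) -> np.ndarray:
    """Load an (L, 20) PSSM and squash log-odds to (0, 1).

    Accepts an array or a headered TSV with the 20 amino-acid columns.
    Raw scores pass through the monotone transform sigmoid(x / 2)
    (:data:`PSSM_SQUASH`), bounding the encoding while preserving order.
    """
    if isinstance(path_or_matrix, (str, Path)):
        df = pd.read_csv(path_or_matrix, sep="\t")
        cols = [c for c in df.columns if c in set(CANONICAL_AA)]
        if len(cols) != 20:
            raise ValidationError(
                f"PSSM table needs the 20 amino-acid columns, found {len(cols)}"
            )
        mat = df[list(CANONICAL_AA)].to_numpy(dtype=np.float64)
    else:
        mat = np.asarray(path_or_matrix, dtype=np.float64)
    if mat.shape != (len(sequence), 20):
        raise ValidationError(
            f"PSSM shape {mat.shape} does not match sequence length "
            f"{len(sequence)} x 20"
        )
    return 1.0 / (1.0 + np.exp(-mat / 2.0))


def structure_potential_encode(
    structure: BackboneStructure, cutoff: float = 10.0
) -> np.ndarray:
    """Contact-derived structure potential: normalized CA neighbor counts.

    Counts CA atoms within ``cutoff`` Å (self excluded) and rescales by a
    fixed saturation constant to [0, 1].  This is a documented stand-in for
    a pairwise contact potential, kept behind this function so a richer
    implementation can be swapped in without touching the graph builder.
    """
    d = cdist(structure.ca, structure.ca)
    counts = np.sum((d > 0) & (d <= cutoff), axis=1)
    return np.clip(counts / MAX_CONTACTS, 0.0, 1.0)


def load_residue_scores(path_or_table, sequence: str) -> np.ndarray:
    """Load an (L, 20) per-residue energy-score table (schema-driven).

    Columns are matched by header name against the 20-term schema in
    :data:`gvpstab._tables.RESIDUE_SCORE_COLUMNS`; column order in the file
    is irrelevant.
    """
    if isinstance(path_or_table, (str, Path)):
        df = pd.read_csv(path_or_table, sep="\t")
    elif isinstance(path_or_table, pd.DataFrame):
        df = path_or_table
    else:
        arr = np.asarray(path_or_table, dtype=np.float64)
        if arr.shape != (len(sequence), 20):
            raise ValidationError(
                f"residue score shape {arr.shape} != ({len(sequence)}, 20)"
            )
        return arr
    missing = set(RESIDUE_SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"residue score table missing columns {sorted(missing)}"
        )
    mat = df[list(RESIDUE_SCORE_COLUMNS)].to_numpy(dtype=np.float64)
    if mat.shape[0] != len(sequence):
        raise ValidationError(
            f"residue score rows {mat.shape[0]} != sequence length "
            f"{len(sequence)}"
        )
    return mat


# ---------------------------------------------------------------------------
# Backbone dihedrals

def _torsion(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle (radians) for stacked four-atom quadruples."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.arctan2(y, x)


@dataclass
class DihedralFeatures:
    """Backbone φ/ψ/ω per residue with validity masking.

    ``angles`` is (L, 3) in radians with NaN where undefined; ``sincos`` is
    the (L, 6) [|sinφ|, cosφ, |sinψ|, cosψ, |sinω|, cosω] encoding with
    (0, 0) at undefined angles; ``mask`` is the (L, 3) validity flag.  The
    sine enters by magnitude because a torsion's *sign* flips under a
    mirror image of the structure: keeping |sin| makes the scalar features
    invariant under reflections as well as rotations, which the classifier
    contract requires.  The signed angles remain available in ``angles``.
    """

    angles: np.ndarray
    sincos: np.ndarray
    mask: np.ndarray


def compute_dihedrals(structure: BackboneStructure) -> DihedralFeatures:
    """Standard backbone dihedrals.

    φ_i = C_{i-1}–N_i–CA_i–C_i (undefined for the first residue),
    ψ_i = N_i–CA_i–C_i–N_{i+1} and ω_i = CA_i–C_i–N_{i+1}–CA_{i+1}
    (undefined for the last residue).  Angles spanning a chain break are
    masked as undefined.
    """
    L = len(structure)
    angles = np.full((L, 3), np.nan)
    if L >= 2:
        broken = structure.chain_break_after()
        ok = ~broken
        n, ca, c = structure.n, structure.ca, structure.c
        phi = _torsion(c[:-1], n[1:], ca[1:], c[1:])
        psi = _torsion(n[:-1], ca[:-1], c[:-1], n[1:])
        omega = _torsion(ca[:-1], c[:-1], n[1:], ca[1:])
        angles[1:, 0] = np.where(ok, phi, np.nan)
        angles[:-1, 1] = np.where(ok, psi, np.nan)
        angles[:-1, 2] = np.where(ok, omega, np.nan)
    mask = ~np.isnan(angles)
    sincos = np.zeros((L, 6))
    with np.errstate(invalid="ignore"):
        sincos[:, 0::2] = np.where(mask, np.abs(np.sin(angles)), 0.0)
        sincos[:, 1::2] = np.where(mask, np.cos(angles), 0.0)
    return DihedralFeatures(angles=angles, sincos=sincos, mask=mask)


# ---------------------------------------------------------------------------
# Encoder stack

@dataclass(frozen=True)
class EncoderStack:
    """Which per-residue encoder families contribute to Sv, in fixed order."""

    one_hot: bool = True
    atchley: bool = True
    pssm: bool = True
    structure_potential: bool = True
    residue_scores: bool = True
    dihedrals: bool = True

    _WIDTHS = (
        ("one_hot", 20), ("atchley", 5), ("pssm", 20),
        ("structure_potential", 1), ("residue_scores", 20), ("dihedrals", 6),
    )

    @property
    def widths(self) -> dict[str, int]:
        return {name: w for name, w in self._WIDTHS if getattr(self, name)}

    @property
    def total_width(self) -> int:
        return sum(self.widths.values())

    @property
    def signature(self) -> str:
        return "+".join(self.widths)

    def scalar_features(
        self,
        structure: BackboneStructure,
        pssm: np.ndarray | None = None,
        residue_scores: np.ndarray | None = None,
    ) -> np.ndarray:
        """Concatenate the enabled families into the (L, total_width) Sv."""
        blocks: list[np.ndarray] = []
        if self.one_hot:
            blocks.append(np.stack(
                [one_hot_encode(r) for r in structure.sequence]))
        if self.atchley:
            blocks.append(np.stack(
                [atchley_encode(r) for r in structure.sequence]))
        if self.pssm:
            if pssm is None:
                raise ValidationError(
                    "encoder stack enables pssm but none was provided"
                )
            blocks.append(load_pssm(pssm, structure.sequence))
        if self.structure_potential:
            blocks.append(structure_potential_encode(structure)[:, None])
        if self.residue_scores:
            if residue_scores is None:
                raise ValidationError(
                    "encoder stack enables residue_scores but none was provided"
                )
            blocks.append(load_residue_scores(
                residue_scores, structure.sequence))
        if self.dihedrals:
            blocks.append(compute_dihedrals(structure).sincos)
        if not blocks:
            raise ValidationError("encoder stack is empty")
        return np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# Graph construction

@dataclass(frozen=True)
class RBFConfig:
    """Gaussian radial basis over [d_min, d_max]; width = center spacing."""

    n_centers: int = 16
    d_min: float = 0.0
    d_max: float = 20.0

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.d_min, self.d_max, self.n_centers)

    @property
    def width(self) -> float:
        return float(self.centers[1] - self.centers[0])

    def expand(self, distances: np.ndarray) -> np.ndarray:
        z = (np.asarray(distances)[..., None] - self.centers) / self.width
        return np.exp(-z * z)


@dataclass
class ProteinGraph:
    """Directed k-NN residue graph with scalar/vector node and edge features."""

    node_scalar: np.ndarray   # (L, S)
    node_vector: np.ndarray   # (L, 3, 3)
    edge_index: np.ndarray    # (2, E) rows: source, destination
    edge_scalar: np.ndarray   # (E, n_rbf)
    edge_vector: np.ndarray   # (E, 1, 3)
    stack_signature: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_scalar.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize as an npz archive with a JSON metadata entry."""
        meta = dict(self.meta, stack_signature=self.stack_signature)
        np.savez(
            path,
            node_scalar=self.node_scalar,
            node_vector=self.node_vector,
            edge_index=self.edge_index,
            edge_scalar=self.edge_scalar,
            edge_vector=self.edge_vector,
            meta_json=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ProteinGraph":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"]))
            return cls(
                node_scalar=z["node_scalar"],
                node_vector=z["node_vector"],
                edge_index=z["edge_index"],
                edge_scalar=z["edge_scalar"],
                edge_vector=z["edge_vector"],
                stack_signature=meta.pop("stack_signature", ""),
                meta=meta,
            )


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.where(norm > 1e-12, v / np.maximum(norm, 1e-12), 0.0)


def _orientation_vectors(structure: BackboneStructure) -> np.ndarray:
    """(L, 3, 3) node vectors: to previous CA, to next CA, side-chain imputation.

    The side-chain direction is imputed in the N–CA–C plane as the unit
    bisector of CA←N and CA←C (a proper vector: it transforms with any
    orthogonal matrix, including reflections).  Undefined directions at
    chain termini/breaks are the zero vector.
    """
    L = len(structure)
    ca = structure.ca
    broken = structure.chain_break_after() if L >= 2 else np.zeros(0, bool)

    forward = np.zeros((L, 3))
    backward = np.zeros((L, 3))
    if L >= 2:
        step = _unit(ca[1:] - ca[:-1])
        ok = ~broken
        forward[:-1] = np.where(ok[:, None], step, 0.0)
        backward[1:] = np.where(ok[:, None], -step, 0.0)

    u1 = _unit(ca - structure.n)
    u2 = _unit(ca - structure.c)
    side = _unit(u1 + u2)
    return np.stack([backward, forward, side], axis=1)


def knn_edges(ca: np.ndarray, k: int) -> np.ndarray:
    """Directed edges (2, E): each node receives its k nearest CA neighbors.

    k is truncated to n-1 for short chains; exact distance ties are broken
    by residue index (lower first).
    """
    n = len(ca)
    if n < 2:
        raise ValidationError("graph needs at least 2 residues")
    k = min(k, n - 1)
    d = cdist(ca, ca)
    np.fill_diagonal(d, np.inf)
    src, dst = [], []
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, d[i]))[:k]
        src.extend(order)
        dst.extend([i] * k)
    return np.asarray([src, dst], dtype=np.int64)


def build_graph(
    structure: BackboneStructure,
    encoder_stack: EncoderStack | None = None,
    k_neighbors: int = 30,
    rbf_config: RBFConfig | None = None,
    pssm: np.ndarray | None = None,
    residue_scores: np.ndarray | None = None,
) -> ProteinGraph:
    """Build the full geometric graph for one backbone structure."""
    if len(structure) < 2:
        raise ValidationError("build_graph needs at least 2 residues")
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be >= 1")
    encoder_stack = encoder_stack or EncoderStack()
    rbf_config = rbf_config or RBFConfig()

    sv = encoder_stack.scalar_features(
        structure, pssm=pssm, residue_scores=residue_scores
    )
    vv = _orientation_vectors(structure)
    edge_index = knn_edges(structure.ca, k_neighbors)
    disp = structure.ca[edge_index[0]] - structure.ca[edge_index[1]]
    dist = np.linalg.norm(disp, axis=1)
    se = rbf_config.expand(dist)
    ve = _unit(disp)[:, None, :]
    return ProteinGraph(
        node_scalar=sv,
        node_vector=vv,
        edge_index=edge_index,
        edge_scalar=se,
        edge_vector=ve,
        stack_signature=encoder_stack.signature,
        meta={
            "k_neighbors": int(k_neighbors),
            "rbf": {"n_centers": rbf_config.n_centers,
                    "d_min": rbf_config.d_min, "d_max": rbf_config.d_max},
            "n_residues": len(structure),
        },
    )
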