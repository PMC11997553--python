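"""Synthetic fixtures: idealized backbones, mutation datasets, side tables.

Everything the pipeline consumes can be generated here deterministically
from a seed, so every stage is exercisable without downloads: idealized
α-helical and extended backbones built residue-by-residue from standard
bond geometry, mutation datasets with a controlled stabilizing/
destabilizing ΔΔG mixture and shared wild types (so thermodynamic-looping
pairs exist), and random PSSM / per-residue score tables matching the
featurization schemas.  The fixtures emulate the *statistical shape* of
curated thermodynamic databases, not physically realistic energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tables import RESIDUE_SCORE_COLUMNS
from .data_model import (
    CANONICAL_AA,
    Dataset,
    MutationRecord,
    PointMutation,
    ValidationError,
    classify_label,
)
from .featurize import BackboneStructure

# Standard backbone bond lengths (Å) and angles (deg).
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}

#: Ideal α-helix backbone torsions (deg).
HELIX_PHI, HELIX_PSI, HELIX_OMEGA = -57.0, -47.0, 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D given A, B, C."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _gen_backbone(n_residues: int, phi: float, psi: float, omega: float,
                  sequence: str | None, seed: int,
                  jitter: float) -> BackboneStructure:
    if n_residues < 2:
        raise ValidationError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(CANONICAL_AA), size=n_residues))
    elif len(sequence) != n_residues:
        raise ValidationError("sequence length does not match n_residues")

    N = np.zeros((n_residues, 3))
    CA = np.zeros((n_residues, 3))
    C = np.zeros((n_residues, 3))
    # seed the first residue with ideal internal geometry
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_BOND["N-CA"], 0.0, 0.0]
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    C[0] = CA[0] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_residues):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            _BOND["N-CA"], _ANGLE["C-N-CA"], omega)
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           _BOND["CA-C"], _ANGLE["N-CA-C"], phi)

    O = np.zeros((n_residues, 3))
    for i in range(n_residues):
        # carbonyl O anti to the next amide N (torsion psi - 180)
        tors = psi - 180.0
        O[i] = _place_atom(N[i], CA[i], C[i],
                           _BOND["C-O"], _ANGLE["CA-C-O"], tors)

    if jitter > 0:
        N = N + rng.uniform(-jitter, jitter, N.shape)
        CA = CA + rng.uniform(-jitter, jitter, CA.shape)
        C = C + rng.uniform(-jitter, jitter, C.shape)
        O = O + rng.uniform(-jitter, jitter, O.shape)
    return BackboneStructure(sequence=sequence, n=N, ca=CA, c=C, o=O)


def gen_helix_backbone(n_residues: int, seed: int = 0,
                       sequence: str | None = None,
                       jitter: float = 0.0) -> BackboneStructure:
    """Ideal α-helical backbone (φ=−57°, ψ=−47°, ω=180°).

    ``jitter`` adds seeded uniform coordinate noise (≤ 0.1 Å recommended).
    """
    if jitter > 0.1:
        raise ValidationError("jitter above 0.1 Å breaks ideal-geometry checks")
    return _gen_backbone(n_residues, HELIX_PHI, HELIX_PSI, HELIX_OMEGA,
                         sequence, seed, jitter)


def gen_extended_backbone(n_residues: int, seed: int = 0,
                          sequence: str | None = None) -> BackboneStructure:
    """Fully extended chain (φ=ψ=180°), useful as a minimal-contact control."""
    return _gen_backbone(n_residues, 180.0, 180.0, 180.0, sequence, seed, 0.0)


def thread_sequence(structure: BackboneStructure,
                    new_sequence: str) -> BackboneStructure:
    """Thread a mutated sequence onto an existing backbone (no remodeling)."""
    if len(new_sequence) != len(structure):
        raise ValidationError("threaded sequence length mismatch")
    return BackboneStructure(
        sequence=new_sequence, n=structure.n.copy(), ca=structure.ca.copy(),
        c=structure.c.copy(),
        o=None if structure.o is None else structure.o.copy(),
        chain_id=structure.chain_id,
    )


# ---------------------------------------------------------------------------
# Mutation datasets

@dataclass
class FixtureSpec:
    """Shape of a synthetic mutation dataset.

    ΔΔG values are drawn from a two-Gaussian mixture (±``ddg_mean`` with sd
    ``ddg_sd``) under the stabilizing-positive convention; the stabilizing
    component is drawn with probability ``stabilizing_fraction`` (default
    0.3 — experimental thermodynamic databases skew destabilizing).
    """

    n_wildtypes: int = 5
    variants_per_wt: int = 4
    chain_length: int = 30
    ddg_mean: float = 1.5
    ddg_sd: float = 0.8
    stabilizing_fraction: float = 0.3
    n_mutations: tuple[int, int] = (1, 1)   # inclusive range per record
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_wildtypes, self.variants_per_wt, self.chain_length) < 1:
            raise ValidationError("counts must be positive")
        if not 0.0 <= self.stabilizing_fraction <= 1.0:
            raise ValidationError("stabilizing_fraction must lie in [0, 1]")


def _random_mutations(rng: np.random.Generator, sequence: str,
                      n_muts: int) -> tuple[PointMutation, ...]:
    positions = rng.choice(len(sequence), size=n_muts, replace=False)
    muts = []
    for pos in sorted(positions):
        from_aa = sequence[pos]
        to_aa = from_aa
        while to_aa == from_aa:
            to_aa = CANONICAL_AA[rng.integers(20)]
        muts.append(PointMutation(int(pos) + 1, from_aa, to_aa))
    return tuple(muts)


def gen_mutation_dataset(spec: FixtureSpec) -> Dataset:
    """Generate a labeled dataset with shared wild types and mixed ΔΔG."""
    rng = np.random.default_rng(spec.seed)
    records: list[MutationRecord] = []
    lo, hi = spec.n_mutations
    for w in range(spec.n_wildtypes):
        wt_seq = "".join(rng.choice(list(CANONICAL_AA),
                                    size=spec.chain_length))
        wt_id = f"synt{w:04d}"
        seen: set[tuple] = set()
        for v in range(spec.variants_per_wt):
            for _ in range(100):
                n_muts = int(rng.integers(lo, hi + 1))
                muts = _random_mutations(rng, wt_seq, n_muts)
                if muts not in seen:
                    seen.add(muts)
                    break
            stabilizing = rng.random() < spec.stabilizing_fraction
            ddg = rng.normal(spec.ddg_mean, spec.ddg_sd)
            ddg = abs(ddg) if stabilizing else -abs(ddg)
            if ddg == 0.0:
                ddg = 1e-6 if stabilizing else -1e-6
            records.append(MutationRecord(
                record_id=f"{wt_id}_v{v}",
                wt_id=wt_id,
                wt_sequence=wt_seq,
                mutations=muts,
                ddg=float(ddg),
                label=classify_label(float(ddg)),
            ))
    return Dataset(records=records, name=f"synthetic(seed={spec.seed})")


# ---------------------------------------------------------------------------
# Encoder side tables

def gen_pssm(sequence: str, seed: int = 0) -> np.ndarray:
    """Random (L, 20) log-odds-style profile, mildly peaked on the residue."""
    if not sequence:
        raise ValidationError("empty sequence")
    rng = np.random.default_rng(seed)
    mat = rng.normal(0.0, 2.0, size=(len(sequence), 20))
    for i, aa in enumerate(sequence):
        mat[i, CANONICAL_AA.index(aa)] += 2.0
    return mat


def gen_pssm_table(sequence: str, seed: int = 0) -> pd.DataFrame:
    """The same profile as a headered table in the featurize TSV dialect."""
    return pd.DataFrame(gen_pssm(sequence, seed), columns=list(CANONICAL_AA))


def gen_residue_scores(sequence: str, seed: int = 0) -> pd.DataFrame:
    """Random (L, 20) per-residue score table matching the 20-term schema."""
    if not sequence:
        raise ValidationError("empty sequence")
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, 1.0, size=(len(sequence), 20))
    return pd.DataFrame(data, columns=list(RESIDUE_SCORE_COLUMNS))


# ---------------------------------------------------------------------------
# Ready-made classifier fixtures

def gen_classification_fixture(
    n_pairs: int,
    seed: int = 0,
    chain_length: int = 12,
    k_neighbors: int = 8,
    separable: bool = True,
):
    """Graph-pair classification data for training sanity checks.

    Each sample is a (wild-type, mutant) graph pair built on an ideal helix.
    When ``separable``, the class is encoded in the mutant residue identity
    (label 1 mutates to tryptophan, label 0 to glycine), which the one-hot
    encoder exposes — a linearly recoverable signal the classifier must be
    able to overfit.  Returns (pairs, labels).
    """
    from .featurize import EncoderStack, build_graph

    rng = np.random.default_rng(seed)
    stack = EncoderStack()
    pairs = []
    labels = rng.integers(0, 2, size=n_pairs)
    for i in range(n_pairs):
        base = "".join(rng.choice(list(CANONICAL_AA.replace("W", "")
                                       .replace("G", "")),
                                  size=chain_length))
        wt = gen_helix_backbone(chain_length, seed=seed + i, sequence=base,
                                jitter=0.05)
        pos = int(rng.integers(1, chain_length - 1))
        if separable:
            to_aa = "W" if labels[i] == 1 else "G"
        else:
            to_aa = str(rng.choice([a for a in CANONICAL_AA
                                    if a != base[pos]]))
        mut_seq = base[:pos] + to_aa + base[pos + 1:]
        mut = thread_sequence(wt, mut_seq)
        pssm = gen_pssm(base, seed=seed + 10_000 + i)
        scores = gen_residue_scores(base, seed=seed + 20_000 + i)
        g_wt = build_graph(wt, stack, k_neighbors=k_neighbors,
                           pssm=pssm, residue_scores=scores)
        g_mut = build_graph(mut, stack, k_neighbors=k_neighbors,
                            pssm=pssm, residue_scores=scores)
        pairs.append((g_wt, g_mut))
    return pairs, np.asarray(labels, dtype=int)
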