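"""Two-level molecular graph featurization.

A drug molecule is represented at two resolutions:

* an **atom graph** — nodes are atoms, edges are chemical bonds, each node
  carrying a 101-dimensional binary feature vector;
* a **substructure graph** — the molecule is segmented into substructures
  (non-ring bonds, and ring clusters formed by merging simple rings that
  share at least three atoms), each substructure becoming one node with a
  35-dimensional binary feature vector.

All chemistry (parsing, sanitization, aromaticity, ring perception) is
delegated to RDKit; this module owns the segmentation rule, the feature
layouts and the substructure vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # RDKit prints parse noise to stderr otherwise

__all__ = [
    "SmilesParseError",
    "AtomRecord",
    "Molecule",
    "AtomGraph",
    "Substructure",
    "SubstructureVocabulary",
    "SubstructureGraph",
    "ATOM_FEATURE_DIM",
    "SUBSTRUCTURE_FEATURE_DIM",
    "ATOM_SYMBOLS",
    "parse_smiles",
    "atom_feature_vector",
    "build_atom_graph",
    "find_simple_rings",
    "segment_substructures",
    "build_vocabulary",
    "substructure_feature_vector",
    "build_substructure_graph",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


# --------------------------------------------------------------------------
# Feature layout
#
# Atom feature vector (101 slots, all binary), concatenated in this order:
#   [0:44)    element symbol one-hot over ATOM_SYMBOLS (43 symbols + "other")
#   [44:55)   degree one-hot, 0-10
#   [55:66)   total H count (explicit+implicit) one-hot, 0-10, clamped
#   [66:77)   implicit H count one-hot, 0-10, clamped
#   [77:88)   total valence one-hot, 0-10, clamped
#   [88:99)   formal charge one-hot, -5..+5, clamped
#   [99]      aromatic flag
#   [100]     in-ring flag
#
# Substructure feature vector (35 slots):
#   [0:11)    member-atom count one-hot, 0-10, clamped
#   [11:22)   neighbouring-substructure count one-hot, 0-10, clamped
#   [22:33)   total H count over member atoms one-hot, 0-10, clamped
#   [33]      contains-ring flag
#   [34]      contains-non-ring-bond flag
# --------------------------------------------------------------------------

ATOM_SYMBOLS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
)  # 43 symbols; a 44th "other" slot catches everything else

ATOM_FEATURE_DIM = 101
SUBSTRUCTURE_FEATURE_DIM = 35


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size, dtype=np.int8)
    v[index] = 1
    return v


def _clamped_one_hot(value: int, size: int) -> np.ndarray:
    return _one_hot(min(max(value, 0), size - 1), size)


@dataclass(frozen=True)
class AtomRecord:
    """Chemistry-toolkit facts about a single atom, frozen at parse time."""

    symbol: str
    formal_charge: int
    is_aromatic: bool
    in_ring: bool
    degree: int
    total_h: int
    implicit_h: int
    total_valence: int


@dataclass
class Molecule:
    """A parsed molecule: ordered atoms, bonds as index pairs, and the source
    SMILES. Atom indices are 0-based and follow RDKit's parse order."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]]
    source_smiles: str
    _rdmol: Chem.Mol = field(repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class AtomGraph:
    n_atoms: int
    adjacency: np.ndarray  # (n, n) symmetric binary, zero diagonal
    features: np.ndarray   # (n, 101) binary


@dataclass(frozen=True)
class Substructure:
    """One segmentation unit: a non-ring bond, a merged ring cluster, or (for
    molecules where nothing else covers an atom) a degenerate single atom."""

    kind: str  # "ring" | "bond" | "atom"
    atom_indices: frozenset[int]
    canonical_key: str


@dataclass
class SubstructureGraph:
    n_subs: int
    adjacency: np.ndarray  # (m, m) symmetric binary, zero diagonal
    features: np.ndarray   # (m, 35) binary
    membership: dict[int, frozenset[int]]


class SubstructureVocabulary:
    """Ordered, de-duplicated registry of substructure canonical keys.

    Ids are assigned in first-seen order, 0-based and contiguous, so the
    vocabulary built from the same SMILES list is always byte-identical when
    serialized.
    """

    def __init__(self, entries: Iterable[str] = ()) -> None:
        self._entries: list[str] = []
        self._index: dict[str, int] = {}
        for key in entries:
            self.add(key)

    def add(self, key: str) -> int:
        if key not in self._index:
            self._index[key] = len(self._entries)
            self._entries.append(key)
        return self._index[key]

    def id_of(self, key: str) -> int:
        return self._index[key]

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> list[str]:
        return list(self._entries)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, key in enumerate(self._entries):
                fh.write(f"{i}\t{key}\n")

    @classmethod
    def from_tsv(cls, path) -> "SubstructureVocabulary":
        vocab = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                _, key = line.split("\t", 1)
                vocab.add(key)
        return vocab


# --------------------------------------------------------------------------
# Parsing and atom-level graph
# --------------------------------------------------------------------------

def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    RDKit's standard sanitization runs, so aromaticity is perceived and
    implicit hydrogens are assigned. Raises :class:`SmilesParseError` for
    invalid or unsanitizable input.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    atoms = [
        AtomRecord(
            symbol=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            is_aromatic=a.GetIsAromatic(),
            in_ring=a.IsInRing(),
            degree=a.GetDegree(),
            total_h=a.GetTotalNumHs(),
            implicit_h=a.GetNumImplicitHs(),
            total_valence=a.GetTotalValence(),
        )
        for a in rdmol.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()
    ]
    return Molecule(atoms=atoms, bonds=bonds, source_smiles=smiles, _rdmol=rdmol)


def atom_feature_vector(molecule: Molecule, atom_index: int) -> np.ndarray:
    """101-dimensional binary feature vector for one atom (layout above)."""
    atom = molecule.atoms[atom_index]
    symbol_idx = ATOM_SYMBOLS.index(atom.symbol) if atom.symbol in ATOM_SYMBOLS else len(ATOM_SYMBOLS)
    parts = [
        _one_hot(symbol_idx, len(ATOM_SYMBOLS) + 1),
        _clamped_one_hot(atom.degree, 11),
        _clamped_one_hot(atom.total_h, 11),
        _clamped_one_hot(atom.implicit_h, 11),
        _clamped_one_hot(atom.total_valence, 11),
        _one_hot(min(max(atom.formal_charge, -5), 5) + 5, 11),
        np.array([1 if atom.is_aromatic else 0], dtype=np.int8),
        np.array([1 if atom.in_ring else 0], dtype=np.int8),
    ]
    return np.concatenate(parts)


def build_atom_graph(molecule: Molecule) -> AtomGraph:
    n = molecule.n_atoms
    adjacency = np.zeros((n, n), dtype=np.int8)
    for i, j in molecule.bonds:
        adjacency[i, j] = 1
        adjacency[j, i] = 1
    features = np.stack([atom_feature_vector(molecule, i) for i in range(n)])
    return AtomGraph(n_atoms=n, adjacency=adjacency, features=features)


# --------------------------------------------------------------------------
# Substructure segmentation
# --------------------------------------------------------------------------

def find_simple_rings(molecule: Molecule) -> list[frozenset[int]]:
    """Symmetrized smallest set of smallest rings, each as an atom-index set."""
    return [frozenset(r) for r in Chem.GetSymmSSSR(molecule._rdmol)]


def _fragment_key(molecule: Molecule, atom_indices: Sequence[int]) -> str:
    """Canonical SMILES of the fragment induced by ``atom_indices``; broken
    ring bonds are hydrogen-capped, so the key is deterministic and
    independent of where the fragment sits in its parent molecule."""
    atom_list = sorted(atom_indices)
    bond_ids = [
        b.GetIdx()
        for b in molecule._rdmol.GetBonds()
        if b.GetBeginAtomIdx() in atom_indices and b.GetEndAtomIdx() in atom_indices
    ]
    return Chem.MolFragmentToSmiles(
        molecule._rdmol,
        atomsToUse=atom_list,
        bondsToUse=bond_ids or None,
        canonical=True,
    )


def segment_substructures(molecule: Molecule) -> list[Substructure]:
    """Segment a molecule into substructures.

    Rules:

    * every bond that is not a member of any ring yields one ``bond``
      substructure (its two endpoint atoms);
    * simple rings are merged pairwise, iterated to a fixpoint, whenever two
      (possibly already merged) ring clusters share >= 3 atoms, then
      de-duplicated — each surviving cluster yields one ``ring``
      substructure;
    * any atom left uncovered (a single-atom molecule, or a bare ion in a
      multi-fragment SMILES) yields a degenerate ``atom`` substructure so the
      substructure graph is never empty and covers every atom.
    """
    subs: list[Substructure] = []
    rdmol = molecule._rdmol

    for bond in rdmol.GetBonds():
        if not bond.IsInRing():
            pair = frozenset((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            subs.append(
                Substructure(kind="bond", atom_indices=pair,
                             canonical_key=_fragment_key(molecule, pair))
            )

    clusters = [set(r) for r in find_simple_rings(molecule)]
    merged = True
    while merged:  # fixpoint: no two clusters share >= 3 atoms afterwards
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if len(clusters[i] & clusters[j]) >= 3:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break

    unique: list[frozenset[int]] = []
    for c in clusters:
        fc = frozenset(c)
        if fc not in unique:
            unique.append(fc)
    unique.sort(key=lambda s: (min(s), len(s)))
    for cluster in unique:
        subs.append(
            Substructure(kind="ring", atom_indices=cluster,
                         canonical_key=_fragment_key(molecule, cluster))
        )

    covered: set[int] = set()
    for s in subs:
        covered |= s.atom_indices
    for idx in range(molecule.n_atoms):
        if idx not in covered:
            single = frozenset((idx,))
            subs.append(
                Substructure(kind="atom", atom_indices=single,
                             canonical_key=_fragment_key(molecule, single))
            )
    return subs


def build_vocabulary(smiles_list: Iterable[str]) -> SubstructureVocabulary:
    """Union of substructure canonical keys over all molecules, first-seen
    order. Idempotent: repeating a SMILES adds nothing."""
    vocab = SubstructureVocabulary()
    for smiles in smiles_list:
        try:
            molecule = parse_smiles(smiles)
        except SmilesParseError as exc:
            raise SmilesParseError(f"in vocabulary input: {exc}") from exc
        for sub in segment_substructures(molecule):
            vocab.add(sub.canonical_key)
    return vocab


# --------------------------------------------------------------------------
# Substructure-level graph
# --------------------------------------------------------------------------

def substructure_feature_vector(
    molecule: Molecule,
    sub: Substructure,
    segmentation: Sequence[Substructure],
) -> np.ndarray:
    """35-dimensional binary feature vector for one substructure."""
    n_neighbors = sum(
        1
        for other in segmentation
        if other is not sub and other.atom_indices & sub.atom_indices
    )
    total_h = sum(molecule.atoms[i].total_h for i in sub.atom_indices)
    parts = [
        _clamped_one_hot(len(sub.atom_indices), 11),
        _clamped_one_hot(n_neighbors, 11),
        _clamped_one_hot(total_h, 11),
        np.array([1 if sub.kind == "ring" else 0], dtype=np.int8),
        np.array([1 if sub.kind == "bond" else 0], dtype=np.int8),
    ]
    return np.concatenate(parts)


def build_substructure_graph(
    molecule: Molecule, segmentation: Sequence[Substructure]
) -> SubstructureGraph:
    """Substructure graph: one node per substructure, edges wherever two
    substructures share at least one atom."""
    m = len(segmentation)
    adjacency = np.zeros((m, m), dtype=np.int8)
    for i in range(m):
        for j in range(i + 1, m):
            if segmentation[i].atom_indices & segmentation[j].atom_indices:
                adjacency[i, j] = 1
                adjacency[j, i] = 1
    features = np.stack(
        [substructure_feature_vector(molecule, s, segmentation) for s in segmentation]
    )
    membership = {i: s.atom_indices for i, s in enumerate(segmentation)}
    return SubstructureGraph(
        n_subs=m, adjacency=adjacency, features=features, membership=membership
    )
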