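"""Dataset I/O, affinity transforms, splitting, and synthetic data.

Supported layouts:

* **triples CSV** — columns ``drug_id, smiles, protein_id, sequence,
  affinity``; one record per row;
* **matrix style** (Davis/KIBA-like) — ``compounds.txt`` (id TAB smiles),
  ``proteins.txt`` (id TAB sequence) or a FASTA, and a dense affinity matrix
  TSV with an ``NA`` sentinel for unmeasured pairs.

Davis-style dissociation constants in nM are mapped to the log scale with
pKd = -log10(Kd / 1e9); KIBA-style composite scores pass through untouched.

The synthetic generator produces parseable small-molecule SMILES from a
fragment grammar, random protein sequences over the 20-letter alphabet, and
a smooth toy affinity that depends on simple molecular and protein
descriptors plus Gaussian noise — enough signal for every downstream stage
to be exercised without external downloads.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit.Chem import rdMolDescriptors

from .chem_graphs import SmilesParseError, parse_smiles
from .protein_embedding import read_fasta_sequences

__all__ = [
    "AffinityRecord",
    "DatasetSplit",
    "kd_to_pkd",
    "load_triples_csv",
    "save_triples_csv",
    "load_matrix_style",
    "split_dataset",
    "generate_synthetic_dataset",
    "toy_affinity",
    "TOY_AFFINITY_COEFFS",
    "HYDROPHOBIC_RESIDUES",
]


@dataclass
class AffinityRecord:
    """One (drug, protein, affinity) triple on the pKd or KIBA scale."""

    drug_smiles: str
    protein_sequence: str
    affinity: float
    drug_id: str = ""
    protein_id: str = ""


@dataclass
class DatasetSplit:
    """Six near-equal record-index parts: part 0 is the independent test
    set, the remaining five serve as cross-validation folds."""

    parts: list[np.ndarray]
    test_part: int = 0

    @property
    def test_indices(self) -> np.ndarray:
        return self.parts[self.test_part]

    @property
    def train_indices(self) -> np.ndarray:
        return np.concatenate(
            [p for i, p in enumerate(self.parts) if i != self.test_part]
        )

    def fold(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) indices for cross-validation fold k in 0..4."""
        folds = [p for i, p in enumerate(self.parts) if i != self.test_part]
        if not 0 <= k < len(folds):
            raise IndexError(f"fold index {k} out of range")
        val = folds[k]
        train = np.concatenate([p for i, p in enumerate(folds) if i != k])
        return train, val


def kd_to_pkd(kd_nM: float) -> float:
    """pKd = -log10(Kd / 1e9) for Kd given in nanomolar units."""
    if not kd_nM > 0:
        raise ValueError(f"Kd must be positive, got {kd_nM}")
    return -math.log10(kd_nM / 1e9)


# --------------------------------------------------------------------------
# File layouts
# --------------------------------------------------------------------------

_TRIPLES_COLUMNS = ["drug_id", "smiles", "protein_id", "sequence", "affinity"]


def load_triples_csv(path) -> list[AffinityRecord]:
    records: list[AffinityRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_TRIPLES_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                affinity = float(row["affinity"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad affinity value") from exc
            try:
                parse_smiles(row["smiles"])
            except SmilesParseError as exc:
                raise SmilesParseError(f"{path}:{lineno}: {exc}") from exc
            if not row["sequence"]:
                raise ValueError(f"{path}:{lineno}: empty protein sequence")
            records.append(
                AffinityRecord(
                    drug_smiles=row["smiles"],
                    protein_sequence=row["sequence"],
                    affinity=affinity,
                    drug_id=row["drug_id"],
                    protein_id=row["protein_id"],
                )
            )
    return records


def save_triples_csv(records: Sequence[AffinityRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRIPLES_COLUMNS)
        for r in records:
            writer.writerow(
                [r.drug_id, r.drug_smiles, r.protein_id, r.protein_sequence,
                 repr(r.affinity)]
            )


def _read_two_column(path) -> list[tuple[str, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                ident, value = line.split("\t", 1)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>value'") from exc
            out.append((ident, value))
    return out


def load_matrix_style(
    compounds_path,
    proteins_path,
    matrix_path,
    sentinel: str = "NA",
    transform: str = "none",
) -> list[AffinityRecord]:
    """Load a compound-list / protein-list / dense-matrix dataset.

    ``transform='pkd'`` applies the Kd -> pKd log transform to every stored
    value (for matrices holding raw Kd in nM); ``'none'`` passes values
    through (KIBA-style scores). Records are emitted in row-major order,
    skipping sentinel cells.
    """
    compounds = _read_two_column(compounds_path)
    for cid, smiles in compounds:
        try:
            parse_smiles(smiles)
        except SmilesParseError as exc:
            raise SmilesParseError(f"compound {cid!r}: {exc}") from exc
    if str(proteins_path).endswith((".fasta", ".fa", ".faa")):
        seqs = read_fasta_sequences(proteins_path)
        proteins = [(f"P{i}", s) for i, s in enumerate(seqs)]
    else:
        proteins = _read_two_column(proteins_path)

    records: list[AffinityRecord] = []
    with open(matrix_path, encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if len(rows) != len(compounds):
        raise ValueError(
            f"{matrix_path}: {len(rows)} rows but {len(compounds)} compounds"
        )
    for i, row in enumerate(rows):
        if len(row) != len(proteins):
            raise ValueError(
                f"{matrix_path}: row {i + 1} has {len(row)} cells, expected {len(proteins)}"
            )
        for j, cell in enumerate(row):
            if cell == sentinel:
                continue
            value = float(cell)
            if transform == "pkd":
                value = kd_to_pkd(value)
            elif transform != "none":
                raise ValueError(f"unknown transform {transform!r}")
            records.append(
                AffinityRecord(
                    drug_smiles=compounds[i][1],
                    protein_sequence=proteins[j][1],
                    affinity=value,
                    drug_id=compounds[i][0],
                    protein_id=proteins[j][0],
                )
            )
    return records


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------

def split_dataset(records: Sequence[AffinityRecord], seed: int) -> DatasetSplit:
    """Seeded shuffle into 6 near-equal parts (sizes differ by at most 1);
    part 0 is the independent test set, parts 1-5 the CV folds."""
    n = len(records)
    if n < 6:
        raise ValueError(f"need at least 6 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    parts = [np.sort(chunk) for chunk in np.array_split(order, 6)]
    return DatasetSplit(parts=parts)


# --------------------------------------------------------------------------
# Synthetic data
# --------------------------------------------------------------------------

# Linear fragments that remain valid SMILES under plain concatenation; all
# are small, so 1-5 of them stay well under 40 heavy atoms.
_FRAGMENTS = (
    "C", "CC", "CO", "CN", "CS", "C(F)", "C(Cl)", "C(Br)", "C(C)",
    "C(=O)N", "C(=O)O", "c1ccccc1", "c1ccncc1", "c1ccsc1", "C1CCCCC1",
    "C1CCNCC1", "c1ccc2ccccc2c1",
)

HYDROPHOBIC_RESIDUES = set("AVLIMFWY")

# affinity = a + b * n_aromatic_rings + c * n_heavy_atoms / 10
#            + d * hydrophobic_fraction + Gaussian(0, noise_sd)
TOY_AFFINITY_COEFFS = {"a": 4.0, "b": 0.8, "c": 0.5, "d": 2.0}


def toy_affinity(smiles: str, sequence: str) -> float:
    """Noise-free toy affinity from simple drug and protein descriptors."""
    mol = parse_smiles(smiles)._rdmol
    n_aromatic = rdMolDescriptors.CalcNumAromaticRings(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    hydro = sum(1 for ch in sequence if ch in HYDROPHOBIC_RESIDUES) / len(sequence)
    k = TOY_AFFINITY_COEFFS
    return k["a"] + k["b"] * n_aromatic + k["c"] * n_heavy / 10.0 + k["d"] * hydro


def generate_synthetic_dataset(
    n_drugs: int = 40,
    n_proteins: int = 20,
    n_records: int = 500,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> list[AffinityRecord]:
    """Generate a reproducible synthetic affinity dataset.

    Drugs are assembled from a fixed fragment grammar (1-5 fragments,
    guaranteeing parseable SMILES with <= 40 heavy atoms); proteins are
    uniform over the 20 standard letters with lengths in [50, 300]; labels
    follow the documented toy affinity plus Gaussian noise.
    """
    if min(n_drugs, n_proteins, n_records) < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)

    drugs: list[str] = []
    while len(drugs) < n_drugs:
        n_frag = int(rng.integers(1, 6))
        smiles = "".join(rng.choice(_FRAGMENTS) for _ in range(n_frag))
        mol = parse_smiles(smiles)._rdmol  # grammar guarantees parseability
        if mol.GetNumHeavyAtoms() <= 40:
            drugs.append(smiles)

    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    proteins = []
    for _ in range(n_proteins):
        length = int(rng.integers(50, 301))
        proteins.append("".join(rng.choice(alphabet, size=length)))

    records = []
    for k in range(n_records):
        di = int(rng.integers(n_drugs))
        pj = int(rng.integers(n_proteins))
        affinity = toy_affinity(drugs[di], proteins[pj])
        if noise_sd > 0:
            affinity += float(rng.normal(0.0, noise_sd))
        records.append(
            AffinityRecord(
                drug_smiles=drugs[di],
                protein_sequence=proteins[pj],
                affinity=float(affinity),
                drug_id=f"D{di}",
                protein_id=f"P{pj}",
            )
        )
    return records
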