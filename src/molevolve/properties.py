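"""Molecular property calculators shared across the pipeline.

QED is the quantitative estimate of drug-likeness (a [0,1] composite of
desirability functions over eight physicochemical properties); the SA score
is the Ertl-Schuffenhauer synthetic-accessibility estimate on its native
1 (easy) to 10 (hard) scale, computed from the published fragment
contributions shipped with RDKit.  Fingerprints are Morgan (ECFP-like)
radius-2, 2048-bit everywhere.

Also provides the deterministic mock docking scorers used in tests and demo
campaigns: cheap stand-ins that map a molecule to a kcal/mol-scale docking
score (lower = better) so the genetic optimizer can be exercised without an
external docking engine.
"""

from __future__ import annotations

import math
import os
import sys
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, QED, rdFingerprintGenerator

from .records import MoleculeRecord, count_stereocenters, mol_from_smiles

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, importable only after path append)

FINGERPRINT_RADIUS = 2
FINGERPRINT_BITS = 2048

# Reference agonists used in the lead-optimization campaigns.  JWH-133 is a
# selective CB2 receptor agonist (a deoxy-Δ8-THC analogue); (+)-pentazocine
# is a high-affinity sigma-1 receptor agonist.  The pentazocine benzomorphan
# nitrogen is encoded in its ammonium (pH ~7) form, the protonation state in
# which docking-prepared ligands are evaluated; JWH-133 has no ionizable
# group.
REFERENCE_LIGANDS = {
    "JWH-133": "CCCC(C)(C)C1=CC2=C(C=C1)[C@@H]1C=C(C)CC[C@H]1C(C)(C)O2",
    "(+)-pentazocine": "CC1[C@@H]2Cc3ccc(O)cc3[C@]1(C)CC[NH+]2CC=C(C)C",
}

_fpgen = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
)


class PropertyError(RuntimeError):
    """A property calculator failed on a supposedly valid molecule."""


@dataclass(frozen=True)
class PropertyVector:
    qed: float
    sa_raw: float
    logp: float
    mw: float
    n_chiral: int


def _as_mol(mol) -> Chem.Mol:
    if isinstance(mol, MoleculeRecord):
        return mol.to_mol()
    if isinstance(mol, str):
        return mol_from_smiles(mol)
    return mol


@lru_cache(maxsize=100_000)
def _qed_cached(smiles: str) -> float:
    try:
        return float(QED.qed(mol_from_smiles(smiles)))
    except Exception as exc:  # pragma: no cover - defensive
        raise PropertyError(f"QED failed: {exc}") from exc


@lru_cache(maxsize=100_000)
def _sa_cached(smiles: str) -> float:
    try:
        return float(sascorer.calculateScore(mol_from_smiles(smiles)))
    except Exception as exc:  # pragma: no cover - defensive
        raise PropertyError(f"SA score failed: {exc}") from exc


def _cache_key(mol) -> str:
    if isinstance(mol, MoleculeRecord):
        return mol.smiles
    if isinstance(mol, str):
        return mol
    return Chem.MolToSmiles(mol)


def qed_score(mol) -> float:
    return _qed_cached(_cache_key(mol))


def sa_score(mol) -> float:
    """Ertl SA score on the native 1-10 scale."""
    return _sa_cached(_cache_key(mol))


def compute_properties(mol) -> PropertyVector:
    m = _as_mol(mol)
    return PropertyVector(
        qed=qed_score(m),
        sa_raw=sa_score(m),
        logp=float(Crippen.MolLogP(m)),
        mw=float(Descriptors.MolWt(m)),
        n_chiral=count_stereocenters(m),
    )


def fingerprint(mol):
    """Morgan radius-2, 2048-bit fingerprint as an RDKit ExplicitBitVect."""
    return _fpgen.GetFingerprint(_as_mol(mol))


@lru_cache(maxsize=50_000)
def _fp_array_cached(smiles: str) -> np.ndarray:
    fp = _fpgen.GetFingerprint(mol_from_smiles(smiles))
    arr = np.zeros(FINGERPRINT_BITS, dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    arr.setflags(write=False)  # cached arrays are shared; keep them immutable
    return arr


def fingerprint_array(mol) -> np.ndarray:
    """Fingerprint as a float64 numpy vector (policy-network input)."""
    return _fp_array_cached(_cache_key(mol))


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a∧b|/|a∨b| between two bit vectors."""
    on_a = set(a.GetOnBits())
    on_b = set(b.GetOnBits())
    union = len(on_a | on_b)
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 0")
        return 0.0
    return len(on_a & on_b) / union


def tanimoto_mols(a, b) -> float:
    return tanimoto(fingerprint(a), fingerprint(b))


# ---------------------------------------------------------------------------
# Mock docking scorers
# ---------------------------------------------------------------------------

def _count_atoms(mol: Chem.Mol, symbol: str) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol)


def _mock_n_count(mol: Chem.Mol) -> float:
    # one pseudo-H-bond per nitrogen, 1.5 kcal/mol each
    return -1.5 * _count_atoms(mol, "N")


def _mock_o_count(mol: Chem.Mol) -> float:
    return -1.2 * _count_atoms(mol, "O")


def _mock_hetero_rings(mol: Chem.Mol) -> float:
    # rewards aromatic rings and polar contacts; loosely pharmacophore-like
    n_arom = Descriptors.NumAromaticRings(mol)
    n_hba = Descriptors.NumHAcceptors(mol)
    n_hbd = Descriptors.NumHDonors(mol)
    return -(1.8 * n_arom + 0.9 * n_hba + 0.7 * n_hbd)


_MOCK_FLAVORS = {
    "n_count": _mock_n_count,
    "o_count": _mock_o_count,
    "hetero_rings": _mock_hetero_rings,
}


def mock_scorer(flavor: str):
    """Return a deterministic SMILES -> docking-score callable.

    Flavors: ``n_count`` (nitrogen pharmacophores), ``o_count`` (oxygen),
    ``hetero_rings`` (aromatic rings + H-bond donors/acceptors).  All return
    kcal/mol-scale non-positive values, lower = better.
    """
    if flavor not in _MOCK_FLAVORS:
        raise ValueError(f"unknown mock scorer flavor {flavor!r}; "
                         f"choose from {sorted(_MOCK_FLAVORS)}")
    fn = _MOCK_FLAVORS[flavor]

    def scorer(smiles: str) -> float:
        return float(fn(_as_mol(smiles)))

    scorer.__name__ = f"mock_{flavor}"
    return scorer


def csv_adapter_scorer(path: str):
    """Scorer reading a ``smiles,score`` CSV produced by an external docking
    program between generations.  Unknown molecules raise ``KeyError``."""
    import pandas as pd

    table = pd.read_csv(path)
    lookup = {
        Chem.MolToSmiles(mol_from_smiles(s)): float(v)
        for s, v in zip(table.iloc[:, 0], table.iloc[:, 1])
    }

    def scorer(smiles: str) -> float:
        can = Chem.MolToSmiles(mol_from_smiles(smiles))
        return lookup[can]

    return scorer


def ligand_efficiency(ds: float, heavy_atom_count: int) -> float:
    """LE = docking score / sqrt(heavy atoms)."""
    if heavy_atom_count < 1:
        raise ValueError("heavy_atom_count must be >= 1")
    return ds / math.sqrt(heavy_atom_count)
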