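"""Corpus standardization and filtering pipeline.

Prepares a training/test corpus the way bioactivity-database extracts are
conventionally cleaned: keep the largest organic fragment (drops counterions
and solvents), neutralize formal charges, strip stereochemistry, replace
isotopes with their natural-abundance parents, canonicalize.  Filtering then
keeps molecules made only of C, N, O, F, P, S, Cl, Br, I (plus hydrogen)
with molecular weight between 160 and 600 Da inclusive, deduplicated by
canonical SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

ALLOWED_ELEMENTS = frozenset({"C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "H"})
MW_MIN = 160.0
MW_MAX = 600.0

_largest = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()


@dataclass
class StandardizerReport:
    n_in: int = 0
    n_after_standardize: int = 0
    n_after_element_filter: int = 0
    n_after_mw_filter: int = 0
    n_unique: int = 0
    rejections: dict = field(default_factory=dict)

    def _bump(self, reason: str) -> None:
        self.rejections[reason] = self.rejections.get(reason, 0) + 1


def standardize(smiles: str) -> str:
    """Standardize one SMILES; raises ``ValueError`` on unparseable input.

    Steps in order: largest organic fragment, charge neutralization, stereo
    removal, isotope parent, canonicalization.  Permanent cations (e.g.
    quaternary nitrogen) survive the uncharger unchanged, mirroring its
    standard behavior.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = _largest.choose(mol)
    mol = _uncharger.uncharge(mol)
    Chem.RemoveStereochemistry(mol)
    mol = rdMolStandardize.IsotopeParent(mol)
    return Chem.MolToSmiles(mol)


def _elements_ok(mol: Chem.Mol) -> bool:
    return all(a.GetSymbol() in ALLOWED_ELEMENTS for a in mol.GetAtoms())


def filter_corpus(smiles_iter) -> tuple[list[str], StandardizerReport]:
    """Standardize then filter a corpus; returns kept SMILES and a report.

    Pipeline: standardize -> element filter -> MW in [160, 600] Da
    (inclusive) -> uniqueness by canonical SMILES.
    """
    report = StandardizerReport()
    seen: set[str] = set()
    kept: list[str] = []
    for raw in smiles_iter:
        report.n_in += 1
        try:
            std = standardize(raw)
        except ValueError:
            report._bump("unparseable")
            continue
        mol = Chem.MolFromSmiles(std)
        if mol is None or mol.GetNumHeavyAtoms() == 0:
            report._bump("empty")
            continue
        report.n_after_standardize += 1
        if not _elements_ok(mol):
            report._bump("element")
            continue
        report.n_after_element_filter += 1
        mw = Descriptors.MolWt(mol)
        if mw < MW_MIN:
            report._bump("mw_low")
            continue
        if mw > MW_MAX:
            report._bump("mw_high")
            continue
        report.n_after_mw_filter += 1
        if std in seen:
            report._bump("duplicate")
            continue
        seen.add(std)
        kept.append(std)
    report.n_unique = len(kept)
    return kept, report
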