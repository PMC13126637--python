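"""BRICS building-block library and fixed substituent vocabularies.

The fragment library is built by BRICS-decomposing a corpus, keeping
fragments with at most ``max_heavy_atoms`` heavy atoms (attachment dummies
excluded), ranking distinct fragments by total occurrence and retaining the
top fraction (default 0.1% of distinct fragments, minimum one).  Ties at the
cutoff are broken by canonical-SMILES lexicographic order so construction is
deterministic for a fixed corpus.

The small-substituent vocabularies (aromatic decorations, polar and
lipophilic groups, halogens) are fixed constants consumed by the
transformation operators and the policy's decoration head.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import BRICS

from .records import mol_from_smiles

log = logging.getLogger(__name__)

# The seven aromatic decoration tokens, in head-index order.
DECORATIONS: tuple[str, ...] = ("F", "Cl", "Br", "I", "CF3", "NO2", "SO2CH3")

# Substituent group -> attachable fragment SMILES (dummy atom = attach point)
DECORATION_FRAGMENTS: dict[str, str] = {
    "F": "[*]F",
    "Cl": "[*]Cl",
    "Br": "[*]Br",
    "I": "[*]I",
    "CF3": "[*]C(F)(F)F",
    "NO2": "[*][N+](=O)[O-]",
    "SO2CH3": "[*]S(C)(=O)=O",
}

POLAR_GROUPS: dict[str, str] = {
    "OH": "[*]O",
    "NH2": "[*]N",
    "COOH": "[*]C(=O)O",
    "CONH2": "[*]C(N)=O",
    "SO2NH2": "[*]S(N)(=O)=O",
}

LIPOPHILIC_GROUPS: dict[str, str] = {
    "CH3": "[*]C",
    "C2H5": "[*]CC",
    "iPr": "[*]C(C)C",
    "tBu": "[*]C(C)(C)C",
    "cPr": "[*]C1CC1",
    "Ph": "[*]c1ccccc1",
}

HALOGENS: tuple[str, ...] = ("F", "Cl", "Br", "I")


@dataclass
class FragmentLibrary:
    """Ordered BRICS building-block library (most frequent first)."""

    fragments: list[str] = field(default_factory=list)
    occurrence_counts: list[int] = field(default_factory=list)
    max_heavy_atoms: int = 10
    top_fraction: float = 0.001

    def __len__(self) -> int:
        return len(self.fragments)

    def sample_fragment(self, index: int) -> str:
        """Fragment at the given occurrence rank (0 = most frequent)."""
        if not 0 <= index < len(self.fragments):
            raise IndexError(
                f"fragment index {index} out of range 0..{len(self.fragments) - 1}"
            )
        return self.fragments[index]

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "fragment_smiles": self.fragments,
                "occurrence": self.occurrence_counts,
                "rank": range(len(self.fragments)),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, max_heavy_atoms: int = 10,
                 top_fraction: float = 0.001) -> "FragmentLibrary":
        table = pd.read_csv(path).sort_values("rank")
        return cls(
            fragments=list(table["fragment_smiles"]),
            occurrence_counts=[int(x) for x in table["occurrence"]],
            max_heavy_atoms=max_heavy_atoms,
            top_fraction=top_fraction,
        )


def brics_fragments(mol: Chem.Mol) -> list[str]:
    """Canonical BRICS fragment SMILES of one molecule (with dummies)."""
    return sorted(BRICS.BRICSDecompose(mol, returnMols=False))


def _heavy_atoms_excluding_dummies(frag: Chem.Mol) -> int:
    return sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 1)


def _has_attachment(frag: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 0 for a in frag.GetAtoms())


def build_library(corpus, max_heavy_atoms: int = 10,
                  top_fraction: float = 0.001) -> FragmentLibrary:
    """Build the BRICS building-block library from a SMILES corpus.

    Invalid SMILES are skipped with a logged warning.  Molecules that BRICS
    cannot cut contribute themselves as a single pseudo-fragment (degenerate
    corpora still yield a usable one-entry library).
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    counts: dict[str, int] = {}
    n_invalid = 0
    for smi in corpus:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            n_invalid += 1
            log.warning("skipping invalid SMILES %r", smi)
            continue
        for frag_smi in BRICS.BRICSDecompose(mol, returnMols=False):
            frag = Chem.MolFromSmiles(frag_smi)
            if frag is None:
                continue
            if not _has_attachment(frag):
                # uncut molecule returned whole: give it a dummy so it can
                # still be attached (degenerate-corpus fallback)
                frag_smi = "[*]" + frag_smi if _valid_attachable(frag_smi) else None
                if frag_smi is None:
                    continue
                frag = Chem.MolFromSmiles(frag_smi)
                if frag is None:
                    continue
            if _heavy_atoms_excluding_dummies(frag) > max_heavy_atoms:
                continue
            can = Chem.MolToSmiles(frag)
            counts[can] = counts.get(can, 0) + 1
    if n_invalid:
        log.warning("skipped %d invalid SMILES out of %d", n_invalid, len(corpus))
    if not counts:
        raise ValueError("corpus produced no usable fragments")
    # occurrence descending, canonical SMILES ascending for ties
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n_keep = max(1, math.ceil(top_fraction * len(ranked)))
    kept = ranked[:n_keep]
    return FragmentLibrary(
        fragments=[s for s, _ in kept],
        occurrence_counts=[c for _, c in kept],
        max_heavy_atoms=max_heavy_atoms,
        top_fraction=top_fraction,
    )


def _valid_attachable(smiles: str) -> bool:
    return Chem.MolFromSmiles("[*]" + smiles) is not None
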