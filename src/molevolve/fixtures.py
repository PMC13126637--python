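"""Deterministic synthetic corpora for tests and demos.

Generates drug-like small molecules by seeded assembly of scaffold and
substituent templates.  A fixed set of anchor molecules spans every
transformation operator's structural precondition (aromatic rings, esters,
amides, alcohols, amines, halogens, stereocenters, nitro/sulfonyl
decorations, cyclizable chains), so each of the non-STOP actions is
applicable to at least one corpus molecule.  All output molecules are
chemically valid, survive the standardization pipeline unchanged, and fall
inside the requested molecular-weight band.

These corpora emulate the size and functional-group mix of a cleaned
bioactivity-database extract; they do not reproduce its scaffold frequency
distribution or activity annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .standardize import standardize
from .transforms import _attach, _has_h  # shared attachment machinery

# every non-STOP operator matches at least one of these
ANCHOR_MOLECULES = (
    "CC(=O)Oc1ccc(CCCCBr)cc1",             # ester/acetyl, terminal halogen, fuseable chain
    "CC(O)c1ccc(CN(C)C)cc1C(F)(F)F",       # stereocenter, alcohol, tert-amine, CF3 decoration
    "CC1CC(=O)CCC1CC(=O)O",                # ketone in ring, carboxylic acid, ring CH2
    "CCCC1CCCCC1CCO",                      # saturated carbocycle (aromatizable), alcohol
    "OCCCCCCOc1ccccc1",                    # cyclizable chain with terminal hydroxyl
    "O=C(NCCc1ccco1)c1ccncc1",             # amide, furan (ring O<->NH), pyridine
    "O=[N+]([O-])c1ccc(S(C)(=O)=O)cc1Cl",  # NO2 / SO2CH3 / Cl decorations
    "CNCCc1ccc(O)cc1OC",                   # phenol, secondary amine, N-methyl, ether linker
)

SCAFFOLDS = (
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCCCC1", "C1CCNCC1",
    "c1ccoc1", "c1cc[nH]c1", "C1COCCN1", "c1ncccn1", "C1CCC2CCCCC2C1",
    "c1ccc2[nH]ccc2c1", "C1CCOC1",
)

SUBSTITUENTS = (
    "[*]F", "[*]Cl", "[*]Br", "[*]O", "[*]N", "[*]C", "[*]CC", "[*]C(C)C",
    "[*]OC", "[*]C(=O)O", "[*]C(N)=O", "[*]C(C)=O", "[*]OC(C)=O",
    "[*]NC(C)=O", "[*]C(F)(F)F", "[*][N+](=O)[O-]", "[*]S(C)(=O)=O",
    "[*]c1ccccc1", "[*]CCCC", "[*]C(C)O", "[*]CCN(C)C", "[*]CCO",
    "[*]N1CCCCC1", "[*]CC(C)(C)C",
)


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 100
    seed: int = 0
    mw_band: tuple = (160.0, 500.0)
    max_substituents: int = 4
    include_anchors: bool = True


def _assemble(rng: np.random.Generator) -> str | None:
    scaffold = Chem.MolFromSmiles(SCAFFOLDS[int(rng.integers(len(SCAFFOLDS)))])
    mol = scaffold
    n_sub = int(rng.integers(1, 5))
    for _ in range(n_sub):
        sites = [a.GetIdx() for a in mol.GetAtoms()
                 if a.GetAtomicNum() == 6 and _has_h(a)]
        if not sites:
            break
        site = sites[int(rng.integers(len(sites)))]
        sub = SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))]
        new = _attach(mol, site, sub, rng)
        if new is not None:
            mol = new
    return Chem.MolToSmiles(mol) if mol is not None else None


def generate_fixture_corpus(spec: FixtureSpec) -> list[str]:
    """Deterministic corpus of standardization-stable SMILES.

    Anchors come first (when enabled), then seeded random assemblies;
    duplicates are skipped.  Same spec + seed gives an identical corpus.
    """
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.mw_band
    out: list[str] = []
    seen: set[str] = set()

    def admit(smiles: str) -> None:
        std = standardize(smiles)
        mol = Chem.MolFromSmiles(std)
        if mol is None or not lo <= Descriptors.MolWt(mol) <= hi:
            return
        if std in seen:
            return
        seen.add(std)
        out.append(std)

    if spec.include_anchors:
        for smi in ANCHOR_MOLECULES:
            admit(smi)
            if len(out) >= spec.n_molecules:
                return out[: spec.n_molecules]

    attempts = 0
    max_attempts = 200 * spec.n_molecules
    while len(out) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        smi = _assemble(rng)
        if smi is not None:
            try:
                admit(smi)
            except ValueError:
                continue
    if len(out) < spec.n_molecules:
        raise RuntimeError(
            f"could only assemble {len(out)} of {spec.n_molecules} molecules")
    return out


def write_smiles(smiles: list[str], path: str) -> None:
    with open(path, "w") as fh:
        for i, smi in enumerate(smiles):
            fh.write(f"{smi}\tmol{i}\n")


def read_smiles(path: str) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(line.split()[0])
    return out
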