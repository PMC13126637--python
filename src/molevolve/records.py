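"""Core molecular record type shared by every stage of the pipeline.

A :class:`MoleculeRecord` wraps a chemically valid molecule identified by its
canonical SMILES, together with the provenance lineage (the sequence of
transformation actions that produced it from its seed).  Equality and hashing
are by canonical SMILES only, so two records reached by different routes
compare equal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from rdkit import Chem


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string fails RDKit parsing/sanitization."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize a SMILES string, raising on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"invalid SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def count_stereocenters(mol: Chem.Mol) -> int:
    """Number of actual plus unassigned potential tetrahedral stereocenters.

    Unassigned centers are included deliberately: the chirality-reduction
    operator must strictly decrease this count, and a transformation that
    merely drops a CIP label without removing the center would otherwise
    pass.
    """
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return len(centers)


@dataclass(frozen=True)
class MoleculeRecord:
    """A valid molecule with canonical-SMILES identity and lineage.

    Parameters
    ----------
    smiles
        Canonical SMILES (computed by :meth:`from_smiles`).
    heavy_atom_count
        Number of non-hydrogen atoms.
    stereocenter_count
        Tetrahedral stereocenters, assigned or potential.
    lineage
        Ordered ``(action_name, params)`` tuples from the seed molecule.
    """

    smiles: str
    heavy_atom_count: int
    stereocenter_count: int
    lineage: tuple = field(default=(), compare=False, hash=False)

    @classmethod
    def from_smiles(cls, smiles: str, lineage: tuple = ()) -> "MoleculeRecord":
        mol = mol_from_smiles(smiles)
        return cls.from_mol(mol, lineage=lineage)

    @classmethod
    def from_mol(cls, mol: Chem.Mol, lineage: tuple = ()) -> "MoleculeRecord":
        can = Chem.MolToSmiles(mol)
        # re-parse: guarantees round-trip stability of the stored SMILES
        mol2 = Chem.MolFromSmiles(can)
        if mol2 is None:
            raise InvalidMoleculeError(f"SMILES does not round-trip: {can!r}")
        return cls(
            smiles=Chem.MolToSmiles(mol2),
            heavy_atom_count=mol2.GetNumHeavyAtoms(),
            stereocenter_count=count_stereocenters(mol2),
            lineage=tuple(lineage),
        )

    def to_mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)

    def with_step(self, action_name: str, params: dict) -> tuple:
        """Lineage extended by one step (helper for transform results)."""
        return self.lineage + ((action_name, tuple(sorted(params.items()))),)

    def lineage_json(self) -> str:
        """Lineage serialized as JSON lines (one record per step)."""
        lines = []
        for action, params in self.lineage:
            lines.append(
                json.dumps(
                    {"smiles": self.smiles, "action": action, "params": dict(params)}
                )
            )
        return "\n".join(lines)
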