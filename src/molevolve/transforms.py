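"""The 33 medicinal-chemistry transformation actions.

Each action is a molecular graph edit with a structural applicability
predicate (its *site* enumeration), uniform stochastic site selection under
a supplied seed, RDKit validity checking, and a bounded retry loop: one
attempt is a fresh site/variant draw followed by sanitization, and up to 20
attempts are made before the action is reported as ``failed_validity``
(distinct from ``inapplicable``, which means no site matched at all).

Operator vocabulary (action ids 0-32): fragment-based modifications,
functional-group transformations, ring-system modifications, reaction-like
edits (oxidation state, ester/amide chemistry), bioisosteric replacements,
chain modifications, and a control STOP action handled by the episode loop
rather than as a graph edit.  Terminal halogen exchange is one of the
bioisosteric sub-rules, and hetero-atom alkylation falls under lipophilic
group addition, whose site set is every atom with an available hydrogen.

All operators return net-neutral molecules except METHYLATE_AMINE, which is
allowed to quaternize a tertiary amine to an ammonium cation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import BondType

from .fragments import (
    DECORATION_FRAGMENTS,
    DECORATIONS,
    FragmentLibrary,
    HALOGENS,
    LIPOPHILIC_GROUPS,
    POLAR_GROUPS,
)
from .records import MoleculeRecord, count_stereocenters

RDLogger.DisableLog("rdApp.*")

MAX_ATTEMPTS = 20

_HALOGEN_NUMS = {9: "F", 17: "Cl", 35: "Br", 53: "I"}

# default condensation partners when no fragment library is supplied
DEFAULT_ALCOHOLS = ("CO", "CCO", "CCCO", "Oc1ccccc1", "OCc1ccccc1")
DEFAULT_AMINES = ("CN", "CCN", "CNC", "Nc1ccccc1", "NCc1ccccc1")

# small fallback fragment set so ADD_FRAG works without a built library
DEFAULT_CORE_FRAGMENTS = (
    "[*]c1ccccc1",
    "[*]C(C)=O",
    "[*]CCO",
    "[*]N1CCCCC1",
    "[*]C1CC1",
    "[*]c1ccncc1",
    "[*]C(N)=O",
)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActionSpec:
    action_id: int
    name: str
    action_class: str
    needs_core_fragment: bool = False
    needs_decoration: bool = False


_CATALOG_DEF = [
    ("ADD_FRAG", "fragment", True, False),
    ("DELETE_RING_SIDECHAIN", "fragment", False, False),
    ("REPLACE_SIDECHAIN_CORE", "fragment", True, False),
    ("REDUCE_CHIRALITY", "fragment", False, False),
    ("DECORATE_AROM", "functional_group", False, True),
    ("DELETE_DECOR_AROM", "functional_group", False, False),
    ("REPLACE_DECOR_AROM", "functional_group", False, True),
    ("HALOGENATE", "functional_group", False, False),
    ("DEHALOGENATE", "functional_group", False, False),
    ("NITRATE", "functional_group", False, False),
    ("SULFONYLATE", "functional_group", False, False),
    ("ADD_POLAR_GROUP", "functional_group", False, False),
    ("ADD_LIPOPHILIC_GROUP", "functional_group", False, False),
    ("SWAP_POLAR_LIPOPHILIC", "functional_group", False, False),
    ("METHYLATE_AMINE", "functional_group", False, False),
    ("DEMETHYLATE_AMINE", "functional_group", False, False),
    ("SATURATE_RING", "ring", False, False),
    ("AROMATIZE_RING", "ring", False, False),
    ("EXPAND_RING", "ring", False, False),
    ("CONTRACT_RING", "ring", False, False),
    ("FUSE_RINGS", "ring", False, False),
    ("CYCLIZE_CHAIN", "ring", False, False),
    ("OXIDIZE_ALCOHOL", "reaction", False, False),
    ("REDUCE_CARBONYL", "reaction", False, False),
    ("HYDROLYZE_ESTER", "reaction", False, False),
    ("FORM_ESTER", "reaction", False, False),
    ("FORM_AMIDE", "reaction", False, False),
    ("ACETYLATE_PHENOL", "reaction", False, False),
    ("DEACETYLATE", "reaction", False, False),
    ("BIOISOSTERIC_SWAP", "bioisostere", False, False),
    ("INSERT_CH2_LINKER", "chain", False, False),
    ("DELETE_CH2_LINKER", "chain", False, False),
    ("STOP", "control", False, False),
]

ACTION_CATALOG: tuple[ActionSpec, ...] = tuple(
    ActionSpec(i, name, cls, frag, deco)
    for i, (name, cls, frag, deco) in enumerate(_CATALOG_DEF)
)
ACTION_BY_NAME: dict[str, ActionSpec] = {a.name: a for a in ACTION_CATALOG}
N_ACTIONS = len(ACTION_CATALOG)
STOP_ACTION = ACTION_BY_NAME["STOP"].action_id


@dataclass(frozen=True)
class TransformResult:
    status: str  # success | inapplicable | failed_validity
    molecule: Optional[MoleculeRecord] = None
    attempts: int = 0


@dataclass
class ActionContext:
    core_fragment: Optional[str] = None
    decoration: Optional[str] = None
    library: Optional[FragmentLibrary] = None


# ---------------------------------------------------------------------------
# Shared graph-edit helpers
# ---------------------------------------------------------------------------

def _finalize(rw) -> Optional[Chem.Mol]:
    """Sanitize and round-trip through canonical SMILES; None on failure."""
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        smi = Chem.MolToSmiles(mol)
    except Exception:
        return None
    out = Chem.MolFromSmiles(smi)
    if out is None or out.GetNumHeavyAtoms() == 0:
        return None
    if len(Chem.GetMolFrags(out)) != 1:
        return None
    return out


def _has_h(atom) -> bool:
    return atom.GetTotalNumHs() >= 1


def _attach(mol: Chem.Mol, atom_idx: int, frag_smiles: str,
            rng: np.random.Generator) -> Optional[Chem.Mol]:
    """Attach a dummy-labelled fragment at ``atom_idx`` by a single bond.

    One dummy atom (chosen uniformly if several) becomes the attachment
    point; any leftover dummies are excised and their anchors regain a
    hydrogen.
    """
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    dummies = [a.GetIdx() for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
    if not dummies:
        return None
    chosen = dummies[int(rng.integers(len(dummies)))]
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    off = mol.GetNumAtoms()
    d_idx = off + chosen
    nbrs = [n.GetIdx() for n in combo.GetAtomWithIdx(d_idx).GetNeighbors()]
    if len(nbrs) != 1:
        return None
    anchor = nbrs[0]
    target = combo.GetAtomWithIdx(atom_idx)
    if target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    if combo.GetBondBetweenAtoms(atom_idx, anchor) is not None:
        return None
    combo.AddBond(atom_idx, anchor, BondType.SINGLE)
    for di in sorted((off + d for d in dummies), reverse=True):
        combo.RemoveAtom(di)
    return _finalize(combo)


def _branch_atoms(mol: Chem.Mol, anchor: int, first: int) -> Optional[set]:
    """Atoms reachable from ``first`` without passing through ``anchor``.

    None if the anchor-first bond is in a ring (no detachable branch).
    """
    bond = mol.GetBondBetweenAtoms(anchor, first)
    if bond is None or bond.IsInRing():
        return None
    seen = {first}
    stack = [first]
    while stack:
        a = stack.pop()
        for n in mol.GetAtomWithIdx(a).GetNeighbors():
            i = n.GetIdx()
            if i == anchor or i in seen:
                continue
            seen.add(i)
            stack.append(i)
    return seen


def _acyclic_branches(mol: Chem.Mol, anchor: int, max_size: int) -> list:
    """(first_atom, branch_set) for each fully acyclic branch off ``anchor``."""
    out = []
    for nbr in mol.GetAtomWithIdx(anchor).GetNeighbors():
        branch = _branch_atoms(mol, anchor, nbr.GetIdx())
        if branch is None or len(branch) > max_size:
            continue
        if any(mol.GetAtomWithIdx(i).IsInRing() for i in branch):
            continue
        out.append((nbr.GetIdx(), frozenset(branch)))
    return out


def _remove_atoms(mol: Chem.Mol, atoms) -> Optional[Chem.Mol]:
    rw = Chem.RWMol(mol)
    for idx in sorted(atoms, reverse=True):
        rw.RemoveAtom(idx)
    return _finalize(rw)


def _branch_signature(mol: Chem.Mol, branch: set) -> Optional[str]:
    """Canonical SMILES of a branch as a standalone molecule."""
    try:
        sub = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(branch))
        frag = Chem.MolFromSmiles(sub)
        if frag is None:
            return None
        return Chem.MolToSmiles(frag)
    except Exception:
        return None


def _group_signature(frag_smiles: str) -> str:
    """Canonical SMILES of a dummy-labelled group with the dummy hydrogenated."""
    mol = Chem.MolFromSmiles(frag_smiles)
    rw = Chem.RWMol(mol)
    for a in sorted((x.GetIdx() for x in rw.GetAtoms() if x.GetAtomicNum() == 0),
                    reverse=True):
        rw.RemoveAtom(a)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


_POLAR_SIGS = {_group_signature(v): k for k, v in POLAR_GROUPS.items()}
_LIPO_SIGS = {_group_signature(v): k for k, v in LIPOPHILIC_GROUPS.items()}
_DECOR_SIGS = {_group_signature(v): k for k, v in DECORATION_FRAGMENTS.items()}


def _matches(mol: Chem.Mol, smarts: str) -> list:
    patt = Chem.MolFromSmarts(smarts)
    return list(mol.GetSubstructMatches(patt))


# ---------------------------------------------------------------------------
# Site enumeration + edit, one pair of functions per action
# ---------------------------------------------------------------------------

def _sites_add_frag(mol, ctx):
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetAtomicNum() in (6, 7, 8) and _has_h(a)]


def _apply_add_frag(mol, site, ctx, rng):
    frag = ctx.core_fragment
    if frag is None:
        frag = DEFAULT_CORE_FRAGMENTS[int(rng.integers(len(DEFAULT_CORE_FRAGMENTS)))]
    return _attach(mol, site, frag, rng)


def _sidechain_cut_sites(mol, max_size=12):
    """(ring_side_atom, branch_first, branch_set): deletable side chains."""
    out = []
    if mol.GetRingInfo().NumRings() == 0:
        return out
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for anchor, first in ((a, b), (b, a)):
            branch = _branch_atoms(mol, anchor, first)
            if branch is None or len(branch) > max_size:
                continue
            if any(mol.GetAtomWithIdx(i).IsInRing() for i in branch):
                continue
            kept = set(range(mol.GetNumAtoms())) - branch
            if not any(mol.GetAtomWithIdx(i).IsInRing() for i in kept):
                continue
            out.append((anchor, first, frozenset(branch)))
    return out


def _sites_delete_ring_sidechain(mol, ctx):
    return _sidechain_cut_sites(mol)


def _apply_delete_ring_sidechain(mol, site, ctx, rng):
    _, _, branch = site
    return _remove_atoms(mol, branch)


def _sites_replace_sidechain_core(mol, ctx):
    return _sidechain_cut_sites(mol)


def _apply_replace_sidechain_core(mol, site, ctx, rng):
    anchor, _, branch = site
    rw = Chem.RWMol(mol)
    rw.GetAtomWithIdx(anchor).SetAtomMapNum(99)
    for idx in sorted(branch, reverse=True):
        rw.RemoveAtom(idx)
    pruned = _finalize(rw)
    if pruned is None:
        return None
    new_anchor = next((a.GetIdx() for a in pruned.GetAtoms()
                       if a.GetAtomMapNum() == 99), None)
    if new_anchor is None:
        return None
    pruned = Chem.RWMol(pruned)
    pruned.GetAtomWithIdx(new_anchor).SetAtomMapNum(0)
    pruned = pruned.GetMol()
    frag = ctx.core_fragment
    if frag is None:
        frag = DEFAULT_CORE_FRAGMENTS[int(rng.integers(len(DEFAULT_CORE_FRAGMENTS)))]
    return _attach(pruned, new_anchor, frag, rng)


def _sites_reduce_chirality(mol, ctx):
    return [0] if count_stereocenters(mol) >= 1 else []


def _sites_decorate_arom(mol, ctx):
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetIsAromatic() and a.GetAtomicNum() == 6 and _has_h(a)]


def _apply_decorate_arom(mol, site, ctx, rng):
    token = ctx.decoration
    if token is None:
        token = DECORATIONS[int(rng.integers(len(DECORATIONS)))]
    return _attach(mol, site, DECORATION_FRAGMENTS[token], rng)


def _decoration_sites(mol):
    """(aromatic_c, branch_set, token) for every recognized decoration."""
    out = []
    for atom in mol.GetAtoms():
        if not (atom.GetIsAromatic() and atom.GetAtomicNum() == 6):
            continue
        for nbr in atom.GetNeighbors():
            branch = _branch_atoms(mol, atom.GetIdx(), nbr.GetIdx())
            if branch is None or len(branch) > 4:
                continue
            sig = _branch_signature(mol, branch)
            if sig in _DECOR_SIGS:
                out.append((atom.GetIdx(), frozenset(branch), _DECOR_SIGS[sig]))
    return out


def _sites_delete_decor_arom(mol, ctx):
    return _decoration_sites(mol)


def _apply_delete_decor_arom(mol, site, ctx, rng):
    _, branch, _ = site
    return _remove_atoms(mol, branch)


def _sites_replace_decor_arom(mol, ctx):
    return _decoration_sites(mol)


def _apply_replace_decor_arom(mol, site, ctx, rng):
    anchor, branch, _ = site
    token = ctx.decoration
    if token is None:
        token = DECORATIONS[int(rng.integers(len(DECORATIONS)))]
    rw = Chem.RWMol(mol)
    rw.GetAtomWithIdx(anchor).SetAtomMapNum(99)
    for idx in sorted(branch, reverse=True):
        rw.RemoveAtom(idx)
    pruned = _finalize(rw)
    if pruned is None:
        return None
    new_anchor = next((a.GetIdx() for a in pruned.GetAtoms()
                       if a.GetAtomMapNum() == 99), None)
    if new_anchor is None:
        return None
    rw2 = Chem.RWMol(pruned)
    rw2.GetAtomWithIdx(new_anchor).SetAtomMapNum(0)
    return _attach(rw2.GetMol(), new_anchor, DECORATION_FRAGMENTS[token], rng)


def _sites_halogenate(mol, ctx):
    arom = [a.GetIdx() for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetIsAromatic() and _has_h(a)]
    if arom:
        return arom
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and _has_h(a)]


def _apply_halogenate(mol, site, ctx, rng):
    hal = HALOGENS[int(rng.integers(len(HALOGENS)))]
    return _attach(mol, site, f"[*]{hal}", rng)


def _sites_dehalogenate(mol, ctx):
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetAtomicNum() in _HALOGEN_NUMS and a.GetDegree() == 1]


def _apply_dehalogenate(mol, site, ctx, rng):
    return _remove_atoms(mol, [site])


def _sites_nitrate(mol, ctx):
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.IsInRing() and _has_h(a)]


def _apply_nitrate(mol, site, ctx, rng):
    return _attach(mol, site, "[*][N+](=O)[O-]", rng)


def _sites_sulfonylate(mol, ctx):
    # nucleophilic N-H preferred (sulfonamide); else aromatic C-H (sulfone)
    nh = [a.GetIdx() for a in mol.GetAtoms()
          if a.GetAtomicNum() == 7 and _has_h(a) and not a.GetIsAromatic()]
    if nh:
        return nh
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetIsAromatic() and _has_h(a)]


def _apply_sulfonylate(mol, site, ctx, rng):
    return _attach(mol, site, "[*]S(C)(=O)=O", rng)


def _sites_add_polar(mol, ctx):
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and _has_h(a)]


def _apply_add_polar(mol, site, ctx, rng):
    keys = sorted(POLAR_GROUPS)
    group = POLAR_GROUPS[keys[int(rng.integers(len(keys)))]]
    return _attach(mol, site, group, rng)


def _sites_add_lipophilic(mol, ctx):
    # includes N/O-H sites: hetero-atom alkylation is this operator's
    # methyl/ethyl case
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetAtomicNum() in (6, 7, 8) and _has_h(a)]


def _apply_add_lipophilic(mol, site, ctx, rng):
    keys = sorted(LIPOPHILIC_GROUPS)
    if mol.GetAtomWithIdx(site).GetAtomicNum() in (7, 8):
        keys = ["CH3", "C2H5"]  # O/N-alkylation: methylate or ethylate
    group = LIPOPHILIC_GROUPS[keys[int(rng.integers(len(keys)))]]
    return _attach(mol, site, group, rng)


def _terminal_group_sites(mol, signatures):
    """(anchor_c, branch_set, token) for complete terminal groups on carbon."""
    out = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        for nbr in atom.GetNeighbors():
            branch = _branch_atoms(mol, atom.GetIdx(), nbr.GetIdx())
            if branch is None or len(branch) > 8:
                continue
            sig = _branch_signature(mol, branch)
            if sig in signatures:
                out.append((atom.GetIdx(), frozenset(branch), signatures[sig]))
    return out


def _sites_swap_polar_lipo(mol, ctx):
    polar = [(a, b, t, "polar") for a, b, t in _terminal_group_sites(mol, _POLAR_SIGS)]
    lipo = [(a, b, t, "lipo") for a, b, t in _terminal_group_sites(mol, _LIPO_SIGS)]
    return polar + lipo


def _apply_swap_polar_lipo(mol, site, ctx, rng):
    anchor, branch, _, kind = site
    table = LIPOPHILIC_GROUPS if kind == "polar" else POLAR_GROUPS
    keys = sorted(table)
    group = table[keys[int(rng.integers(len(keys)))]]
    rw = Chem.RWMol(mol)
    rw.GetAtomWithIdx(anchor).SetAtomMapNum(99)
    for idx in sorted(branch, reverse=True):
        rw.RemoveAtom(idx)
    pruned = _finalize(rw)
    if pruned is None:
        return None
    new_anchor = next((a.GetIdx() for a in pruned.GetAtoms()
                       if a.GetAtomMapNum() == 99), None)
    if new_anchor is None:
        return None
    rw2 = Chem.RWMol(pruned)
    rw2.GetAtomWithIdx(new_anchor).SetAtomMapNum(0)
    return _attach(rw2.GetMol(), new_anchor, group, rng)


def _is_amine_n(atom) -> bool:
    if atom.GetAtomicNum() != 7 or atom.GetIsAromatic():
        return False
    # exclude amides/sulfonamides: N bonded to C=O or S=O
    for nbr in atom.GetNeighbors():
        for b in nbr.GetBonds():
            if b.GetBondType() == BondType.DOUBLE:
                other = b.GetOtherAtom(nbr)
                if other.GetAtomicNum() in (8, 16) and other.GetIdx() != atom.GetIdx():
                    return False
    return True


def _sites_methylate_amine(mol, ctx):
    out = []
    for a in mol.GetAtoms():
        if not _is_amine_n(a) or a.GetFormalCharge() != 0:
            continue
        if _has_h(a) or a.GetDegree() == 3:
            out.append(a.GetIdx())
    return out


def _apply_methylate_amine(mol, site, ctx, rng):
    atom = mol.GetAtomWithIdx(site)
    quaternize = not _has_h(atom) and atom.GetDegree() == 3
    rw = Chem.RWMol(mol)
    c = rw.AddAtom(Chem.Atom(6))
    target = rw.GetAtomWithIdx(site)
    if quaternize:
        target.SetFormalCharge(1)
    elif target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    rw.AddBond(site, c, BondType.SINGLE)
    return _finalize(rw)


def _sites_demethylate_amine(mol, ctx):
    out = []
    for a in mol.GetAtoms():
        if a.GetAtomicNum() != 7 or a.GetIsAromatic():
            continue
        for nbr in a.GetNeighbors():
            if (nbr.GetAtomicNum() == 6 and nbr.GetDegree() == 1
                    and nbr.GetTotalNumHs() == 3):
                out.append((a.GetIdx(), nbr.GetIdx()))
    return out


def _apply_demethylate_amine(mol, site, ctx, rng):
    n_idx, c_idx = site
    rw = Chem.RWMol(mol)
    n = rw.GetAtomWithIdx(n_idx)
    if n.GetFormalCharge() == 1:
        n.SetFormalCharge(0)
    rw.RemoveAtom(c_idx)
    return _finalize(rw)


def _aromatic_rings(mol):
    info = mol.GetRingInfo()
    rings = []
    for ring in info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(tuple(ring))
    return rings


def _sites_saturate_ring(mol, ctx):
    # only aromatic rings not fused to another aromatic ring: saturating one
    # ring of a fused aromatic system cannot yield a kekulizable molecule
    rings = _aromatic_rings(mol)
    out = []
    for i, ring in enumerate(rings):
        shared = False
        for j, other in enumerate(rings):
            if i != j and set(ring) & set(other):
                shared = True
                break
        if not shared:
            out.append(ring)
    return out


def _apply_saturate_ring(mol, site, ctx, rng):
    ring = set(site)
    rw = Chem.RWMol(mol)
    for idx in ring:
        atom = rw.GetAtomWithIdx(idx)
        atom.SetIsAromatic(False)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
    for bond in rw.GetBonds():
        if bond.GetBeginAtomIdx() in ring and bond.GetEndAtomIdx() in ring:
            bond.SetBondType(BondType.SINGLE)
            bond.SetIsAromatic(False)
        elif bond.GetBeginAtomIdx() in ring or bond.GetEndAtomIdx() in ring:
            if bond.GetIsAromatic():
                return None
    return _finalize(rw)


def _sites_aromatize_ring(mol, ctx):
    out = []
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) != 6:
            continue
        ok = True
        for idx in ring:
            atom = mol.GetAtomWithIdx(idx)
            if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
                ok = False
                break
            if atom.GetDegree() > 3 or atom.GetFormalCharge() != 0:
                ok = False
                break
            for b in atom.GetBonds():
                other = b.GetOtherAtom(atom)
                if (b.GetBondType() != BondType.SINGLE
                        and other.GetIdx() not in ring):
                    ok = False  # exocyclic multiple bond blocks aromatization
                    break
            if not ok:
                break
        if ok:
            out.append(tuple(ring))
    return out


def _apply_aromatize_ring(mol, site, ctx, rng):
    ring = set(site)
    rw = Chem.RWMol(mol)
    for idx in ring:
        atom = rw.GetAtomWithIdx(idx)
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
        atom.SetIsAromatic(True)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
    for bond in rw.GetBonds():
        if bond.GetBeginAtomIdx() in ring and bond.GetEndAtomIdx() in ring:
            bond.SetBondType(BondType.AROMATIC)
            bond.SetIsAromatic(True)
    return _finalize(rw)


def _sites_expand_ring(mol, ctx):
    return [(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
            for b in mol.GetBonds() if b.IsInRing()]


def _apply_expand_ring(mol, site, ctx, rng):
    a, b = site
    rw = Chem.RWMol(mol)
    try:
        Chem.Kekulize(rw, clearAromaticFlags=True)
    except Exception:
        return None
    bond = rw.GetBondBetweenAtoms(a, b)
    if bond is None:
        return None
    rw.RemoveBond(a, b)
    c = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(a, c, BondType.SINGLE)
    rw.AddBond(c, b, BondType.SINGLE)
    return _finalize(rw)


def _sites_contract_ring(mol, ctx):
    out = []
    ri = mol.GetRingInfo()
    for a in mol.GetAtoms():
        if a.GetAtomicNum() != 6 or a.GetIsAromatic():
            continue
        if not a.IsInRing() or ri.NumAtomRings(a.GetIdx()) != 1:
            continue
        if a.GetDegree() != 2 or a.GetTotalNumHs() < 2:
            continue
        n1, n2 = [n.GetIdx() for n in a.GetNeighbors()]
        if mol.GetBondBetweenAtoms(n1, n2) is not None:
            continue
        out.append((a.GetIdx(), n1, n2))
    return out


def _apply_contract_ring(mol, site, ctx, rng):
    idx, n1, n2 = site
    rw = Chem.RWMol(mol)
    try:
        Chem.Kekulize(rw, clearAromaticFlags=True)
    except Exception:
        return None
    rw.RemoveAtom(idx)
    shift = lambda i: i - 1 if i > idx else i
    rw.AddBond(shift(n1), shift(n2), BondType.SINGLE)
    return _finalize(rw)


def _sites_fuse_rings(mol, ctx):
    # ring edge (a1,a2) plus an acyclic chain of 3-5 atoms rooted at a1:
    # bonding the chain terminus to a2 creates a fused 5-7-membered ring
    out = []
    for bond in mol.GetBonds():
        if not bond.IsInRing():
            continue
        for a1, a2 in ((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()),
                       (bond.GetEndAtomIdx(), bond.GetBeginAtomIdx())):
            if not _has_h(mol.GetAtomWithIdx(a2)):
                continue
            for nbr in mol.GetAtomWithIdx(a1).GetNeighbors():
                if nbr.IsInRing() or nbr.GetIdx() == a2:
                    continue
                # simple acyclic paths from nbr, up to 5 atoms
                paths = [[nbr.GetIdx()]]
                for path in paths:
                    last = mol.GetAtomWithIdx(path[-1])
                    if 3 <= len(path) <= 5 and _has_h(last):
                        out.append((a1, a2, tuple(path)))
                    if len(path) >= 5:
                        continue
                    for nxt in last.GetNeighbors():
                        i = nxt.GetIdx()
                        if i == a1 or i in path or nxt.IsInRing():
                            continue
                        paths.append(path + [i])
    return out


def _apply_fuse_rings(mol, site, ctx, rng):
    a1, a2, path = site
    terminus = path[-1]
    rw = Chem.RWMol(mol)
    if rw.GetBondBetweenAtoms(terminus, a2) is not None:
        return None
    t = rw.GetAtomWithIdx(terminus)
    if t.GetNumExplicitHs() > 0:
        t.SetNumExplicitHs(t.GetNumExplicitHs() - 1)
    target = rw.GetAtomWithIdx(a2)
    if not _has_h(target):
        return None
    if target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    rw.AddBond(terminus, a2, BondType.SINGLE)
    return _finalize(rw)


def _sites_cyclize_chain(mol, ctx):
    out = []
    n = mol.GetNumAtoms()
    cands = []
    for a in mol.GetAtoms():
        if a.IsInRing() or not _has_h(a):
            continue
        z = a.GetAtomicNum()
        if z == 6 or (z in (7, 8) and a.GetDegree() == 1):
            cands.append(a.GetIdx())
    for i_pos, i in enumerate(cands):
        for j in cands[i_pos + 1:]:
            path = Chem.GetShortestPath(mol, i, j)
            if not path:
                continue
            nbonds = len(path) - 1
            if not 3 <= nbonds <= 10:
                continue
            ok = True
            for k in range(nbonds):
                b = mol.GetBondBetweenAtoms(path[k], path[k + 1])
                if b.GetBondType() != BondType.SINGLE or b.IsInRing():
                    ok = False
                    break
            if ok and not any(mol.GetAtomWithIdx(p).IsInRing() for p in path):
                out.append((i, j))
    return out


def _apply_cyclize_chain(mol, site, ctx, rng):
    i, j = site
    rw = Chem.RWMol(mol)
    for idx in (i, j):
        a = rw.GetAtomWithIdx(idx)
        if a.GetNumExplicitHs() > 0:
            a.SetNumExplicitHs(a.GetNumExplicitHs() - 1)
    rw.AddBond(i, j, BondType.SINGLE)
    return _finalize(rw)


def _sites_oxidize_alcohol(mol, ctx):
    return _matches(mol, "[CX4;H1,H2]-[OX2H1]")


def _apply_oxidize_alcohol(mol, site, ctx, rng):
    c, o = site
    rw = Chem.RWMol(mol)
    rw.GetBondBetweenAtoms(c, o).SetBondType(BondType.DOUBLE)
    atom_c = rw.GetAtomWithIdx(c)
    atom_o = rw.GetAtomWithIdx(o)
    atom_c.SetNumExplicitHs(max(0, atom_c.GetTotalNumHs() - 1))
    atom_c.SetNoImplicit(False)
    atom_o.SetNumExplicitHs(0)
    atom_o.SetNoImplicit(False)
    return _finalize(rw)


def _sites_reduce_carbonyl(mol, ctx):
    out = []
    for c, o in _matches(mol, "[CX3]=[OX1]"):
        atom = mol.GetAtomWithIdx(c)
        if atom.GetIsAromatic():
            continue
        skip = False
        for nbr in atom.GetNeighbors():
            if nbr.GetIdx() == o:
                continue
            if nbr.GetAtomicNum() in (7, 8, 16):
                skip = True  # acid/ester/amide/thioester, not a ketone
                break
        if not skip:
            out.append((c, o))
    return out


def _apply_reduce_carbonyl(mol, site, ctx, rng):
    c, o = site
    rw = Chem.RWMol(mol)
    rw.GetBondBetweenAtoms(c, o).SetBondType(BondType.SINGLE)
    for idx in (c, o):
        a = rw.GetAtomWithIdx(idx)
        a.SetNumExplicitHs(0)
        a.SetNoImplicit(False)
    return _finalize(rw)


def _ester_matches(mol):
    # acyl C, carbonyl O, ester O, R' C
    return _matches(mol, "[CX3](=[OX1])[OX2][#6]")


def _sites_hydrolyze_ester(mol, ctx):
    return _ester_matches(mol)


def _apply_hydrolyze_ester(mol, site, ctx, rng):
    acyl, _, ester_o, _ = site
    rw = Chem.RWMol(mol)
    in_ring = rw.GetBondBetweenAtoms(acyl, ester_o).IsInRing()
    rw.RemoveBond(acyl, ester_o)
    new_o = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(acyl, new_o, BondType.SINGLE)
    eo = rw.GetAtomWithIdx(ester_o)
    eo.SetNumExplicitHs(0)
    eo.SetNoImplicit(False)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if in_ring:
        return _finalize(Chem.RWMol(out))
    frags = Chem.GetMolFrags(out, asMols=True, sanitizeFrags=True)
    if not frags:
        return None
    # keep the largest fragment; ties broken by canonical SMILES
    best = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return _finalize(Chem.RWMol(best))


def _sites_carboxyl(mol, ctx):
    # acid C, =O, OH
    return _matches(mol, "[CX3](=[OX1])[OX2H1]")


def _condensation_partners(ctx, kind):
    """Hydroxyl- or amine-bearing partners for condensation reactions."""
    patt = "[OX2H1]" if kind == "alcohol" else "[NX3;H1,H2]"
    if ctx.library is not None and len(ctx.library) > 0:
        p = Chem.MolFromSmarts(patt)
        cands = [f for f in ctx.library.fragments
                 if (m := Chem.MolFromSmiles(f)) is not None
                 and m.HasSubstructMatch(p)]
        if cands:
            return cands
    return list(DEFAULT_ALCOHOLS if kind == "alcohol" else DEFAULT_AMINES)


def _apply_form_ester(mol, site, ctx, rng):
    acid_c, _, oh = site
    partners = _condensation_partners(ctx, "alcohol")
    partner_smi = partners[int(rng.integers(len(partners)))]
    partner = Chem.MolFromSmiles(partner_smi)
    if partner is None:
        return None
    # pick an OH in the partner; its carbon attaches to the acid oxygen
    oh_matches = partner.GetSubstructMatches(Chem.MolFromSmarts("[#6][OX2H1]"))
    if not oh_matches:
        return None
    pc, po = oh_matches[int(rng.integers(len(oh_matches)))]
    rw = Chem.RWMol(partner)
    rw.GetAtomWithIdx(pc).SetAtomMapNum(98)
    rw.RemoveAtom(po)
    for d in sorted((a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0),
                    reverse=True):
        rw.RemoveAtom(d)
    radical = rw.GetMol()
    combo = Chem.RWMol(Chem.CombineMols(mol, radical))
    p_anchor = next((a.GetIdx() for a in combo.GetAtoms()
                     if a.GetAtomMapNum() == 98), None)
    if p_anchor is None:
        return None
    combo.GetAtomWithIdx(p_anchor).SetAtomMapNum(0)
    o_atom = combo.GetAtomWithIdx(oh)
    o_atom.SetNumExplicitHs(0)
    o_atom.SetNoImplicit(False)
    combo.AddBond(oh, p_anchor, BondType.SINGLE)
    return _finalize(combo)


def _apply_form_amide(mol, site, ctx, rng):
    acid_c, _, oh = site
    partners = _condensation_partners(ctx, "amine")
    partner_smi = partners[int(rng.integers(len(partners)))]
    partner = Chem.MolFromSmiles(partner_smi)
    if partner is None:
        return None
    n_matches = [m[0] for m in partner.GetSubstructMatches(
        Chem.MolFromSmarts("[NX3;H1,H2;!$(N=*)]"))]
    if not n_matches:
        return None
    pn = n_matches[int(rng.integers(len(n_matches)))]
    rw = Chem.RWMol(partner)
    rw.GetAtomWithIdx(pn).SetAtomMapNum(98)
    for d in sorted((a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0),
                    reverse=True):
        rw.RemoveAtom(d)
    combo = Chem.RWMol(Chem.CombineMols(mol, rw.GetMol()))
    p_anchor = next((a.GetIdx() for a in combo.GetAtoms()
                     if a.GetAtomMapNum() == 98), None)
    if p_anchor is None:
        return None
    n_atom = combo.GetAtomWithIdx(p_anchor)
    n_atom.SetAtomMapNum(0)
    if n_atom.GetNumExplicitHs() > 0:
        n_atom.SetNumExplicitHs(n_atom.GetNumExplicitHs() - 1)
    combo.RemoveAtom(oh)  # acid OH leaves as water
    shift = lambda i: i - 1 if i > oh else i
    combo.AddBond(shift(acid_c), shift(p_anchor), BondType.SINGLE)
    return _finalize(combo)


def _sites_acetylate_phenol(mol, ctx):
    return [m[1] for m in _matches(mol, "[c][OX2H1]")]


def _apply_acetylate_phenol(mol, site, ctx, rng):
    return _attach(mol, site, "[*]C(C)=O", rng)


def _sites_deacetylate(mol, ctx):
    # terminal acetyl branch R-C(=O)CH3 on O, N or C
    out = []
    for anchor, acyl, _o, _c in _matches(mol, "[#6,#7,#8][CX3](=[OX1])[CH3]"):
        branch = _branch_atoms(mol, anchor, acyl)
        if branch is None:
            continue
        if _branch_signature(mol, branch) == "CC=O":
            out.append((anchor, frozenset(branch)))
    return out


def _apply_deacetylate(mol, site, ctx, rng):
    _, branch = site
    return _remove_atoms(mol, branch)


# --- bioisosteric sub-rules -------------------------------------------------

def _bio_ring_o_nh(mol):
    out = []
    for a in mol.GetAtoms():
        if not a.IsInRing() or a.GetDegree() != 2 or a.GetFormalCharge() != 0:
            continue
        in5 = mol.GetRingInfo().IsAtomInRingOfSize(a.GetIdx(), 5)
        if not in5:
            continue
        if a.GetAtomicNum() == 8:
            out.append(("ring_o_nh", a.GetIdx(), 7))
        elif a.GetAtomicNum() == 7 and a.GetTotalNumHs() == 1:
            out.append(("ring_o_nh", a.GetIdx(), 8))
    return out


_LINKER_ELEMS = {6, 7, 8, 16}


def _bio_linker(mol):
    out = []
    for a in mol.GetAtoms():
        if a.IsInRing() or a.GetIsAromatic() or a.GetFormalCharge() != 0:
            continue
        if a.GetAtomicNum() not in _LINKER_ELEMS or a.GetDegree() != 2:
            continue
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() != 2:
            continue
        if any(b.GetBondType() != BondType.SINGLE for b in a.GetBonds()):
            continue
        for z in sorted(_LINKER_ELEMS - {a.GetAtomicNum()}):
            out.append(("linker", a.GetIdx(), z))
    return out


def _bio_carbonyl_thio(mol):
    out = []
    for c, x in _matches(mol, "[CX3]=[OX1]"):
        out.append(("chalcogen", x, 16))
    for c, x in _matches(mol, "[CX3]=[SX1]"):
        out.append(("chalcogen", x, 8))
    return out


def _bio_ester_hydrazide(mol):
    out = []
    for m in _ester_matches(mol):
        out.append(("ester_to_hydrazide", m, None))
    for m in _matches(mol, "[CX3](=[OX1])[NX3;H1][NX3;H1][#6]"):
        out.append(("hydrazide_to_ester", m, None))
    return out


def _bio_terminal(mol):
    out = []
    for a in mol.GetAtoms():
        if a.GetDegree() != 1 or a.GetFormalCharge() != 0:
            continue
        nbr = a.GetNeighbors()[0]
        if nbr.GetAtomicNum() != 6:
            continue
        z = a.GetAtomicNum()
        bond = a.GetBonds()[0]
        if bond.GetBondType() != BondType.SINGLE:
            continue
        if z == 9:
            out.append(("delete_terminal", a.GetIdx(), None))  # F -> H
        elif z in (8, 7, 6):
            # OH <-> NH2 <-> CH3 terminal swaps
            for new_z in (8, 7, 6):
                if new_z != z:
                    out.append(("element_swap", a.GetIdx(), new_z))
        elif z in (17, 35, 53):
            for new_z in (9, 17, 35, 53):
                if new_z != z:
                    out.append(("element_swap", a.GetIdx(), new_z))
    # H -> F on a carbon with an available hydrogen
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 6 and _has_h(a):
            out.append(("add_f", a.GetIdx(), None))
    return out


_BIO_SUBRULES = (
    _bio_ring_o_nh,
    _bio_linker,
    _bio_carbonyl_thio,
    _bio_ester_hydrazide,
    _bio_terminal,
)


def _sites_bioisosteric(mol, ctx):
    groups = [fn(mol) for fn in _BIO_SUBRULES]
    return [g for g in groups if g]


def _apply_bioisosteric(mol, site_group, ctx, rng):
    # one sub-rule was drawn (= the group); now one site uniformly within it
    kind, payload, arg = site_group[int(rng.integers(len(site_group)))]
    rw = Chem.RWMol(mol)
    if kind in ("ring_o_nh", "linker", "chalcogen", "element_swap"):
        atom = rw.GetAtomWithIdx(payload)
        atom.SetAtomicNum(arg)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
        if kind == "ring_o_nh" and arg == 7 and atom.GetIsAromatic():
            atom.SetNumExplicitHs(1)
        return _finalize(rw)
    if kind == "delete_terminal":
        return _remove_atoms(mol, [payload])
    if kind == "add_f":
        return _attach(mol, payload, "[*]F", rng)
    if kind == "ester_to_hydrazide":
        acyl, _, ester_o, rprime = payload
        o_atom = rw.GetAtomWithIdx(ester_o)
        o_atom.SetAtomicNum(7)
        o_atom.SetNumExplicitHs(0)
        o_atom.SetNoImplicit(False)
        rw.RemoveBond(ester_o, rprime)
        n2 = rw.AddAtom(Chem.Atom(7))
        rw.AddBond(ester_o, n2, BondType.SINGLE)
        rw.AddBond(n2, rprime, BondType.SINGLE)
        return _finalize(rw)
    if kind == "hydrazide_to_ester":
        acyl, _, n1, n2, rprime = payload
        rw.GetAtomWithIdx(n1).SetAtomicNum(8)
        rw.GetAtomWithIdx(n1).SetNumExplicitHs(0)
        rw.GetAtomWithIdx(n1).SetNoImplicit(False)
        rw.RemoveBond(n1, n2)
        rw.RemoveBond(n2, rprime)
        rw.AddBond(n1, rprime, BondType.SINGLE)
        rw.RemoveAtom(n2)
        return _finalize(rw)
    return None


def _sites_insert_ch2(mol, ctx):
    out = []
    for b in mol.GetBonds():
        if b.IsInRing() or b.GetBondType() != BondType.SINGLE:
            continue
        if (b.GetBeginAtom().GetAtomicNum() > 1
                and b.GetEndAtom().GetAtomicNum() > 1):
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
    return out


def _apply_insert_ch2(mol, site, ctx, rng):
    a, b = site
    rw = Chem.RWMol(mol)
    if rw.GetBondBetweenAtoms(a, b) is None:
        return None
    rw.RemoveBond(a, b)
    c = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(a, c, BondType.SINGLE)
    rw.AddBond(c, b, BondType.SINGLE)
    return _finalize(rw)


def _sites_delete_ch2(mol, ctx):
    out = []
    for a in mol.GetAtoms():
        if a.GetAtomicNum() != 6 or a.IsInRing() or a.GetIsAromatic():
            continue
        if a.GetDegree() != 2 or a.GetTotalNumHs() != 2:
            continue
        if any(b.GetBondType() != BondType.SINGLE for b in a.GetBonds()):
            continue
        n1, n2 = [n.GetIdx() for n in a.GetNeighbors()]
        if mol.GetBondBetweenAtoms(n1, n2) is not None:
            continue
        out.append((a.GetIdx(), n1, n2))
    return out


def _apply_delete_ch2(mol, site, ctx, rng):
    idx, n1, n2 = site
    rw = Chem.RWMol(mol)
    rw.RemoveAtom(idx)
    shift = lambda i: i - 1 if i > idx else i
    rw.AddBond(shift(n1), shift(n2), BondType.SINGLE)
    return _finalize(rw)


_SITES: dict[str, Callable] = {
    "ADD_FRAG": _sites_add_frag,
    "DELETE_RING_SIDECHAIN": _sites_delete_ring_sidechain,
    "REPLACE_SIDECHAIN_CORE": _sites_replace_sidechain_core,
    "REDUCE_CHIRALITY": _sites_reduce_chirality,
    "DECORATE_AROM": _sites_decorate_arom,
    "DELETE_DECOR_AROM": _sites_delete_decor_arom,
    "REPLACE_DECOR_AROM": _sites_replace_decor_arom,
    "HALOGENATE": _sites_halogenate,
    "DEHALOGENATE": _sites_dehalogenate,
    "NITRATE": _sites_nitrate,
    "SULFONYLATE": _sites_sulfonylate,
    "ADD_POLAR_GROUP": _sites_add_polar,
    "ADD_LIPOPHILIC_GROUP": _sites_add_lipophilic,
    "SWAP_POLAR_LIPOPHILIC": _sites_swap_polar_lipo,
    "METHYLATE_AMINE": _sites_methylate_amine,
    "DEMETHYLATE_AMINE": _sites_demethylate_amine,
    "SATURATE_RING": _sites_saturate_ring,
    "AROMATIZE_RING": _sites_aromatize_ring,
    "EXPAND_RING": _sites_expand_ring,
    "CONTRACT_RING": _sites_contract_ring,
    "FUSE_RINGS": _sites_fuse_rings,
    "CYCLIZE_CHAIN": _sites_cyclize_chain,
    "OXIDIZE_ALCOHOL": _sites_oxidize_alcohol,
    "REDUCE_CARBONYL": _sites_reduce_carbonyl,
    "HYDROLYZE_ESTER": _sites_hydrolyze_ester,
    "FORM_ESTER": _sites_carboxyl,
    "FORM_AMIDE": _sites_carboxyl,
    "ACETYLATE_PHENOL": _sites_acetylate_phenol,
    "DEACETYLATE": _sites_deacetylate,
    "BIOISOSTERIC_SWAP": _sites_bioisosteric,
    "INSERT_CH2_LINKER": _sites_insert_ch2,
    "DELETE_CH2_LINKER": _sites_delete_ch2,
}

_APPLY: dict[str, Callable] = {
    "ADD_FRAG": _apply_add_frag,
    "DELETE_RING_SIDECHAIN": _apply_delete_ring_sidechain,
    "REPLACE_SIDECHAIN_CORE": _apply_replace_sidechain_core,
    "DECORATE_AROM": _apply_decorate_arom,
    "DELETE_DECOR_AROM": _apply_delete_decor_arom,
    "REPLACE_DECOR_AROM": _apply_replace_decor_arom,
    "HALOGENATE": _apply_halogenate,
    "DEHALOGENATE": _apply_dehalogenate,
    "NITRATE": _apply_nitrate,
    "SULFONYLATE": _apply_sulfonylate,
    "ADD_POLAR_GROUP": _apply_add_polar,
    "ADD_LIPOPHILIC_GROUP": _apply_add_lipophilic,
    "SWAP_POLAR_LIPOPHILIC": _apply_swap_polar_lipo,
    "METHYLATE_AMINE": _apply_methylate_amine,
    "DEMETHYLATE_AMINE": _apply_demethylate_amine,
    "SATURATE_RING": _apply_saturate_ring,
    "AROMATIZE_RING": _apply_aromatize_ring,
    "EXPAND_RING": _apply_expand_ring,
    "CONTRACT_RING": _apply_contract_ring,
    "FUSE_RINGS": _apply_fuse_rings,
    "CYCLIZE_CHAIN": _apply_cyclize_chain,
    "OXIDIZE_ALCOHOL": _apply_oxidize_alcohol,
    "REDUCE_CARBONYL": _apply_reduce_carbonyl,
    "HYDROLYZE_ESTER": _apply_hydrolyze_ester,
    "FORM_ESTER": _apply_form_ester,
    "FORM_AMIDE": _apply_form_amide,
    "ACETYLATE_PHENOL": _apply_acetylate_phenol,
    "DEACETYLATE": _apply_deacetylate,
    "BIOISOSTERIC_SWAP": _apply_bioisosteric,
    "INSERT_CH2_LINKER": _apply_insert_ch2,
    "DELETE_CH2_LINKER": _apply_delete_ch2,
}


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _charge_ok(action_name: str, before: Chem.Mol, after: Chem.Mol) -> bool:
    delta = Chem.GetFormalCharge(after) - Chem.GetFormalCharge(before)
    if action_name == "METHYLATE_AMINE":
        return delta in (0, 1)
    return delta == 0


def apply_action(mol: MoleculeRecord, action_id: int, rng_seed: int,
                 core_fragment: Optional[str] = None,
                 decoration: Optional[str] = None,
                 library: Optional[FragmentLibrary] = None) -> TransformResult:
    """Apply one transformation action with uniform site selection.

    Up to 20 independent site/variant draws are attempted; a structure that
    never survives sanitization yields ``failed_validity``, while the
    absence of any matching site yields ``inapplicable``.
    """
    if not 0 <= action_id < N_ACTIONS:
        raise ValueError(f"unknown action_id {action_id}")
    spec = ACTION_CATALOG[action_id]
    if spec.name == "STOP":
        raise ValueError("STOP is handled by the episode loop, not as a graph edit")
    if spec.needs_core_fragment and core_fragment is None and library is None:
        raise ValueError(f"{spec.name} requires a core fragment")
    if spec.needs_decoration and decoration is None:
        raise ValueError(f"{spec.name} requires a decoration token")
    if decoration is not None and decoration not in DECORATIONS:
        raise ValueError(f"unknown decoration {decoration!r}")

    rng = np.random.default_rng(rng_seed)
    if spec.name == "REDUCE_CHIRALITY":
        return reduce_chirality(mol, rng_seed)

    m = mol.to_mol()
    ctx = ActionContext(core_fragment=core_fragment, decoration=decoration,
                        library=library)
    sites = _SITES[spec.name](m, ctx)
    if not sites:
        return TransformResult(status="inapplicable", attempts=0)
    apply_fn = _APPLY[spec.name]
    for attempt in range(1, MAX_ATTEMPTS + 1):
        site = sites[int(rng.integers(len(sites)))]
        new = apply_fn(m, site, ctx, rng)
        if new is not None and _charge_ok(spec.name, m, new):
            params = {}
            if core_fragment is not None:
                params["core_fragment"] = core_fragment
            if decoration is not None:
                params["decoration"] = decoration
            record = MoleculeRecord.from_mol(
                new, lineage=mol.with_step(spec.name, params))
            return TransformResult(status="success", molecule=record,
                                   attempts=attempt)
    return TransformResult(status="failed_validity", attempts=MAX_ATTEMPTS)


def _chirality_candidates(mol: Chem.Mol):
    """Edit candidates grouped by strategy, in the order they are attempted.

    A: remove a small side chain (<=12 heavy atoms; <=3 if the center is
    ring-embedded) from a stereocenter; B: sp3->sp2 unsaturation in C-O,
    C-N, C-C patterns at the center; C: prune an exocyclic branch from a
    quaternary stereocenter with no hydrogen; fallback: ring contraction or
    aromatization of a ring holding a stereocenter.
    """
    centers = [idx for idx, _ in Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False)]
    center_set = set(centers)
    strat_a, strat_b, strat_c, fallback = [], [], [], []
    for c in centers:
        atom = mol.GetAtomWithIdx(c)
        cap = 3 if atom.IsInRing() else 12
        for first, branch in _acyclic_branches(mol, c, cap):
            strat_a.append(("delete", branch))
        if atom.GetTotalNumHs() >= 1:
            for nbr in atom.GetNeighbors():
                if nbr.GetAtomicNum() not in (6, 7, 8):
                    continue
                bond = mol.GetBondBetweenAtoms(c, nbr.GetIdx())
                if bond.GetBondType() != BondType.SINGLE or bond.GetIsAromatic():
                    continue
                if nbr.GetTotalNumHs() >= 1:
                    strat_b.append(("unsaturate", (c, nbr.GetIdx())))
        if atom.GetTotalNumHs() == 0 and atom.GetDegree() == 4 and atom.IsInRing():
            for first, branch in _acyclic_branches(mol, c, 12):
                strat_c.append(("delete", branch))
    for site in _sites_contract_ring(mol, None):
        fallback.append(("contract", site))
    for ring in _sites_aromatize_ring(mol, None):
        fallback.append(("aromatize", ring))
    del center_set  # strict-decrease check filters non-stereocenter edits
    return [strat_a, strat_b, strat_c, fallback]


def reduce_chirality(mol: MoleculeRecord, rng_seed: int) -> TransformResult:
    """Eliminate one stereocenter via hierarchical structural edits.

    Success requires the stereocenter count to strictly decrease.
    """
    if mol.stereocenter_count < 1:
        return TransformResult(status="inapplicable", attempts=0)
    m = mol.to_mol()
    n_before = count_stereocenters(m)
    rng = np.random.default_rng(rng_seed)
    attempts = 0
    for group in _chirality_candidates(m):
        if not group:
            continue
        order = rng.permutation(len(group))
        for k in order:
            if attempts >= MAX_ATTEMPTS:
                return TransformResult(status="failed_validity",
                                       attempts=attempts)
            kind, payload = group[int(k)]
            attempts += 1
            if kind == "delete":
                new = _remove_atoms(m, payload)
            elif kind == "unsaturate":
                a, b = payload
                rw = Chem.RWMol(m)
                rw.GetBondBetweenAtoms(a, b).SetBondType(BondType.DOUBLE)
                for idx in (a, b):
                    at = rw.GetAtomWithIdx(idx)
                    at.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
                    at.SetNumExplicitHs(max(0, at.GetTotalNumHs() - 1))
                    at.SetNoImplicit(False)
                new = _finalize(rw)
            elif kind == "contract":
                new = _apply_contract_ring(m, payload, None, rng)
            else:
                new = _apply_aromatize_ring(m, payload, None, rng)
            if new is None or not _charge_ok("REDUCE_CHIRALITY", m, new):
                continue
            if count_stereocenters(new) < n_before:
                record = MoleculeRecord.from_mol(
                    new, lineage=mol.with_step("REDUCE_CHIRALITY", {}))
                return TransformResult(status="success", molecule=record,
                                       attempts=attempts)
    status = "failed_validity" if attempts else "inapplicable"
    return TransformResult(status=status, attempts=attempts)


def enumerate_applicable(mol: MoleculeRecord) -> set[int]:
    """Every non-STOP action whose structural precondition matches a site."""
    m = mol.to_mol()
    ctx = ActionContext()
    out = set()
    for spec in ACTION_CATALOG:
        if spec.name == "STOP":
            continue
        if _SITES[spec.name](m, ctx):
            out.add(spec.action_id)
    return out


def random_mutate(mol: MoleculeRecord, n_steps: int, rng_seed: int,
                  library: Optional[FragmentLibrary] = None) -> MoleculeRecord:
    """Apply ``n_steps`` uniformly drawn non-STOP actions (random baseline).

    Fragment and decoration parameters are drawn uniformly where required;
    inapplicable or failed draws leave the state unchanged and consume the
    step.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    state = mol
    non_stop = [a for a in ACTION_CATALOG if a.name != "STOP"]
    for _ in range(n_steps):
        spec = non_stop[int(rng.integers(len(non_stop)))]
        core = None
        deco = None
        if spec.needs_core_fragment:
            if library is not None and len(library) > 0:
                core = library.sample_fragment(int(rng.integers(len(library))))
            else:
                core = DEFAULT_CORE_FRAGMENTS[
                    int(rng.integers(len(DEFAULT_CORE_FRAGMENTS)))]
        if spec.needs_decoration:
            deco = DECORATIONS[int(rng.integers(len(DECORATIONS)))]
        result = apply_action(state, spec.action_id,
                              int(rng.integers(2 ** 31)),
                              core_fragment=core, decoration=deco,
                              library=library)
        if result.status == "success":
            state = result.molecule
    return state
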