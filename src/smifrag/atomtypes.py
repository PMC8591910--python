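"""Atom typing, extended bond typing, and cleavable-bond selection.

An attachment atom is identified by the 4-tuple

    (pi electrons, element symbol, heavy-neighbor count, formal charge)

in the spirit of classic atom-pair descriptors.  A bond between atoms
``u`` and ``v`` is typed by the *directed* triple
``(type(u), bond order, type(v))``; direction matters because the two
ends of an asymmetric bond are chemically distinct attachment
environments.  Stereochemistry never enters an atom type.

Cleavable bonds are the single, acyclic bonds between two heavy atoms
that are neither attached to a specified stereocenter nor involved in
cis/trans isomerism — cutting one and re-forming it reconstructs the
molecule exactly, which is what makes string-level reassembly sound.
"""

from __future__ import annotations

from typing import NamedTuple

from rdkit import Chem

__all__ = [
    "AtomType",
    "BondType",
    "CleavableBond",
    "BOND_ORDER_NAMES",
    "type_atom",
    "type_bond",
    "find_cleavable_bonds",
]


class AtomType(NamedTuple):
    """Attachment-environment fingerprint of a heavy atom."""

    pi_electrons: int
    element: str
    heavy_degree: int
    formal_charge: int


class BondType(NamedTuple):
    """Directed extended bond type: ``(A, single, B) != (B, single, A)``."""

    left: AtomType
    bond_order: str  # 'single' | 'double' | 'triple' | 'aromatic'
    right: AtomType


class CleavableBond(NamedTuple):
    atom_index_u: int
    atom_index_v: int
    bond_type: BondType


BOND_ORDER_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

# Per-bond pi-electron contribution to each end, for non-aromatic atoms.
_PI_PER_BOND = {
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
}


def _pi_electrons(atom: Chem.Atom) -> int:
    # Aromatic atoms contribute one pi electron by convention; otherwise
    # each double bond adds 1 and each triple bond adds 2.
    if atom.GetIsAromatic():
        return 1
    return sum(_PI_PER_BOND.get(b.GetBondType(), 0) for b in atom.GetBonds())


def type_atom(mol: Chem.Mol, atom_index: int) -> AtomType:
    """Type the heavy atom at *atom_index*.

    Raises
    ------
    IndexError
        If *atom_index* does not address an atom of *mol*.
    ValueError
        If the addressed atom is a hydrogen.
    """
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    if atom.GetAtomicNum() == 1:
        raise ValueError("hydrogen atoms are not typed")
    heavy = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
    return AtomType(
        pi_electrons=_pi_electrons(atom),
        element=atom.GetSymbol(),
        heavy_degree=heavy,
        formal_charge=atom.GetFormalCharge(),
    )


def type_bond(mol: Chem.Mol, bond_index: int) -> BondType:
    """Directed type of the bond at *bond_index* (begin atom on the left)."""
    if not 0 <= bond_index < mol.GetNumBonds():
        raise IndexError(f"bond index {bond_index} out of range")
    bond = mol.GetBondWithIdx(bond_index)
    u, v = bond.GetBeginAtom(), bond.GetEndAtom()
    if u.GetAtomicNum() == 1 or v.GetAtomicNum() == 1:
        raise ValueError("bonds to hydrogen are not typed")
    return BondType(
        left=type_atom(mol, u.GetIdx()),
        bond_order=BOND_ORDER_NAMES[bond.GetBondType()],
        right=type_atom(mol, v.GetIdx()),
    )


_CHIRAL_TAGS = (
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
_DIR_MARKS = (Chem.BondDir.ENDUPRIGHT, Chem.BondDir.ENDDOWNRIGHT)


def find_cleavable_bonds(mol: Chem.Mol) -> list[CleavableBond]:
    """All bonds eligible for cleavage, in the molecule's bond order.

    A bond qualifies when it is single, not in a ring, joins two heavy
    atoms, neither endpoint carries a specified tetrahedral chirality
    tag, and the bond carries no cis/trans direction mark.  Unspecified
    or implicit stereocenters do not block cleavage.
    """
    out: list[CleavableBond] = []
    for bond in mol.GetBonds():
        if bond.GetBondType() is not Chem.BondType.SINGLE:
            continue
        if bond.IsInRing():
            continue
        u, v = bond.GetBeginAtom(), bond.GetEndAtom()
        if u.GetAtomicNum() <= 1 or v.GetAtomicNum() <= 1:
            continue
        if u.GetChiralTag() in _CHIRAL_TAGS or v.GetChiralTag() in _CHIRAL_TAGS:
            continue
        if bond.GetBondDir() in _DIR_MARKS:
            continue
        out.append(
            CleavableBond(
                atom_index_u=u.GetIdx(),
                atom_index_v=v.GetIdx(),
                bond_type=type_bond(mol, bond.GetIdx()),
            )
        )
    return out
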