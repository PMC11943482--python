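"""SMILES parsing via RDKit, mapped onto the package graph model.

RDKit performs syntax parsing, valence checking and aromaticity perception;
the resulting heavy-atom skeleton is converted to a
:class:`~flavopred.graph.MolecularGraph` with aromatic bonds kept as a
distinct order and atom types recomputed by the package's own vocabulary
rules, so structures entering through SMILES and through KCF-style records
are typed identically. Stereochemistry and isotopes are discarded.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit import RDLogger

from .graph import MolecularGraph
from .vocab import assign_atom_types

RDLogger.DisableLog("rdApp.error")  # we raise our own parse errors

_BOND_MAP = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    pass


def parse_linear(smiles: str, name: str = "") -> MolecularGraph:
    """Parse a SMILES string into a typed molecular graph.

    Raises
    ------
    SmilesParseError
        If RDKit rejects the string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    g = MolecularGraph(name=name)
    for atom in mol.GetAtoms():
        g.add_atom(
            atom.GetSymbol(),
            charge=atom.GetFormalCharge(),
            index=atom.GetIdx() + 1,
        )
    for bond in mol.GetBonds():
        if bond.GetIsAromatic():
            order = "aromatic"
        else:
            order = _BOND_MAP.get(bond.GetBondType())
            if order is None:
                raise SmilesParseError(
                    f"unsupported bond type {bond.GetBondType()} in {smiles!r}"
                )
        g.add_bond(bond.GetBeginAtomIdx() + 1, bond.GetEndAtomIdx() + 1, order)
    assign_atom_types(g)
    return g


#: Alias matching the field's usual verb for this operation.
parse_smiles = parse_linear
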