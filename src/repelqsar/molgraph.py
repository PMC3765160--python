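"""Hydrogen-suppressed molecular graphs with atom environment labels.

The 2D QSAR machinery in this package works on labeled molecular graphs:
atoms are vertices carrying element / hydrogen-count / ring / hybridization
state, bonds are edges carrying an order (aromatic is treated as its own
order, rings are not kekulized).  Hydrogens are implicit and kept as counts;
descriptor code that needs explicit hydrogens (partial charges) expands them
internally from the underlying RDKit molecule.

Environment labels follow the field's conventional shorthand, e.g.
``C(-CH3)`` for a terminal methyl carbon, ``O_sp2`` for a carbonyl oxygen,
``O(-OH)`` for a hydroxyl oxygen.  Labels are a deterministic function of
the atom's element, hybridization, attached hydrogen count and first-shell
neighbors; environments outside the calibrated tables fall back to a
generic per-element label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Tuple, Union

import networkx as nx
from rdkit import Chem

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "parse_smiles",
    "environment_label",
    "to_networkx",
    "write_graphml",
    "graphs_isomorphic",
]

BondOrder = Union[int, str]  #: 1, 2, 3 or "ar"

_HYB_CLASS = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a hydrogen-suppressed molecular graph."""

    element: str
    formal_charge: int
    n_h: int
    aromatic: bool
    in_ring: bool
    hybridization: str  # "sp", "sp2", "sp3" or "other"


@dataclass(frozen=True)
class Bond:
    """A bond between two heavy atoms; ``order`` is 1, 2, 3 or ``"ar"``."""

    i: int
    j: int
    order: BondOrder


@dataclass
class MolecularGraph:
    """Heavy-atom graph of a single-fragment molecule.

    Wraps the sanitized RDKit molecule it was built from so that descriptor
    code can expand hydrogens when needed; all topology consumers use only
    ``atoms`` / ``bonds``.
    """

    id: str
    atoms: List[Atom]
    bonds: List[Bond]
    mol: Chem.Mol = field(repr=False, default=None)
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> List[Tuple[int, BondOrder]]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append((b.j, b.order))
            elif b.j == idx:
                out.append((b.i, b.order))
        return out

    def degree(self, idx: int) -> int:
        return len(self.neighbors(idx))


def _bond_order(bond: Chem.Bond) -> BondOrder:
    if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
        return "ar"
    return {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
    }[bond.GetBondType()]


def parse_smiles(smiles: str, id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Aromaticity and rings are perceived by RDKit; stereo annotations are
    retained on the wrapped molecule but ignored by the 2D method.

    Raises
    ------
    ValueError
        If the SMILES cannot be parsed or encodes a multi-fragment species.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES for compound {id!r}: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(f"compound {id!r} is not a single fragment: {smiles!r}")
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_h=a.GetTotalNumHs(),
            aromatic=a.GetIsAromatic(),
            in_ring=a.IsInRing(),
            hybridization=_HYB_CLASS.get(a.GetHybridization(), "other"),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_order(b))
        for b in mol.GetBonds()
    ]
    return MolecularGraph(id=id, atoms=atoms, bonds=bonds, mol=mol, smiles=smiles)


def environment_label(graph: MolecularGraph, atom_index: int) -> str:
    """Deterministic first-shell environment label for one atom.

    The calibrated descriptor tables are keyed by these labels; anything
    not covered resolves to a generic label (``"N(generic)"`` etc.) which
    the tables treat as default-valued.
    """
    a = graph.atoms[atom_index]
    nbrs = graph.neighbors(atom_index)
    el = a.element
    if el == "C":
        if a.hybridization == "sp":
            return "C(≡CH)" if a.n_h == 1 else "C_sp"
        if a.aromatic:
            return "C_ar"
        if a.hybridization == "sp2":
            return "C_sp2"
        # sp3: a carbinol carbon outranks the plain CHn labels
        for j, order in nbrs:
            nb = graph.atoms[j]
            if nb.element == "O" and nb.n_h >= 1 and order == 1 and a.n_h >= 1:
                return "C(-CH2-OH)"
        if a.n_h == 3:
            return "C(-CH3)"
        if a.n_h == 2:
            return "C(-CH2-)"
        if a.n_h == 1:
            return "C(-CH<)"
        return "C(quat)"
    if el == "O":
        if a.formal_charge == -1:
            return "O_minus"
        if any(order == 2 for _, order in nbrs) or a.hybridization == "sp2":
            return "O_sp2"
        if a.n_h >= 1:
            return "O(-OH)"
        return "O(-O-)"
    if el == "N":
        for j, _ in nbrs:
            if graph.atoms[j].element == "C" and any(
                o == 2 and graph.atoms[k].element == "O"
                for k, o in graph.neighbors(j)
            ):
                return "N(amide)"
        return "N(generic)"
    if el in ("F", "Cl", "Br", "I"):
        return el
    return f"{el}(generic)"


def to_networkx(graph: MolecularGraph) -> nx.Graph:
    """Annotated undirected graph for debugging / GraphML export."""
    g = nx.Graph(compound=graph.id, smiles=graph.smiles)
    for i, a in enumerate(graph.atoms):
        g.add_node(
            i,
            element=a.element,
            n_h=a.n_h,
            aromatic=int(a.aromatic),
            in_ring=int(a.in_ring),
            hybridization=a.hybridization,
            label=environment_label(graph, i),
        )
    for b in graph.bonds:
        g.add_edge(b.i, b.j, order=str(b.order))
    return g


def write_graphml(graph: MolecularGraph, path: str) -> None:
    nx.write_graphml(to_networkx(graph), path)


def graphs_isomorphic(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    """Element/bond-order preserving isomorphism test (small graphs only)."""
    return nx.is_isomorphic(
        to_networkx(g1),
        to_networkx(g2),
        node_match=lambda a, b: a["element"] == b["element"] and a["n_h"] == b["n_h"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )


def parse_all(pairs: Iterable[Tuple[str, str]]) -> List[MolecularGraph]:
    """Parse ``(smiles, id)`` pairs, raising on the first failure."""
    return [parse_smiles(s, i) for s, i in pairs]
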