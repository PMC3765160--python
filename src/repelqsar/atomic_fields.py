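"""Local atomic descriptor fields.

Five per-atom fields drive the 2D QSAR model:

``Q``
    Gasteiger–Marsili PEOE partial charges (units of e).  Computed by an
    in-package implementation of the iterative partial equalization of
    orbital electronegativity, run with explicit hydrogens for 8 damped
    iterations (damping factor 1/2 per cycle); the reported value is the
    heavy atom's own charge.  Hydrogen charges can optionally be folded
    onto their heavy atom, but the calibrated anchor values are
    heavy-atom charges, so folding is off by default.
``vdW``
    Van der Waals radius (Å), an element lookup with environment
    overrides (a carbonyl oxygen is 1.5 Å, any carbon 1.7 Å).
``Lipo``
    Atom-additive lipophilicity contribution.  Calibrated environments
    come from an editable table; everything else falls back to Crippen
    logP atomic contributions.
``HBa`` / ``HBd``
    Hydrogen-bond acceptor / donor scores from the same table; the scale
    is anchored by four published values, extensions are flagged in the
    table's provenance column, unlisted environments score 0.
``EN``
    Pauling electronegativity of the element; available but excluded
    from the default field set.

Unoccupied supergraph positions ("vacancies") are filled with fixed
per-field values: charge 0, radius 0, lipophilicity −0.25, HB scores 0.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen

from .molgraph import MolecularGraph, environment_label

__all__ = [
    "FIELD_NAMES",
    "VACANCY_VALUES",
    "AtomicFieldVector",
    "gasteiger_charges",
    "vdw_radius",
    "atomic_lipophilicity",
    "hbond_scales",
    "electronegativity",
    "compute_fields",
    "load_field_table",
]

log = logging.getLogger(__name__)

FIELD_NAMES = ("Q", "vdW", "Lipo", "HBa", "HBd")

#: Fill values for supergraph positions a molecule does not occupy.
VACANCY_VALUES: Dict[str, float] = {
    "Q": 0.0,
    "vdW": 0.0,
    "Lipo": -0.25,
    "HBa": 0.0,
    "HBd": 0.0,
    "EN": 0.0,
}

# ---------------------------------------------------------------------------
# PEOE (Gasteiger-Marsili) charges
# ---------------------------------------------------------------------------

# (a, b, c) of chi(q) = a + b q + c q^2, by element and hybridization class.
_PEOE_PARAMS: Dict[Tuple[str, str], Tuple[float, float, float]] = {
    ("H", "any"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("S", "sp3"): (10.14, 9.13, 1.38),
    ("F", "any"): (14.66, 13.85, 2.31),
    ("Cl", "any"): (11.00, 9.69, 1.35),
    ("Br", "any"): (10.08, 8.47, 1.16),
    ("I", "any"): (9.90, 7.96, 0.96),
}
_H_CHI_PLUS = 20.02  # special cation electronegativity for hydrogen
_SINGLE_CLASS = ("H", "F", "Cl", "Br", "I")


def _peoe_class(atom: Chem.Atom) -> Tuple[str, str]:
    el = atom.GetSymbol()
    if el in _SINGLE_CLASS:
        return el, "any"
    if atom.GetIsAromatic():
        return el, "sp2"
    hyb = {
        Chem.HybridizationType.SP: "sp",
        Chem.HybridizationType.SP2: "sp2",
        Chem.HybridizationType.SP3: "sp3",
    }.get(atom.GetHybridization(), "sp3")
    return el, hyb


def gasteiger_charges(
    graph: MolecularGraph,
    n_iter: int = 8,
    damping: float = 0.5,
    fold_hydrogens: bool = False,
) -> np.ndarray:
    """Heavy-atom PEOE partial charges.

    Runs the iterative partial equalization of orbital electronegativity
    with explicit hydrogens; per cycle *k* the transferred charge is damped
    by ``damping**k``.  Charges sum to the molecular formal charge.

    Parameters
    ----------
    fold_hydrogens:
        If true, each hydrogen's charge is summed onto its heavy atom.
        Off by default: the calibrated anchor values are reproduced in
        sign and ordering by the bare heavy-atom charges, while folding
        collapses the alkyl-carbon charges to ~0.

    Raises
    ------
    ValueError
        If the molecule contains an element without PEOE parameters.
    """
    mol = Chem.AddHs(graph.mol)
    atoms = list(mol.GetAtoms())
    params = []
    for a in atoms:
        key = _peoe_class(a)
        if key not in _PEOE_PARAMS:
            raise ValueError(
                f"no PEOE parameters for element {key[0]} ({key[1]}) "
                f"in compound {graph.id!r}"
            )
        params.append(_PEOE_PARAMS[key])
    chi_plus = [
        _H_CHI_PLUS if a.GetSymbol() == "H" else sum(p)
        for a, p in zip(atoms, params)
    ]
    q = np.array([float(a.GetFormalCharge()) for a in atoms])
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    for k in range(1, n_iter + 1):
        damp = damping**k
        chi = np.array([a + b * qi + c * qi * qi for (a, b, c), qi in zip(params, q)])
        dq = np.zeros_like(q)
        for i, j in bonds:
            if chi[i] > chi[j]:
                d = (chi[i] - chi[j]) / chi_plus[j] * damp
                dq[i] -= d
                dq[j] += d
            elif chi[j] > chi[i]:
                d = (chi[j] - chi[i]) / chi_plus[i] * damp
                dq[j] -= d
                dq[i] += d
        q += dq
    heavy = np.array(
        [q[a.GetIdx()] for a in atoms if a.GetSymbol() != "H"], dtype=float
    )
    if fold_hydrogens:
        for a in atoms:
            if a.GetSymbol() == "H":
                nbr = a.GetNeighbors()[0].GetIdx()
                heavy[nbr] += q[a.GetIdx()]
    return heavy


# ---------------------------------------------------------------------------
# Lookup-table fields
# ---------------------------------------------------------------------------

_VDW_BY_ELEMENT = {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

_PAULING_EN = {
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "S": 2.58,
    "F": 3.98,
    "Cl": 3.16,
    "Br": 2.96,
    "I": 2.66,
}


@dataclass
class _FieldTable:
    values: Dict[Tuple[str, str], float] = field(default_factory=dict)
    provenance: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def get(self, label: str, fld: str):
        return self.values.get((label, fld))


_table_cache: _FieldTable = None


def load_field_table(path: str = None) -> _FieldTable:
    """Load the (environment_label, field, value) calibration table.

    The packaged table reproduces every published anchor value exactly and
    marks implementation-defined extensions in its provenance column; users
    can point ``path`` at an edited copy to re-parameterize.
    """
    global _table_cache
    if path is None and _table_cache is not None:
        return _table_cache
    tab = _FieldTable()
    if path is None:
        src = resources.files("repelqsar.data").joinpath("field_tables.csv")
        text = src.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    for row in csv.DictReader(text.splitlines()):
        key = (row["environment_label"], row["field"])
        tab.values[key] = float(row["value"])
        tab.provenance[key] = row.get("provenance", "")
    if path is None:
        _table_cache = tab
    return tab


def vdw_radius(label: str, element: str) -> float:
    """Van der Waals radius (Å) for an environment label.

    Environment overrides (``O_sp2`` → 1.5) take precedence over the
    per-element defaults; a vacancy has radius 0 by convention.
    """
    v = load_field_table().get(label, "vdW")
    if v is not None:
        return v
    if element not in _VDW_BY_ELEMENT:
        raise ValueError(f"no van der Waals radius for element {element!r}")
    return _VDW_BY_ELEMENT[element]


def _crippen_contribs(graph: MolecularGraph) -> List[float]:
    return [c[0] for c in Crippen.rdMolDescriptors._CalcCrippenContribs(graph.mol)]


def atomic_lipophilicity(graph: MolecularGraph) -> np.ndarray:
    """Per-atom lipophilicity contributions.

    Calibrated environments come from the packaged table (exact to the
    published values); anything else falls back to the Crippen logP atomic
    contribution, with fallbacks counted at debug level.
    """
    tab = load_field_table()
    crippen = None
    out = np.zeros(graph.n_atoms)
    n_fallback = 0
    for i in range(graph.n_atoms):
        label = environment_label(graph, i)
        v = tab.get(label, "Lipo")
        if v is None:
            if crippen is None:
                crippen = _crippen_contribs(graph)
            out[i] = crippen[i]
            n_fallback += 1
        else:
            out[i] = v
    if n_fallback:
        log.debug(
            "%s: %d/%d atoms use Crippen lipophilicity fallback",
            graph.id, n_fallback, graph.n_atoms,
        )
    return out


def hbond_scales(graph: MolecularGraph) -> Tuple[np.ndarray, np.ndarray]:
    """Per-atom (HBa, HBd) hydrogen-bond scores; non-polar default is 0."""
    tab = load_field_table()
    hba = np.zeros(graph.n_atoms)
    hbd = np.zeros(graph.n_atoms)
    for i in range(graph.n_atoms):
        label = environment_label(graph, i)
        a = tab.get(label, "HBa")
        if a is not None:
            hba[i] = a
        d = tab.get(label, "HBd")
        if d is not None:
            # donors must actually carry a proton
            if graph.atoms[i].element == "C" or graph.atoms[i].n_h >= 1:
                hbd[i] = d
    return hba, hbd


def electronegativity(graph: MolecularGraph) -> np.ndarray:
    """Pauling electronegativity per atom (optional field)."""
    return np.array([_PAULING_EN.get(a.element, math.nan) for a in graph.atoms])


@dataclass
class AtomicFieldVector:
    """Per-atom field values for one compound."""

    compound_id: str
    values: Dict[str, np.ndarray]

    def at(self, field_name: str, atom_index: int) -> float:
        return float(self.values[field_name][atom_index])


def compute_fields(
    graph: MolecularGraph, fields: Tuple[str, ...] = FIELD_NAMES
) -> AtomicFieldVector:
    """Compute the requested local descriptor fields for every atom."""
    vals: Dict[str, np.ndarray] = {}
    for f in fields:
        if f == "Q":
            vals["Q"] = gasteiger_charges(graph)
        elif f == "vdW":
            vals["vdW"] = np.array(
                [
                    vdw_radius(environment_label(graph, i), a.element)
                    for i, a in enumerate(graph.atoms)
                ]
            )
        elif f == "Lipo":
            vals["Lipo"] = atomic_lipophilicity(graph)
        elif f == "HBa":
            vals["HBa"], hbd = hbond_scales(graph)
            if "HBd" in fields:
                vals["HBd"] = hbd
        elif f == "HBd":
            if "HBd" not in vals:
                _, vals["HBd"] = hbond_scales(graph)
        elif f == "EN":
            vals["EN"] = electronegativity(graph)
        else:
            raise ValueError(f"unknown field name {f!r}")
    bad = [f for f, v in vals.items() if not np.all(np.isfinite(v))]
    if bad:
        raise ValueError(f"non-finite field values for {graph.id!r}: {bad}")
    return AtomicFieldVector(compound_id=graph.id, values=vals)
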