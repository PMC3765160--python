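"""Molecular supergraph construction and the atom-descriptor matrix.

The molecular supergraph (MSG) is a union graph built by iteratively
superimposing the training molecules' 2D graphs: each molecule is embedded
into the current MSG by a maximum-overlap common-subgraph search, and its
unmatched atoms/bonds are appended as new vertices/edges.  Every training
molecule therefore embeds injectively into the final MSG, and each MSG
position becomes a set of descriptor columns (one per molecular field).
Positions a molecule does not occupy are filled with fixed vacancy values.

The overlap search is a connected backtracking maximum-common-edge-subgraph
(McGregor-style) with deterministic tie-breaking; it is exact on small
graphs and degrades to the best embedding found within a node budget on
large ones (logged).  Match options control whether atoms must agree on
element, bonds on order, and whether ring atoms may map onto chain atoms.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field as dfield
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .atomic_fields import FIELD_NAMES, VACANCY_VALUES, AtomicFieldVector
from .molgraph import MolecularGraph, environment_label

__all__ = [
    "MsgOptions",
    "Supergraph",
    "AtomMapping",
    "superimpose",
    "embed",
    "build_msg",
    "descriptor_matrix",
    "order_sensitivity",
    "msg_to_networkx",
    "write_msg_graphml",
    "msg_to_json",
    "msg_from_json",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MsgOptions:
    """Match options, fixed for a whole MSG build.

    ``allow_cyclic_acyclic`` lets ring atoms map onto chain atoms (needed
    when a series mixes cyclohexyl/phenyl with open chains).  With
    ``match_element`` on, atoms must agree on element.  ``match_level``
    sets how strictly atom types must agree: ``"element"`` (any same-element
    atoms may merge), ``"class"`` (element + hybridization) or ``"label"``
    (full first-shell environment label, with ring carbons pooled so an
    aromatic CH can still superimpose on a cyclohexyl CH2).  Label-level
    matching is the default: it keeps congeneric molecules on the same
    vertices, which the looser levels measurably fail to do.  With
    ``match_bond_order`` off, a single bond may map onto an aromatic or
    double MSG edge.  ``forced_pairs`` may pin
    ``(compound_id, atom_index) -> vertex_id`` superpositions.
    """

    allow_cyclic_acyclic: bool = True
    match_element: bool = True
    match_level: str = "label"  # "element" | "class" | "label"
    match_bond_order: bool = False
    forced_pairs: tuple = ()
    node_budget: int = 300_000


@dataclass
class _Vertex:
    vid: int
    element: str
    in_ring: bool
    labels: Counter = dfield(default_factory=Counter)
    classes: set = dfield(default_factory=set)
    match_keys: set = dfield(default_factory=set)
    occupancy: int = 0


@dataclass(frozen=True)
class AtomMapping:
    """Injective, edge-preserving map of one compound's atoms to MSG vertices."""

    compound_id: str
    atom_to_vertex: Tuple[Tuple[int, int], ...]  # sorted (atom_index, vertex_id)

    def as_dict(self) -> Dict[int, int]:
        return dict(self.atom_to_vertex)


class Supergraph:
    """Union graph accumulated over a training set."""

    def __init__(self, options: MsgOptions = MsgOptions()):
        self.options = options
        self.vertices: Dict[int, _Vertex] = {}
        self.edges: Dict[FrozenSet[int], Counter] = {}
        self.adj: Dict[int, set] = {}
        self._next_id = 0

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def vertex_ids(self) -> List[int]:
        return sorted(self.vertices)

    def has_edge(self, u: int, v: int) -> bool:
        return frozenset((u, v)) in self.edges

    def neighbors(self, vid: int) -> List[int]:
        return sorted(self.adj.get(vid, ()))

    def _add_vertex(self, element: str, in_ring: bool) -> int:
        vid = self._next_id
        self._next_id += 1
        self.vertices[vid] = _Vertex(vid=vid, element=element, in_ring=in_ring)
        self.adj[vid] = set()
        return vid

    def _add_edge(self, u: int, v: int, order) -> None:
        self.edges.setdefault(frozenset((u, v)), Counter())[order] += 1
        self.adj[u].add(v)
        self.adj[v].add(u)


def _atom_compatible(sg: Supergraph, graph: MolecularGraph, a: int, v: int) -> bool:
    opt = sg.options
    atom = graph.atoms[a]
    vert = sg.vertices[v]
    if opt.match_element and atom.element != vert.element:
        return False
    if opt.match_level == "label":
        if _match_key(graph, a) not in vert.match_keys:
            return False
    elif opt.match_level == "class":
        if _atom_class(atom) not in vert.classes:
            return False
    if not opt.allow_cyclic_acyclic and atom.in_ring != vert.in_ring:
        return False
    return True


def _atom_class(atom) -> str:
    """Coarse matching class: element + hybridization (aromatic separate)."""
    if atom.element in ("F", "Cl", "Br", "I"):
        return atom.element
    if atom.aromatic:
        return f"{atom.element}_ar"
    return f"{atom.element}_{atom.hybridization}"


def _match_key(graph, a) -> str:
    """Type key for label-level matching.  Ring carbons are pooled (an
    aromatic CH may superimpose on a cyclohexyl CH2); everything else
    matches on the full environment label."""
    atom = graph.atoms[a]
    if atom.element == "C" and atom.in_ring:
        return "C_ring"
    return environment_label(graph, a)


def _bond_compatible(sg: Supergraph, order, edge_key: FrozenSet[int]) -> bool:
    if edge_key not in sg.edges:
        return False
    if not sg.options.match_bond_order:
        return True
    return order in sg.edges[edge_key]


class _SearchState:
    __slots__ = ("best_map", "best_score", "nodes", "budget", "exhausted")

    def __init__(self, budget: int):
        self.best_map: Dict[int, int] = {}
        self.best_score = (-1, -1, -1, ())
        self.nodes = 0
        self.budget = budget
        self.exhausted = False


def _score(sg: Supergraph, graph: MolecularGraph, mapping: Dict[int, int],
           matched_bonds: int) -> tuple:
    label_hits = 0
    for a, v in mapping.items():
        if environment_label(graph, a) in sg.vertices[v].labels:
            label_hits += 1
    lex = tuple(mapping[a] for a in sorted(mapping))
    # negated lex so that "greater" score prefers the lexicographically
    # smallest vertex-id sequence
    return (matched_bonds, label_hits, len(mapping), tuple(-x for x in lex))


def _extend(sg: Supergraph, graph: MolecularGraph, mapping: Dict[int, int],
            used: set, skipped: set, matched_bonds: int, st: _SearchState) -> None:
    st.nodes += 1
    if st.nodes > st.budget:
        st.exhausted = True
        return
    # cheap primary comparison first; full (label/lex) score only on ties
    primary = (matched_bonds,)
    if primary >= st.best_score[:1]:
        score = _score(sg, graph, mapping, matched_bonds)
        if score > st.best_score:
            st.best_score = score
            st.best_map = dict(mapping)
    # frontier: unmapped, unskipped atoms adjacent to the mapped set
    frontier = []
    for a in range(graph.n_atoms):
        if a in mapping or a in skipped:
            continue
        back = [(b, o) for b, o in graph.neighbors(a) if b in mapping]
        if back:
            frontier.append((-len(back), a, back))
    if not frontier:
        return
    # upper bound: every not-yet-decided bond could still be matched
    n_bonds = len(graph.bonds)
    decided = sum(
        1 for b in graph.bonds
        if (b.i in mapping or b.i in skipped) and (b.j in mapping or b.j in skipped)
    )
    if matched_bonds + (n_bonds - decided) < st.best_score[0]:
        return
    frontier.sort()
    _, a, back = frontier[0]
    # candidate vertices: unmapped, compatible, adjacent to >=1 mapped image
    cands = []
    for b, order in back:
        vb = mapping[b]
        for v in sg.neighbors(vb):
            if v in used or not _atom_compatible(sg, graph, a, v):
                continue
            hits = sum(
                1
                for bb, oo in back
                if _bond_compatible(sg, oo, frozenset((v, mapping[bb])))
            )
            if hits == 0:
                continue
            cands.append((-hits, v))
    lab_a = environment_label(graph, a)
    seen = set()
    for neg_hits, lab_miss, v in sorted(
        (nh, 0 if lab_a in sg.vertices[v].labels else 1, v) for nh, v in cands
    ):
        if v in seen:
            continue
        seen.add(v)
        mapping[a] = v
        used.add(v)
        _extend(sg, graph, mapping, used, skipped, matched_bonds - neg_hits, st)
        del mapping[a]
        used.discard(v)
        if st.exhausted:
            return
    # branch: leave this atom unmatched
    skipped.add(a)
    _extend(sg, graph, mapping, used, skipped, matched_bonds, st)
    skipped.discard(a)


def _best_embedding(
    sg: Supergraph, graph: MolecularGraph, budget: int,
    forced: Optional[Dict[int, int]] = None,
) -> Tuple[Dict[int, int], int, bool]:
    """Maximum-overlap common-subgraph embedding of ``graph`` into ``sg``.

    Returns ``(mapping, matched_bonds, exact)`` where ``exact`` is false
    when the node budget was exhausted (best-found embedding returned).
    """
    st = _SearchState(budget)
    if forced:
        st.best_map = {}
        mapping = dict(forced)
        used = set(mapping.values())
        matched = sum(
            1 for b in graph.bonds
            if b.i in mapping and b.j in mapping
            and _bond_compatible(sg, b.order, frozenset((mapping[b.i], mapping[b.j])))
        )
        _extend(sg, graph, mapping, used, set(), matched, st)
        return st.best_map, st.best_score[0], not st.exhausted
    # deterministic seed order: label-matching pairs first (keeps congeneric
    # molecules on the same vertices), then rarest element, then indices
    elem_freq = Counter(v.element for v in sg.vertices.values())
    seeds = []
    for a in range(graph.n_atoms):
        lab = environment_label(graph, a)
        for v in sg.vertex_ids():
            if not _atom_compatible(sg, graph, a, v):
                continue
            pref = (
                0 if lab in sg.vertices[v].labels else 1,
                elem_freq[graph.atoms[a].element],
                a,
                v,
            )
            seeds.append((pref, a, v))
    seeds.sort()
    per_seed = max(2000, budget // max(1, len(seeds)))
    for _, a, v in seeds:
        st.budget = min(budget, st.nodes + per_seed)
        st.exhausted = False
        _extend(sg, graph, {a: v}, {v}, set(), 0, st)
        if (
            st.best_score[0] >= len(graph.bonds)
            and st.best_score[1] >= graph.n_atoms
        ):
            break  # perfect embedding (all bonds and labels); cannot improve
    exact = st.nodes <= budget
    return st.best_map, max(st.best_score[0], 0), exact


def superimpose(
    sg: Supergraph, graph: MolecularGraph, extend: bool = True
) -> AtomMapping:
    """Superimpose one molecule onto the MSG.

    Finds the maximum-overlap embedding under the MSG's match options
    (ties broken deterministically: most matched bonds, then atoms, then
    label agreement, then lowest vertex-id sequence), then — when
    ``extend`` is true — appends unmatched atoms and bonds as new
    vertices/edges so the returned mapping is total.  With ``extend``
    false the MSG is left untouched and the mapping may be partial
    (used for prediction-time embedding of new molecules).
    """
    forced = {
        a: v
        for cid, a, v in sg.options.forced_pairs
        if cid == graph.id
    } or None
    if sg.n_vertices == 0:
        mapping: Dict[int, int] = {}
        exact = True
    else:
        mapping, _, exact = _best_embedding(
            sg, graph, sg.options.node_budget, forced
        )
        if not exact:
            log.info(
                "%s: overlap search hit node budget; best-found embedding used",
                graph.id,
            )
    if extend:
        for a in range(graph.n_atoms):
            if a not in mapping:
                at = graph.atoms[a]
                mapping[a] = sg._add_vertex(at.element, at.in_ring)
        for b in graph.bonds:
            key = frozenset((mapping[b.i], mapping[b.j]))
            if key not in sg.edges:
                sg._add_edge(mapping[b.i], mapping[b.j], b.order)
            else:
                sg.edges[key][b.order] += 1
        for a, v in mapping.items():
            sg.vertices[v].labels[environment_label(graph, a)] += 1
            sg.vertices[v].classes.add(_atom_class(graph.atoms[a]))
            sg.vertices[v].match_keys.add(_match_key(graph, a))
            sg.vertices[v].occupancy += 1
    atom_to_vertex = tuple(sorted(mapping.items()))
    _check_mapping(sg, graph, dict(atom_to_vertex), partial=not extend)
    return AtomMapping(compound_id=graph.id, atom_to_vertex=atom_to_vertex)


def embed(sg: Supergraph, graph: MolecularGraph) -> AtomMapping:
    """Embed without extending the MSG (prediction-time superposition)."""
    return superimpose(sg, graph, extend=False)


def _check_mapping(sg: Supergraph, graph: MolecularGraph,
                   mapping: Dict[int, int], partial: bool) -> None:
    values = list(mapping.values())
    if len(set(values)) != len(values):
        raise AssertionError(f"{graph.id}: mapping is not injective")
    if not partial:
        for b in graph.bonds:
            if not sg.has_edge(mapping[b.i], mapping[b.j]):
                raise AssertionError(
                    f"{graph.id}: bond {b.i}-{b.j} not on an MSG edge"
                )


def _similarity_chain(graphs: Sequence[MolecularGraph]) -> List[MolecularGraph]:
    """Progressive insertion order: largest molecule first, then repeatedly
    the molecule most similar (Morgan-fingerprint Tanimoto) to any already
    inserted one.  Keeps congeneric molecules adjacent in the fold so they
    inherit each other's vertex placements; fully deterministic."""
    from rdkit.Chem import rdFingerprintGenerator
    from rdkit import DataStructs

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
    items = sorted(graphs, key=lambda g: (-g.n_atoms, g.id))
    fps = {g.id: gen.GetFingerprint(g.mol) for g in items}
    ordered = [items[0]]
    remaining = items[1:]
    best_sim = {g.id: DataStructs.TanimotoSimilarity(fps[g.id], fps[items[0].id])
                for g in remaining}
    while remaining:
        remaining.sort(key=lambda g: (-best_sim[g.id], -g.n_atoms, g.id))
        nxt = remaining.pop(0)
        ordered.append(nxt)
        for g in remaining:
            s = DataStructs.TanimotoSimilarity(fps[g.id], fps[nxt.id])
            if s > best_sim[g.id]:
                best_sim[g.id] = s
    return ordered


def build_msg(
    graphs: Sequence[MolecularGraph],
    options: MsgOptions = MsgOptions(),
    seed_order: str = "similarity",
) -> Tuple[Supergraph, List[AtomMapping]]:
    """Fold the training molecules into an MSG and return final mappings.

    ``seed_order="similarity"`` (default) inserts the largest molecule
    first and then repeatedly the one most similar to an already inserted
    molecule, so congeners inherit each other's placements;
    ``"size"`` inserts by descending atom count then id and ``"given"``
    preserves the input order.  After the fold every molecule
    is re-embedded into the final MSG; if the re-embedding is not total
    (budget exhaustion) the fold-time mapping — which stays valid because
    vertices and edges are only ever appended — is kept.
    """
    if not graphs:
        raise ValueError("build_msg needs at least one molecule")
    if seed_order == "similarity":
        ordered = _similarity_chain(graphs)
    elif seed_order == "size":
        ordered = sorted(graphs, key=lambda g: (-g.n_atoms, g.id))
    elif seed_order == "given":
        ordered = list(graphs)
    else:
        raise ValueError(f"unknown seed_order {seed_order!r}")
    # deduplicate by id (idempotence under repeated inputs)
    seen = set()
    unique = []
    for g in ordered:
        if g.id not in seen:
            seen.add(g.id)
            unique.append(g)
    sg = Supergraph(options)
    fold_maps: Dict[str, AtomMapping] = {}
    for g in unique:
        fold_maps[g.id] = superimpose(sg, g, extend=True)
    mappings: List[AtomMapping] = []
    by_id = {g.id: g for g in unique}
    for g in unique:
        re_map = superimpose(sg, g, extend=False)
        m = fold_maps[g.id]
        if len(re_map.atom_to_vertex) == g.n_atoms:
            try:
                # a usable re-embedding must also lie on MSG edges
                _check_mapping(sg, g, re_map.as_dict(), partial=False)
                m = re_map
            except AssertionError:
                pass
        _check_mapping(sg, g, m.as_dict(), partial=False)
        mappings.append(m)
    # recompute occupancy / label multisets from the final mappings
    for v in sg.vertices.values():
        v.labels = Counter()
        v.occupancy = 0
    for m in mappings:
        g = by_id[m.compound_id]
        for a, v in m.as_dict().items():
            sg.vertices[v].labels[environment_label(g, a)] += 1
            sg.vertices[v].classes.add(_atom_class(g.atoms[a]))
            sg.vertices[v].match_keys.add(_match_key(g, a))
            sg.vertices[v].occupancy += 1
    return sg, mappings


def descriptor_matrix(
    sg: Supergraph,
    mappings: Sequence[AtomMapping],
    field_vectors: Dict[str, AtomicFieldVector],
    fields: Tuple[str, ...] = FIELD_NAMES,
    vacancy: Dict[str, float] = VACANCY_VALUES,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Vacancy-filled compounds × (MSG position × field) matrix.

    Columns are ordered vertex-id major, field minor, and named
    ``"v{vertex:03d}|{field}"``.  Returns ``(matrix, vacancy_mask)``
    with the mask true where a cell holds a vacancy fill.
    """
    vids = sg.vertex_ids()
    cols = [f"v{v:03d}|{f}" for v in vids for f in fields]
    rows = []
    mask_rows = []
    index = []
    for m in mappings:
        fv = field_vectors[m.compound_id]
        v_to_a = {v: a for a, v in m.atom_to_vertex}
        row = np.empty(len(cols))
        mask = np.zeros(len(cols), dtype=bool)
        k = 0
        for v in vids:
            a = v_to_a.get(v)
            for f in fields:
                if a is None:
                    row[k] = vacancy[f]
                    mask[k] = True
                else:
                    row[k] = fv.at(f, a)
                k += 1
        rows.append(row)
        mask_rows.append(mask)
        index.append(m.compound_id)
    X = pd.DataFrame(rows, index=index, columns=cols)
    M = pd.DataFrame(mask_rows, index=index, columns=cols)
    return X, M


def order_sensitivity(
    graphs: Sequence[MolecularGraph],
    options: MsgOptions = MsgOptions(),
    n_shuffles: int = 10,
    seed: int = 0,
) -> Dict[str, object]:
    """Measure how input order affects MSG size (it is not hidden).

    Builds the MSG from ``n_shuffles`` shuffled input orders and reports
    the vertex-count spread alongside the canonical build's size.
    """
    rng = np.random.default_rng(seed)
    sizes = []
    for _ in range(n_shuffles):
        perm = list(rng.permutation(len(graphs)))
        sg, _ = build_msg([graphs[i] for i in perm], options, seed_order="given")
        sizes.append(sg.n_vertices)
    canonical, _ = build_msg(graphs, options, seed_order="similarity")
    return {
        "canonical_size": canonical.n_vertices,
        "shuffled_sizes": sizes,
        "spread": max(sizes) - min(sizes) if sizes else 0,
    }


def msg_to_networkx(sg: Supergraph) -> nx.Graph:
    g = nx.Graph()
    for vid in sg.vertex_ids():
        v = sg.vertices[vid]
        g.add_node(
            vid,
            element=v.element,
            occupancy=v.occupancy,
            labels=";".join(f"{l}:{c}" for l, c in sorted(v.labels.items())),
        )
    for e, orders in sg.edges.items():
        u, v = sorted(e)
        g.add_edge(u, v, orders=";".join(str(o) for o in sorted(orders, key=str)))
    return g


def write_msg_graphml(sg: Supergraph, path: str) -> None:
    nx.write_graphml(msg_to_networkx(sg), path)


def msg_to_json(sg: Supergraph) -> str:
    """Serialize an MSG (vertices, edges, match state, options) to JSON."""
    import json

    return json.dumps(
        {
            "options": {
                "allow_cyclic_acyclic": sg.options.allow_cyclic_acyclic,
                "match_element": sg.options.match_element,
                "match_level": sg.options.match_level,
                "match_bond_order": sg.options.match_bond_order,
                "node_budget": sg.options.node_budget,
            },
            "vertices": [
                {
                    "vid": v.vid,
                    "element": v.element,
                    "in_ring": v.in_ring,
                    "labels": dict(v.labels),
                    "classes": sorted(v.classes),
                    "match_keys": sorted(v.match_keys),
                    "occupancy": v.occupancy,
                }
                for v in (sg.vertices[i] for i in sg.vertex_ids())
            ],
            "edges": [
                {"u": min(e), "v": max(e), "orders": {str(k): c for k, c in cnt.items()}}
                for e, cnt in sorted(sg.edges.items(), key=lambda kv: sorted(kv[0]))
            ],
        },
        indent=1,
    )


def msg_from_json(text: str) -> Supergraph:
    import json

    d = json.loads(text)
    sg = Supergraph(MsgOptions(**d["options"]))
    for v in d["vertices"]:
        vid = sg._add_vertex(v["element"], v["in_ring"])
        assert vid == v["vid"], "vertex ids must be dense and ordered"
        vert = sg.vertices[vid]
        vert.labels = Counter(v["labels"])
        vert.classes = set(v["classes"])
        vert.match_keys = set(v["match_keys"])
        vert.occupancy = v["occupancy"]
    for e in d["edges"]:
        for o, c in e["orders"].items():
            order = int(o) if o.isdigit() else o
            key = frozenset((e["u"], e["v"]))
            sg.edges.setdefault(key, Counter())[order] = c
            sg.adj[e["u"]].add(e["v"])
            sg.adj[e["v"]].add(e["u"])
    return sg
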