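"""Supergraph construction: superposition, invariants, descriptor matrix."""

import itertools

import numpy as np
import pytest

from repelqsar.atomic_fields import FIELD_NAMES, VACANCY_VALUES, compute_fields
from repelqsar.molgraph import parse_smiles
from repelqsar.supergraph import (
    MsgOptions,
    Supergraph,
    build_msg,
    descriptor_matrix,
    embed,
    msg_from_json,
    msg_to_json,
    order_sensitivity,
    superimpose,
)

ELEMENT_OPTS = MsgOptions(match_level="element")


def brute_force_max_overlap(sg: Supergraph, graph) -> int:
    """Independent exhaustive oracle: maximum number of molecule bonds that
    can lie on MSG edges under an injective, element-compatible mapping.

    Enumerates every injective assignment of every atom subset — viable
    only for graphs of a handful of atoms.
    """
    vids = sg.vertex_ids()
    best = 0
    atoms = range(graph.n_atoms)
    for size in range(graph.n_atoms, 0, -1):
        for subset in itertools.combinations(atoms, size):
            for perm in itertools.permutations(vids, size):
                mapping = dict(zip(subset, perm))
                if any(
                    sg.vertices[v].element != graph.atoms[a].element
                    for a, v in mapping.items()
                ):
                    continue
                matched = sum(
                    1
                    for b in graph.bonds
                    if b.i in mapping
                    and b.j in mapping
                    and sg.has_edge(mapping[b.i], mapping[b.j])
                )
                best = max(best, matched)
    return best


class TestSuperimpose:
    def test_onto_empty_msg_reproduces_the_molecule(self):
        g = parse_smiles("CCO", "ethanol")
        sg = Supergraph(ELEMENT_OPTS)
        m = superimpose(sg, g)
        assert sg.n_vertices == 3 and sg.n_edges == 2
        assert len(m.atom_to_vertex) == 3

    def test_idempotent_for_contained_molecule(self):
        sg = Supergraph(ELEMENT_OPTS)
        superimpose(sg, parse_smiles("CCO", "a"))
        before = (sg.n_vertices, sg.n_edges)
        m = superimpose(sg, parse_smiles("CCO", "b"))
        assert (sg.n_vertices, sg.n_edges) == before
        assert len(m.atom_to_vertex) == 3

    def test_ethanol_plus_ethylamine_gives_four_vertices(self):
        """With element matching the carbon chains align and O/N stay apart;
        the 4-vertex result was verified by exhaustive enumeration."""
        sg = Supergraph(ELEMENT_OPTS)
        superimpose(sg, parse_smiles("CCO", "ethanol"))
        superimpose(sg, parse_smiles("CCN", "ethylamine"))
        assert sg.n_vertices == 4

    def test_overlap_matches_exhaustive_oracle_on_small_graphs(self):
        pairs = [
            ("CCO", "CCN"),
            ("CCO", "CC(C)O"),
            ("C1CCCCC1", "CCCCCC"),
            ("CC(=O)NC", "CC(=O)OC"),
            ("c1ccccc1", "C1CCCCC1"),
        ]
        for s1, s2 in pairs:
            sg = Supergraph(ELEMENT_OPTS)
            superimpose(sg, parse_smiles(s1, "seed"))
            g2 = parse_smiles(s2, "probe")
            mapping = embed(sg, g2)
            mdict = mapping.as_dict()
            matched = sum(
                1
                for b in g2.bonds
                if b.i in mdict and b.j in mdict
                and sg.has_edge(mdict[b.i], mdict[b.j])
            )
            assert matched == brute_force_max_overlap(sg, g2), (s1, s2)

    def test_disjoint_union_when_nothing_matches(self):
        sg = Supergraph(ELEMENT_OPTS)
        superimpose(sg, parse_smiles("CC", "ethane"))
        superimpose(sg, parse_smiles("O=O", "dioxygen"))
        assert sg.n_vertices == 4


class TestBuildMsg:
    def test_single_molecule_msg_is_that_molecule(self):
        g = parse_smiles("CCN(CC)C(=O)c1cccc(C)c1", "DEET")
        sg, maps = build_msg([g])
        assert sg.n_vertices == g.n_atoms
        assert sg.n_edges == len(g.bonds)

    def test_duplicated_inputs_are_deduplicated(self, training_graphs):
        subset = training_graphs[:6]
        sg1, m1 = build_msg(subset)
        sg2, m2 = build_msg(subset + subset)
        assert sg1.n_vertices == sg2.n_vertices
        assert len(m2) == len(subset)

    def test_build_is_deterministic(self, training_graphs):
        subset = training_graphs[:12]
        sg1, m1 = build_msg(subset)
        sg2, m2 = build_msg(subset)
        assert sg1.n_vertices == sg2.n_vertices
        assert [m.atom_to_vertex for m in m1] == [m.atom_to_vertex for m in m2]

    def test_all_training_molecules_embed_injectively(
        self, msg_and_mappings, training_graphs
    ):
        sg, maps = msg_and_mappings
        by_id = {g.id: g for g in training_graphs}
        assert len(maps) == 71
        for m in maps:
            g = by_id[m.compound_id]
            mapping = m.as_dict()
            assert len(mapping) == g.n_atoms  # total
            assert len(set(mapping.values())) == g.n_atoms  # injective
            for b in g.bonds:  # edge-preserving
                assert sg.has_edge(mapping[b.i], mapping[b.j])

    def test_msg_size_bounds(self, msg_and_mappings, training_graphs):
        sg, _ = msg_and_mappings
        sizes = [g.n_atoms for g in training_graphs]
        assert max(sizes) <= sg.n_vertices <= sum(sizes)

    def test_amide_core_superposition_of_representative_structures(
        self, msg_and_mappings, training_graphs
    ):
        """The N-ethyl-toluamide and the cyclohexyl amide land their amide
        C=O and N on the same supergraph positions."""
        sg, maps = msg_and_mappings
        by_id = {g.id: g for g in training_graphs}
        cores = {}
        for cid in ("DEET", "5m", "5a"):
            g = by_id[cid]
            mapping = dict(next(m for m in maps if m.compound_id == cid).atom_to_vertex)
            o = next(i for i, a in enumerate(g.atoms) if a.element == "O")
            n = next(i for i, a in enumerate(g.atoms) if a.element == "N")
            cores[cid] = (mapping[o], mapping[n])
        assert cores["DEET"] == cores["5m"] == cores["5a"]

    def test_order_sensitivity_reports_spread(self, training_graphs):
        rep = order_sensitivity(training_graphs[:8], n_shuffles=3, seed=0)
        assert rep["canonical_size"] >= max(g.n_atoms for g in training_graphs[:8])
        assert len(rep["shuffled_sizes"]) == 3
        assert rep["spread"] >= 0

    def test_json_round_trip(self, msg_and_mappings):
        sg, _ = msg_and_mappings
        back = msg_from_json(msg_to_json(sg))
        assert back.n_vertices == sg.n_vertices
        assert back.n_edges == sg.n_edges
        assert back.options == sg.options
        vid = sg.vertex_ids()[0]
        assert back.vertices[vid].labels == sg.vertices[vid].labels


class TestDescriptorMatrix:
    def test_shape_and_vacancy_fills(self, msg_and_mappings, field_vectors,
                                      training_matrix):
        sg, maps = msg_and_mappings
        X, mask = training_matrix
        assert X.shape == (71, sg.n_vertices * len(FIELD_NAMES))
        lipo_cols = [c for c in X.columns if c.endswith("|Lipo")]
        vals = X[lipo_cols].to_numpy()[mask[lipo_cols].to_numpy()]
        assert np.all(vals == VACANCY_VALUES["Lipo"])
        q_cols = [c for c in X.columns if c.endswith("|Q")]
        assert np.all(X[q_cols].to_numpy()[mask[q_cols].to_numpy()] == 0.0)

    def test_single_molecule_matrix_has_no_vacancies(self):
        g = parse_smiles("CCO", "ethanol")
        sg, maps = build_msg([g])
        fv = {"ethanol": compute_fields(g)}
        X, mask = descriptor_matrix(sg, maps, fv)
        assert X.shape == (1, 3 * len(FIELD_NAMES))
        assert not mask.to_numpy().any()

    def test_occupied_cells_carry_atom_values(self):
        g = parse_smiles("CCO", "ethanol")
        sg, maps = build_msg([g])
        fv = {"ethanol": compute_fields(g)}
        X, _ = descriptor_matrix(sg, maps, fv)
        mapping = maps[0].as_dict()
        v_of_o = mapping[2]  # the hydroxyl oxygen's vertex
        assert X.loc["ethanol", f"v{v_of_o:03d}|HBd"] == 1.2
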