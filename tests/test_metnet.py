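import itertools

import networkx as nx
import numpy as np
import pytest

from metnetpca.metnet import (
    CompoundGraph,
    NetworkParseError,
    carbon_filter,
    collapse_compartments,
    extract_subnetwork,
    lightest_path,
    load_network,
    path_distance_matrix,
    remove_side_compounds,
)
from metnetpca.synthetic import NetworkDesign, generate_toy_network


def brute_force_lightest(graph: CompoundGraph, source: str, target: str):
    """Minimum sum of squared degrees over all simple paths (oracle)."""
    if source == target:
        return 0.0
    deg = dict(graph.g.degree())
    best = None
    for path in nx.all_simple_paths(graph.g, source, target):
        cost = sum(deg[n] ** 2 for n in path)
        if best is None or cost < best:
            best = cost
    return best


def random_compound_graph(rng, n_nodes, p_edge=0.4):
    g = CompoundGraph()
    nodes = [f"n{i}" for i in range(n_nodes)]
    for n in nodes:
        g.add_metabolite(n)
    r = 0
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < p_edge:
            g.add_reaction_edge(u, v, f"r{r}", carbon_transfer=True)
            r += 1
    return g


class TestLoadNetwork:
    def write_toy(self, tmp_path, edge_rows):
        nodes = tmp_path / "nodes.tsv"
        nodes.write_text(
            "id\tname\tpathways\tside_compound\n"
            "A\tmetA\tpw1\t0\nB\tmetB\tpw1\t0\nC\tmetC\tpw2\t0\n"
        )
        edges = tmp_path / "edges.tsv"
        edges.write_text("u\tv\treaction\tcarbon_transfer\n" + "\n".join(edge_rows) + "\n")
        return nodes, edges

    def test_toy_file_counts(self, tmp_path):
        nodes, edges = self.write_toy(tmp_path, ["A\tB\tr1\t1", "B\tC\tr2\t1"])
        g = load_network(nodes, edges)
        assert g.n_nodes == 3 and g.n_edges == 2 and g.n_reactions == 2
        assert g.node_pathways("A") == {"pw1"}

    def test_dangling_edge_endpoint_rejected_with_record(self, tmp_path):
        nodes, edges = self.write_toy(tmp_path, ["A\tZ\tr1\t1"])
        with pytest.raises(NetworkParseError, match="record 0"):
            load_network(nodes, edges)

    def test_missing_carbon_flag_rejected(self, tmp_path):
        nodes, edges = self.write_toy(tmp_path, ["A\tB\tr1\t"])
        with pytest.raises(NetworkParseError, match="carbon_transfer"):
            load_network(nodes, edges)

    def test_generator_counts_match_declared(self):
        toy = generate_toy_network(NetworkDesign(seed=11))
        assert toy.graph.n_nodes == toy.declared_nodes
        assert toy.graph.n_edges == toy.declared_edges

    def test_round_trip_through_tables(self, tmp_path):
        toy = generate_toy_network(NetworkDesign(seed=5))
        toy.graph.export_tables(tmp_path)
        back = load_network(tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
        assert back.n_nodes == toy.graph.n_nodes
        assert back.n_edges == toy.graph.n_edges
        assert sorted(back.g.nodes) == sorted(toy.graph.g.nodes)


class TestLoadSbml:
    SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="toy">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="glc_c" name="glucose" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="g6p_c" name="glucose-6-phosphate" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="f6p_c" name="fructose-6-phosphate" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="HEX" reversible="false" fast="false">
        <listOfReactants><speciesReference species="glc_c" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="g6p_c" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
      <reaction id="PGI" reversible="true" fast="false">
        <listOfReactants><speciesReference species="g6p_c" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="f6p_c" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

    def test_species_become_nodes_and_substrate_product_pairs_edges(self, tmp_path):
        pytest.importorskip("libsbml")
        from metnetpca.metnet import load_sbml

        path = tmp_path / "toy.xml"
        path.write_text(self.SBML)
        g = load_sbml(path)
        assert sorted(g.g.nodes) == ["f6p_c", "g6p_c", "glc_c"]
        assert g.n_edges == 2
        assert g.g.edges["glc_c", "g6p_c"]["reactions"] == {"HEX"}


class TestCollapseCompartments:
    def test_cross_compartment_transport_becomes_single_node(self):
        g = CompoundGraph()
        g.add_metabolite("atp_c")
        g.add_metabolite("atp_m")
        g.add_reaction_edge("atp_c", "atp_m", "transport", carbon_transfer=True)
        out = collapse_compartments(g)
        assert sorted(out.g.nodes) == ["atp"]
        assert out.n_edges == 0  # transport self-loop deleted

    def test_no_suffixes_identity(self):
        g = CompoundGraph()
        for n in ("alanine", "pyruvate"):
            g.add_metabolite(n)
        g.add_reaction_edge("alanine", "pyruvate", "r1", carbon_transfer=True)
        out = collapse_compartments(g, suffix_pattern=r"_[a-z]$")
        assert sorted(out.g.nodes) == ["alanine", "pyruvate"]
        assert out.n_edges == 1

    def test_parallel_edges_merged_with_carbon_or(self):
        g = CompoundGraph()
        for n in ("glc_c", "g6p_c", "glc_m", "g6p_m"):
            g.add_metabolite(n)
        g.add_reaction_edge("glc_c", "g6p_c", "hex1", carbon_transfer=True)
        g.add_reaction_edge("glc_m", "g6p_m", "hex2", carbon_transfer=False)
        out = collapse_compartments(g)
        assert sorted(out.g.nodes) == ["g6p", "glc"]
        assert out.n_edges == 1
        assert out.g.edges["glc", "g6p"]["carbon_transfer"] is True
        assert out.g.edges["glc", "g6p"]["reactions"] == {"hex1", "hex2"}

    def test_pathway_memberships_unioned(self):
        g = CompoundGraph()
        g.add_metabolite("cit_c", pathways={"tca"})
        g.add_metabolite("cit_m", pathways={"tca", "glyoxylate"})
        out = collapse_compartments(g)
        assert out.node_pathways("cit") == {"tca", "glyoxylate"}

    def test_pattern_matching_whole_id_rejected(self):
        g = CompoundGraph()
        g.add_metabolite("_c")
        with pytest.raises(NetworkParseError, match="whole id"):
            collapse_compartments(g)


class TestRemoveSideCompounds:
    def test_hub_removal_isolates_star(self):
        g = CompoundGraph()
        g.add_metabolite("hub")
        for i in range(10):
            g.add_metabolite(f"leaf{i}")
            g.add_reaction_edge("hub", f"leaf{i}", f"r{i}", carbon_transfer=True)
        out = remove_side_compounds(g, ["hub"])
        assert out.n_nodes == 10 and out.n_edges == 0

    def test_empty_list_identity(self, chain_graph):
        out = remove_side_compounds(chain_graph, [])
        assert out.n_nodes == chain_graph.n_nodes
        assert out.n_edges == chain_graph.n_edges

    def test_unknown_ids_ignored_with_warning(self, chain_graph):
        with pytest.warns(UserWarning, match="ignored"):
            out = remove_side_compounds(chain_graph, ["A", "not_a_node"])
        assert "A" not in out.g

    def test_default_list_removes_flagged_hubs_lowering_max_degree(self):
        toy = generate_toy_network(NetworkDesign(seed=11))
        before = max(d for _, d in toy.graph.g.degree())
        out = remove_side_compounds(toy.graph)
        after = max(d for _, d in out.g.degree())
        assert after < before


class TestCarbonFilter:
    def test_all_true_identity(self, chain_graph):
        out = carbon_filter(chain_graph)
        assert out.n_edges == chain_graph.n_edges

    def test_all_false_gives_edgeless_graph_keeping_nodes(self):
        g = CompoundGraph()
        for n in "ABC":
            g.add_metabolite(n)
        g.add_reaction_edge("A", "B", "r1", carbon_transfer=False)
        g.add_reaction_edge("B", "C", "r2", carbon_transfer=False)
        out = carbon_filter(g)
        assert out.n_nodes == 3 and out.n_edges == 0

    def test_mixed_flags_keep_exactly_true_edges(self):
        rng = np.random.default_rng(2)
        g = CompoundGraph()
        nodes = [f"n{i}" for i in range(8)]
        for n in nodes:
            g.add_metabolite(n)
        n_true = 0
        for r, (u, v) in enumerate(itertools.combinations(nodes, 2)):
            if rng.random() < 0.5:
                flag = bool(rng.random() < 0.5)
                g.add_reaction_edge(u, v, f"r{r}", carbon_transfer=flag)
                n_true += flag
        assert carbon_filter(g).n_edges == n_true

    def test_commutes_with_side_compound_removal(self):
        toy = generate_toy_network(NetworkDesign(seed=3))
        a = carbon_filter(remove_side_compounds(toy.graph))
        b = remove_side_compounds(carbon_filter(toy.graph))
        assert sorted(a.g.nodes) == sorted(b.g.nodes)
        assert sorted(map(tuple, map(sorted, a.g.edges))) == sorted(map(tuple, map(sorted, b.g.edges)))


class TestLightestPath:
    def test_chain_cost_includes_endpoints(self, chain_graph):
        lp = lightest_path(chain_graph, "A", "C")
        assert lp.nodes == ["A", "B", "C"]
        assert lp.cost == 1 + 4 + 4  # degrees 1, 2, 2 on the 5-node chain
        assert lp.cost == brute_force_lightest(chain_graph, "A", "C")

    def test_self_distance_zero(self, chain_graph):
        lp = lightest_path(chain_graph, "B", "B")
        assert lp.cost == 0 and lp.nodes == ["B"]

    def test_hub_avoidance(self):
        # A-B-C and A-H-C with H also touching D and E: the route via B wins
        g = CompoundGraph()
        for n in "ABCHDE":
            g.add_metabolite(n)
        for u, v in [("A", "B"), ("B", "C"), ("A", "H"), ("H", "C"), ("H", "D"), ("H", "E")]:
            g.add_reaction_edge(u, v, f"r{u}{v}", carbon_transfer=True)
        lp = lightest_path(g, "A", "C")
        assert lp.nodes == ["A", "B", "C"]
        assert lp.cost == 4 + 4 + 4
        assert lp.cost == brute_force_lightest(g, "A", "C")

    def test_disconnected_pair_explicit_result(self):
        g = CompoundGraph()
        for n in "AB":
            g.add_metabolite(n)
        lp = lightest_path(g, "A", "B")
        assert not lp.connected and lp.cost == float("inf")

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(100):
            n = int(rng.integers(3, 9))
            g = random_compound_graph(rng, n, p_edge=float(rng.uniform(0.25, 0.7)))
            u, v = "n0", f"n{n - 1}"
            lp = lightest_path(g, u, v)
            oracle = brute_force_lightest(g, u, v)
            if oracle is None:
                assert not lp.connected
            else:
                assert lp.cost == oracle
            n_checked += 1
        assert n_checked == 100

    def test_degrees_recomputed_after_filtering(self):
        # B is a hub before filtering; removing its non-carbon spokes makes
        # the route through B optimal, which pre-filter degrees would forbid
        g = CompoundGraph()
        for n in ["S", "T", "B", "x1", "x2", "x3", "c1", "c2"]:
            g.add_metabolite(n)
        g.add_reaction_edge("S", "B", "r1", carbon_transfer=True)
        g.add_reaction_edge("B", "T", "r2", carbon_transfer=True)
        for i, x in enumerate(["x1", "x2", "x3"]):
            g.add_reaction_edge("B", x, f"spoke{i}", carbon_transfer=False)
        g.add_reaction_edge("S", "c1", "alt1", carbon_transfer=True)
        g.add_reaction_edge("c1", "c2", "alt2", carbon_transfer=True)
        g.add_reaction_edge("c2", "T", "alt3", carbon_transfer=True)
        before = lightest_path(g, "S", "T")
        assert before.nodes == ["S", "c1", "c2", "T"]  # avoids the degree-5 hub
        after = lightest_path(carbon_filter(g), "S", "T")
        assert after.nodes == ["S", "B", "T"]

    def test_triangle_like_bound_against_intermediates(self):
        rng = np.random.default_rng(7)
        g = random_compound_graph(rng, 7, p_edge=0.5)
        deg = dict(g.g.degree())
        nodes = sorted(g.g.nodes)
        for u, v, w in itertools.permutations(nodes, 3):
            d_uw = lightest_path(g, u, w)
            d_uv = lightest_path(g, u, v)
            d_vw = lightest_path(g, v, w)
            if d_uv.connected and d_vw.connected:
                assert d_uw.connected
                assert d_uw.cost <= d_uv.cost + d_vw.cost - deg[v] ** 2 + 1e-9


class TestExtractSubnetwork:
    def test_single_seed(self, chain_graph):
        sub = extract_subnetwork(chain_graph, {"C"})
        assert sorted(sub.g.nodes) == ["C"] and sub.n_edges == 0

    def test_two_adjacent_seeds(self, chain_graph):
        sub = extract_subnetwork(chain_graph, {"A", "B"})
        assert sorted(sub.g.nodes) == ["A", "B"] and sub.n_edges == 1

    def test_seeds_on_chain_recover_whole_chain(self, chain_graph):
        sub = extract_subnetwork(chain_graph, {"A", "C", "E"})
        assert sorted(sub.g.nodes) == list("ABCDE")
        assert sub.n_edges == 4
        assert sub.g.nodes["A"]["seed"] and sub.g.nodes["B"]["intermediate"]

    def test_empty_seed_set_rejected(self, chain_graph):
        with pytest.raises(ValueError):
            extract_subnetwork(chain_graph, set())


class TestPathDistanceMatrix:
    def test_chain_distances_monotone_in_separation(self, chain_graph):
        dm = path_distance_matrix(chain_graph, ["A", "B", "C", "D"])
        assert dm.matrix.loc["A", "B"] < dm.matrix.loc["A", "C"] < dm.matrix.loc["A", "D"]
        assert (dm.matrix.to_numpy().diagonal() == 0).all()
        np.testing.assert_array_equal(dm.matrix.to_numpy(), dm.matrix.to_numpy().T)

    def test_all_disconnected_uses_fallback_sentinel(self):
        g = CompoundGraph()
        for n in "ABC":
            g.add_metabolite(n)
        dm = path_distance_matrix(g, ["A", "B", "C"], fallback_sentinel=7.0)
        off = dm.matrix.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off == 7.0).all()
        assert len(dm.disconnected_pairs) == 3

    def test_sentinel_is_twice_max_finite(self):
        g = CompoundGraph()
        for n in "ABCD":
            g.add_metabolite(n)
        g.add_reaction_edge("A", "B", "r1", carbon_transfer=True)
        dm = path_distance_matrix(g, ["A", "B", "C"])
        finite = dm.matrix.loc["A", "B"]
        assert dm.sentinel == 2 * finite
        assert dm.matrix.loc["A", "C"] == dm.sentinel
        assert ("A", "C") in dm.disconnected_pairs

    def test_matches_brute_force_on_toy_graph(self):
        rng = np.random.default_rng(5)
        g = random_compound_graph(rng, 6, p_edge=0.5)
        subset = sorted(g.g.nodes)
        dm = path_distance_matrix(g, subset, fallback_sentinel=1.0)
        for i, u in enumerate(subset):
            for v in subset[i + 1:]:
                oracle = brute_force_lightest(g, u, v)
                if oracle is not None:
                    assert dm.matrix.loc[u, v] == oracle

    def test_subset_validation(self, chain_graph):
        with pytest.raises(ValueError):
            path_distance_matrix(chain_graph, ["A"])
        with pytest.raises(KeyError):
            path_distance_matrix(chain_graph, ["A", "zz"])
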