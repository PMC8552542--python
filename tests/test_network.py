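"""CDR3 similarity networks: edge construction, modularity, betweenness."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from allotrace import (
    analyze_sample,
    build_network,
    donor_reactive_network_summary,
    network_metrics,
    trim_inner,
)
from allotrace.donor_reactivity import DonorReactiveSet
from allotrace.network import ImmuneNetwork, _edges_distance_one
from allotrace.synthetic import generate_cdr3
from allotrace.types import Compartment

from conftest import make_meta, make_sample


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance; the independent oracle."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestTrimInner:
    @pytest.mark.parametrize(
        "seq,inner",
        [("CASSLGQETQYF", "SLGQET"), ("CASSSGF", "S"), ("CASSIRSSYEQYF", "SIRSSYE")],
    )
    def test_flanks_removed(self, seq, inner):
        assert trim_inner(seq) == inner

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="inner segment"):
            trim_inner("CASSF")

    def test_nonproductive_rejected(self):
        with pytest.raises(ValueError, match="non-productive"):
            trim_inner("CASS*GQETQYF")


def _aa_sample(aa_seqs, counts=None):
    n = len(aa_seqs)
    return make_sample(
        counts or [10] * n,
        aa_seqs=list(aa_seqs),
        nt_seqs=[f"TGT{i:06d}" for i in range(n)],
    )


class TestBuildNetwork:
    def test_single_substitution_linked(self):
        net = build_network(_aa_sample(["CASSLGQETQYF", "CASSLGQESQYF"]))
        assert net.n_edges == 1

    def test_distance_two_not_linked(self):
        # inner segments SLGQET vs SLGQ differ by two deletions
        net = build_network(_aa_sample(["CASSLGQETQYF", "CASSLGQQYF"]))
        assert net.n_edges == 0

    def test_identical_inner_segments_not_linked(self):
        # flank-only difference: inner distance 0, no edge by default
        net = build_network(_aa_sample(["CASSLGQETQYF", "AASSLGQETQYW"]))
        assert net.n_nodes == 2 and net.n_edges == 0

    def test_short_sequences_excluded_and_counted(self):
        net = build_network(_aa_sample(["CASSF", "CASSLGQETQYF"]))
        assert net.n_nodes == 1
        assert net.n_excluded_short == 1

    def test_convergent_amino_acids_merged(self):
        sample = make_sample(
            [6, 4],
            aa_seqs=["CASSLGQETQYF", "CASSLGQETQYF"],
            nt_seqs=["TGTAAA", "TGTAAG"],  # two nucleotide variants, one aa node
        )
        net = build_network(sample)
        assert net.n_nodes == 1
        assert net.nodes["frequency"].iloc[0] == pytest.approx(1.0)

    def test_single_indel_linked(self):
        net = build_network(_aa_sample(["CASSLGQETQYF", "CASSLGQETAQYF"]))
        assert net.n_edges == 1

    @pytest.mark.parametrize("n", [100, 200])
    def test_edge_set_equals_bruteforce_oracle(self, n):
        rng = np.random.default_rng(n)
        seqs = []
        seen = set()
        while len(seqs) < n:
            _, aa = generate_cdr3(rng, length_mean=11, length_sd=1.0)
            if aa not in seen:
                seen.add(aa)
                seqs.append(aa)
        # plant mutated pairs so the expected edge set is non-trivial
        for i in range(0, n // 2, 5):
            _, variant = generate_cdr3(rng, family_seed=seqs[i])
            if variant not in seen:
                seen.add(variant)
                seqs[n - 1 - i] = variant
        net = build_network(_aa_sample(seqs, counts=list(range(1, len(seqs) + 1))))
        segments = dict(zip(net.nodes["sequence"], net.nodes["inner"]))
        expected = set()
        nodes = sorted(segments)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                if levenshtein_dp(segments[u], segments[v]) == 1:
                    expected.add(frozenset((u, v)))
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected
        assert expected  # the oracle actually saw some edges


class TestNetworkMetrics:
    def _net_from_graph(self, graph) -> ImmuneNetwork:
        import pandas as pd

        nodes = pd.DataFrame(
            {
                "sequence": list(graph.nodes),
                "inner": list(graph.nodes),
                "frequency": [1 / graph.number_of_nodes()] * graph.number_of_nodes(),
                "donor_reactive": [False] * graph.number_of_nodes(),
            }
        )
        return ImmuneNetwork(
            sample_ref=make_meta(), graph=graph, nodes=nodes
        )

    def test_complete_graph_density_one(self):
        net = network_metrics(self._net_from_graph(nx.complete_graph(5)))
        assert net.edge_density == 1.0

    def test_two_disjoint_cliques_modularity_half(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        net = network_metrics(self._net_from_graph(g))
        assert net.modularity == pytest.approx(0.5)
        assert len(net.communities) == 2

    def test_path_betweenness(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {0: "A", 1: "B", 2: "C"})
        net = network_metrics(self._net_from_graph(g))
        bc = dict(zip(net.nodes["sequence"], net.nodes["betweenness"]))
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    @pytest.mark.parametrize("n", [5, 9])
    def test_star_center_betweenness_closed_form(self, n):
        g = nx.star_graph(n - 1)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        net = network_metrics(self._net_from_graph(g))
        bc = dict(zip(net.nodes["sequence"], net.nodes["betweenness"]))
        assert bc["N0"] == (n - 1) * (n - 2) / 2

    def test_empty_edge_set_degenerate(self):
        g = nx.empty_graph(4)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        net = network_metrics(self._net_from_graph(g))
        assert net.modularity == 0.0
        assert (net.nodes["betweenness"] == 0).all()

    def test_planted_clusters_beat_random_graph(self):
        rng = np.random.default_rng(17)
        planted = nx.disjoint_union(
            nx.gnp_random_graph(20, 0.5, seed=1), nx.gnp_random_graph(20, 0.5, seed=2)
        )
        m = planted.number_of_edges()
        random = nx.gnm_random_graph(40, m, seed=3)
        q_planted = network_metrics(
            self._net_from_graph(nx.relabel_nodes(planted, str))
        ).modularity
        q_random = network_metrics(
            self._net_from_graph(nx.relabel_nodes(random, str))
        ).modularity
        assert -0.5 <= q_random <= 1 and -0.5 <= q_planted <= 1
        assert q_planted > q_random

    def test_clone_families_more_modular_than_background(self):
        rng = np.random.default_rng(23)
        family_seqs, background = [], []
        seen = set()
        for _ in range(30):
            _, seed_aa = generate_cdr3(rng)
            family_seqs.append(seed_aa)
            for _ in range(2):
                _, var = generate_cdr3(rng, family_seed=seed_aa)
                if var not in seen:
                    family_seqs.append(var)
            seen.update(family_seqs)
        while len(background) < len(family_seqs):
            _, aa = generate_cdr3(rng)
            if aa not in seen:
                seen.add(aa)
                background.append(aa)
        q_family = analyze_sample(_aa_sample(sorted(set(family_seqs)))).modularity
        q_background = analyze_sample(_aa_sample(background)).modularity
        assert q_family > q_background


class TestDonorReactiveSummary:
    def test_empty_intersection(self):
        net = analyze_sample(_aa_sample(["CASSLGQETQYF", "CASSLGQESQYF"]))
        out = donor_reactive_network_summary(net, {"CASSNOTHEREF"})
        assert out.pct_dr_in_network == 0.0
        assert not out.top_node_donor_reactive

    def test_all_nodes_donor_reactive(self):
        seqs = ["CASSLGQETQYF", "CASSLGQESQYF", "CASSLGQEAQYF"]
        net = analyze_sample(_aa_sample(seqs))
        out = donor_reactive_network_summary(net, set(seqs))
        assert out.pct_dr_in_network == 100.0
        assert out.top_node_donor_reactive

    def test_planted_donor_reactive_hub_tops_betweenness(self):
        # star of inner-segment variants: the hub differs from each leaf at a
        # different position, leaves are pairwise at distance 2
        hub = "CASAAAAAQYF"  # inner AAAAA
        leaves = ["CASBAAAAQYF", "CASABAAAQYF", "CASAABAAQYF", "CASAAABAQYF"]
        net = analyze_sample(_aa_sample([hub] + leaves))
        assert net.n_edges == 4
        out = donor_reactive_network_summary(net, {hub})
        assert out.top_betweenness_node == hub
        assert out.top_node_donor_reactive
        # unnormalized star-center betweenness over n=5 nodes
        bc = dict(zip(net.nodes["sequence"], net.nodes["betweenness"]))
        assert bc[hub] == (5 - 1) * (5 - 2) / 2
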