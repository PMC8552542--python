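"""CDR3 amino-acid similarity networks.

Nodes are unique productive CDR3β amino-acid sequences among the top-N most
frequent clonotypes; two nodes are linked when the Levenshtein distance
between their *inner segments* (sequence minus the first and last three
residues, i.e. without the conserved C...F flanks) equals 1.  Graph-level
modularity and edge density, and per-node degree and betweenness centrality,
summarize the cluster structure of the repertoire.

For the default unit distance the edge set is built exactly by
deletion-variant hashing (two equal-length strings are at distance 1 iff
they share a one-character deletion at the same position; strings whose
lengths differ by 1 are at distance 1 iff the shorter equals a deletion of
the longer).  Other thresholds fall back to length-banded pairwise
comparison via edlib.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .donor_reactivity import DonorReactiveSet
from .types import ClonotypeKey, RepertoireSample, SampleMeta

MIN_CDR3_LENGTH = 7  # below this the inner segment is undefined
TRIM = 3


def trim_inner(cdr3_aa: str, trim: int = TRIM) -> str:
    """Inner segment of a productive CDR3: drop the first and last ``trim`` residues."""
    if "*" in cdr3_aa or "_" in cdr3_aa:
        raise ValueError(f"non-productive CDR3 sequence: {cdr3_aa}")
    if len(cdr3_aa) < 2 * trim + 1:
        raise ValueError(
            f"CDR3 {cdr3_aa!r} shorter than {2 * trim + 1} aa has no inner segment"
        )
    return cdr3_aa[trim:-trim]


def levenshtein_within(a: str, b: str, k: int) -> int:
    """Levenshtein distance if ≤ k, else -1 (edlib banded alignment)."""
    import edlib

    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def _edges_distance_one(segments: list[str]) -> set[tuple[int, int]]:
    """Exact set of index pairs whose segments are at Levenshtein distance 1."""
    edges: set[tuple[int, int]] = set()
    exact: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(segments):
        exact[s].append(i)
    # substitutions: same length, share a deletion variant at the same position
    subst: dict[tuple[int, str], list[int]] = defaultdict(list)
    for i, s in enumerate(segments):
        for p in range(len(s)):
            variant = s[:p] + s[p + 1 :]
            for j in subst[(p, variant)]:
                if segments[j] != s:
                    edges.add((min(i, j), max(i, j)))
            subst[(p, variant)].append(i)
            # single insertion/deletion: the variant itself is another segment
            for j in exact.get(variant, ()):
                if j != i:
                    edges.add((min(i, j), max(i, j)))
    return edges


def _edges_banded(segments: list[str], k: int) -> set[tuple[int, int]]:
    """Pairs at Levenshtein distance exactly ``k``; O(n²) within length bands."""
    edges: set[tuple[int, int]] = set()
    by_length: dict[int, list[int]] = defaultdict(list)
    for i, s in enumerate(segments):
        by_length[len(s)].append(i)
    lengths = sorted(by_length)
    for la in lengths:
        for lb in lengths:
            if lb < la or lb - la > k:
                continue
            for i in by_length[la]:
                for j in by_length[lb]:
                    if lb == la and j <= i:
                        continue
                    if levenshtein_within(segments[i], segments[j], k) == k:
                        edges.add((min(i, j), max(i, j)))
    return edges


@dataclass
class ImmuneNetwork:
    """A CDR3 similarity graph with node and graph-level metrics.

    ``nodes`` has one row per unique amino-acid sequence (columns: sequence,
    inner, frequency, donor_reactive, degree, betweenness, community).
    """

    sample_ref: SampleMeta
    graph: nx.Graph
    nodes: pd.DataFrame
    n_excluded_short: int = 0
    n_excluded_nonproductive: int = 0
    modularity: float = float("nan")
    edge_density: float = float("nan")
    communities: list[set[str]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    sample: RepertoireSample,
    top_n: int = 10000,
    distance_threshold: int = 1,
    trim: int = TRIM,
    dr: DonorReactiveSet | None = None,
) -> ImmuneNetwork:
    """Build the similarity graph over the sample's top-``top_n`` clonotypes.

    Non-productive clones and sequences shorter than ``2*trim + 1`` aa are
    excluded (counted in the report).  Nucleotide-convergent clonotypes with
    the same amino-acid sequence are merged with frequencies summed.  An edge
    joins two sequences iff their inner segments are at Levenshtein distance
    exactly ``distance_threshold``; identical inner segments (flank-only
    differences) are not linked.
    """
    ranked = sorted(sample.clonotypes, key=lambda c: (-c.frequency, c.cdr3_aa, c.key))
    n_nonproductive = sum(1 for c in ranked if not c.productive)
    ranked = [c for c in ranked if c.productive][:top_n]

    dr_keys: set[ClonotypeKey] = set(dr.entries) if dr is not None else set()
    freq: dict[str, float] = {}
    flagged: dict[str, bool] = {}
    n_short = 0
    inner: dict[str, str] = {}
    for c in ranked:
        seq = c.cdr3_aa
        if seq not in freq:
            if len(seq) < 2 * trim + 1:
                n_short += 1
                continue
            freq[seq] = 0.0
            flagged[seq] = False
            inner[seq] = trim_inner(seq, trim)
        freq[seq] += c.frequency
        flagged[seq] = flagged[seq] or (c.key in dr_keys)

    sequences = sorted(freq)
    segments = [inner[s] for s in sequences]
    if distance_threshold == 1:
        edge_idx = _edges_distance_one(segments)
    else:
        edge_idx = _edges_banded(segments, distance_threshold)

    graph = nx.Graph()
    graph.add_nodes_from(sequences)
    graph.add_edges_from((sequences[i], sequences[j]) for i, j in edge_idx)

    nodes = pd.DataFrame(
        {
            "sequence": sequences,
            "inner": segments,
            "frequency": [freq[s] for s in sequences],
            "donor_reactive": [flagged[s] for s in sequences],
        }
    )
    return ImmuneNetwork(
        sample_ref=sample.meta,
        graph=graph,
        nodes=nodes,
        n_excluded_short=n_short,
        n_excluded_nonproductive=n_nonproductive,
    )


def _modularity_and_communities(
    graph: nx.Graph, method: str = "greedy", seed: int = 0
) -> tuple[float, list[set[str]]]:
    if graph.number_of_edges() == 0:
        return 0.0, [{n} for n in graph.nodes]
    if method == "greedy":
        communities = [set(c) for c in nx.community.greedy_modularity_communities(graph)]
    elif method == "louvain":
        communities = [set(c) for c in nx.community.louvain_communities(graph, seed=seed)]
    else:
        raise ValueError(f"unknown community-detection method: {method!r}")
    q = nx.community.modularity(graph, communities)
    return float(q), communities


def network_metrics(
    net: ImmuneNetwork,
    betweenness: bool = True,
    community_method: str = "greedy",
    seed: int = 0,
) -> ImmuneNetwork:
    """Fill in modularity, edge density, communities, degree, and betweenness.

    Communities come from deterministic greedy (CNM) modularity maximization
    by default (``community_method='louvain'`` with a fixed seed is the
    alternative); betweenness is the unnormalized shortest-path count form,
    used for ranking only.
    """
    g = net.graph
    n = g.number_of_nodes()
    net.edge_density = (
        g.number_of_edges() / (n * (n - 1) / 2) if n >= 2 else 0.0
    )
    net.modularity, net.communities = _modularity_and_communities(
        g, method=community_method, seed=seed
    )
    community_of = {
        node: idx for idx, members in enumerate(net.communities) for node in members
    }
    net.nodes["degree"] = [g.degree(s) for s in net.nodes["sequence"]]
    net.nodes["community"] = [community_of[s] for s in net.nodes["sequence"]]
    if betweenness:
        bc = (
            nx.betweenness_centrality(g, normalized=False)
            if g.number_of_edges() > 0
            else {s: 0.0 for s in g.nodes}
        )
        net.nodes["betweenness"] = [bc[s] for s in net.nodes["sequence"]]
    return net


def analyze_sample(
    sample: RepertoireSample,
    top_n: int = 10000,
    distance_threshold: int = 1,
    trim: int = TRIM,
    dr: DonorReactiveSet | None = None,
    betweenness: bool = True,
) -> ImmuneNetwork:
    """Build the network and compute all its metrics in one call."""
    net = build_network(
        sample, top_n=top_n, distance_threshold=distance_threshold, trim=trim, dr=dr
    )
    return network_metrics(net, betweenness=betweenness)


def donor_reactive_sequences(
    sample: RepertoireSample, dr: DonorReactiveSet
) -> set[str]:
    """Amino-acid sequences of the donor-reactive clonotypes found in a sample."""
    return {c.cdr3_aa for c in sample.clonotypes if c.key in dr.entries}


@dataclass
class DRNetworkSummary:
    """How the donor-reactive repertoire sits inside an immune network."""

    pct_dr_in_network: float
    top_betweenness_node: str | None
    top_node_donor_reactive: bool
    top_node_frequency_rank: int | None
    dr_subgraph_modularity: float
    dr_subgraph_edge_density: float
    network_modularity: float
    network_edge_density: float


def donor_reactive_network_summary(
    net: ImmuneNetwork, dr_sequences: set[str]
) -> DRNetworkSummary:
    """Relate a donor-reactive sequence set to the network's central nodes.

    Reports the percentage of donor-reactive sequences included as nodes, the
    top node by betweenness (ties: degree, then sequence) with its
    donor-reactive flag and frequency rank, and the modularity/edge density
    of the donor-reactive induced subgraph vs. the whole network.
    """
    if "betweenness" not in net.nodes.columns:
        net = network_metrics(net, betweenness=True)
    node_set = set(net.nodes["sequence"])
    pct = 100.0 * len(dr_sequences & node_set) / len(dr_sequences) if dr_sequences else 0.0

    top_node = None
    top_dr = False
    top_rank = None
    if len(net.nodes):
        tbl = net.nodes.sort_values(
            ["betweenness", "degree", "sequence"], ascending=[False, False, True]
        )
        top = tbl.iloc[0]
        top_node = str(top["sequence"])
        top_dr = top_node in dr_sequences or bool(top["donor_reactive"])
        ranks = net.nodes.sort_values(
            ["frequency", "sequence"], ascending=[False, True]
        )["sequence"].tolist()
        top_rank = ranks.index(top_node) + 1

    sub = net.graph.subgraph(dr_sequences & node_set)
    n_sub = sub.number_of_nodes()
    sub_density = (
        sub.number_of_edges() / (n_sub * (n_sub - 1) / 2) if n_sub >= 2 else 0.0
    )
    sub_q, _ = _modularity_and_communities(sub) if n_sub else (0.0, [])
    return DRNetworkSummary(
        pct_dr_in_network=pct,
        top_betweenness_node=top_node,
        top_node_donor_reactive=top_dr,
        top_node_frequency_rank=top_rank,
        dr_subgraph_modularity=sub_q,
        dr_subgraph_edge_density=float(sub_density),
        network_modularity=net.modularity,
        network_edge_density=net.edge_density,
    )
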