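"""Brute-force reference computations, kept independent of the package's
own traversals: trees are re-expressed as networkx digraphs and every
quantity is recomputed from edges alone."""

from __future__ import annotations

import networkx as nx

from cladeview.tree_io import LineageTree


def as_digraph(tree: LineageTree) -> nx.DiGraph:
    g = nx.DiGraph()
    for node in tree.iter_nodes():
        g.add_node(node.label, bl=node.branch_length)
        if node.parent is not None:
            g.add_edge(node.parent.label, node.label)
    return g


def leaves_below(g: nx.DiGraph, label: str) -> set[str]:
    reach = nx.descendants(g, label) | {label}
    return {n for n in reach if g.out_degree(n) == 0}


def depth_of(g: nx.DiGraph, root: str, label: str) -> int:
    return nx.shortest_path_length(g, root, label)


def depth_cut_groups(g: nx.DiGraph, root: str, k: int) -> dict[str, set[str]]:
    depths = nx.single_source_shortest_path_length(g, root)
    founders = [n for n, d in depths.items()
                if d == k or (g.out_degree(n) == 0 and d < k)]
    return {f: leaves_below(g, f) for f in founders}


def node_times_oracle(g: nx.DiGraph, root: str, mode: str) -> dict[str, float]:
    if mode == "absolute":
        return {n: float(g.nodes[n]["bl"]) for n in g}
    times = {root: float(g.nodes[root]["bl"] or 0.0)}
    for parent, child in nx.bfs_edges(g, root):
        times[child] = times[parent] + float(g.nodes[child]["bl"])
    return times


def time_cut_groups(g: nx.DiGraph, root: str, mode: str, t: float) -> dict[str, set[str]]:
    times = node_times_oracle(g, root, mode)
    groups: dict[str, set[str]] = {}
    for n in g:
        preds = list(g.predecessors(n))
        t_parent = times[preds[0]] if preds else float("-inf")
        if t_parent < t <= times[n]:
            groups[n] = leaves_below(g, n)
        elif g.out_degree(n) == 0 and times[n] < t:
            groups[n] = {n}
    return groups


def mrca_oracle(g: nx.DiGraph, root: str, a: str, b: str) -> str:
    anc_a = nx.ancestors(g, a) | {a}
    anc_b = nx.ancestors(g, b) | {b}
    common = anc_a & anc_b
    depths = nx.single_source_shortest_path_length(g, root)
    return max(common, key=lambda n: (depths[n], n))


def relationship_oracle(g: nx.DiGraph, root: str, focal: str) -> dict[str, int]:
    depths = nx.single_source_shortest_path_length(g, root)
    leaves = [n for n in g if g.out_degree(n) == 0]
    return {leaf: depths[mrca_oracle(g, root, focal, leaf)] for leaf in leaves}
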