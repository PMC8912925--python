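"""Median-joining haplotype network over subfamily consensus sequences.

Built from non-gap SNP columns of the consensus alignment: a minimum
spanning network (all minimum-spanning links) under Hamming distance is
augmented with median (Steiner) vectors — the per-site majority of a
linked node pair and a third node — until convergence, after which
medians not on any shortest path between observed taxa are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .phylo import Alignment


class NetworkError(ValueError):
    pass


@dataclass
class SNPMatrix:
    taxa: list[str]
    sites: list[int]  # retained alignment column coordinates
    states: list[str]  # per taxon, the concatenated SNP symbols


def snp_matrix(consensus_alignment: Alignment) -> SNPMatrix:
    """Retain columns that are gap-free, N-free and polymorphic."""
    arr = consensus_alignment.array()
    ok = ~((arr == ord("-")) | (arr == ord("N"))).any(axis=0)
    poly = (arr != arr[0]).any(axis=0)
    keep = np.flatnonzero(ok & poly)
    if keep.size == 0:
        raise NetworkError("no polymorphic gap-free columns (no SNPs)")
    sub = arr[:, keep]
    return SNPMatrix(
        list(consensus_alignment.ids),
        [int(k) for k in keep],
        [row.tobytes().decode() for row in sub],
    )


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _spanning_total(haps: list[str]) -> int:
    """Minimum spanning total Hamming length over a node set."""
    if len(haps) < 2:
        return 0
    arr = np.frombuffer("".join(haps).encode(), dtype=np.uint8).reshape(len(haps), -1)
    D = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return int(minimum_spanning_tree(D).sum())


def _msn_edges(nodes: list[str], dist, epsilon: int = 0):
    """Minimum spanning network: edge (u,v) kept iff u,v lie in different
    components of the graph of all strictly shorter (minus epsilon) links.
    Ties broken (ordering only) lexicographically."""
    pairs = sorted(
        ((dist(u, v), u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]),
        key=lambda t: (t[0], t[1], t[2]),
    )
    edges = []
    # union-find over links processed in weight order
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    i = 0
    while i < len(pairs):
        w = pairs[i][0]
        batch = []
        while i < len(pairs) and pairs[i][0] <= w + epsilon:
            batch.append(pairs[i])
            i += 1
        # components formed by links shorter than this weight class
        for bw, u, v in batch:
            if find(u) != find(v):
                edges.append((u, v, bw))
        for bw, u, v in batch:
            parent[find(u)] = find(v)
    return edges


def _median(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:  # all distinct: keep first (deterministic; rare for DNA triples)
            out.append(x)
    return "".join(out)


def build_mjn(
    snp: SNPMatrix,
    epsilon: int = 0,
    max_iter: int = 25,
    sizes: dict | None = None,
) -> nx.Graph:
    """Median-joining network; deterministic given input order.

    Nodes are haplotype strings labelled by the taxa carrying them (one
    node per distinct haplotype; ``median<k>`` for inferred vectors).
    Edge weights are Hamming distances over the retained SNP sites.
    """
    if len(snp.taxa) < 2:
        raise NetworkError("need >= 2 taxa")
    hap_of: dict[str, list[str]] = {}
    for taxon, hap in zip(snp.taxa, snp.states):
        hap_of.setdefault(hap, []).append(taxon)
    observed = list(hap_of)
    haplotypes = list(observed)
    n_medians = 0
    for _ in range(max_iter):
        edges = _msn_edges(haplotypes, _hamming, epsilon)
        new = []
        for u, v, _ in edges:
            for w in haplotypes:
                if w in (u, v):
                    continue
                m = _median(u, v, w)
                if m not in haplotypes and m not in new:
                    new.append(m)
        if not new:
            break
        haplotypes.extend(new)
        n_medians += len(new)
    else:
        raise NetworkError(
            f"median-joining did not converge in {max_iter} iterations "
            f"({len(haplotypes)} nodes)"
        )
    # prune medians not on any shortest path between observed haplotypes
    while True:
        edges = _msn_edges(haplotypes, _hamming, epsilon)
        G = nx.Graph()
        G.add_nodes_from(haplotypes)
        G.add_weighted_edges_from(edges)
        dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
        keep = set(observed)
        for m in haplotypes:
            if m in keep:
                continue
            on_path = False
            for i, a in enumerate(observed):
                for b in observed[i + 1:]:
                    if (
                        m in dist[a]
                        and b in dist[m]
                        and dist[a][m] + dist[m][b] == dist[a].get(b, np.inf)
                    ):
                        on_path = True
                        break
                if on_path:
                    break
            if on_path:
                keep.add(m)
        if len(keep) == len(haplotypes):
            break
        haplotypes = [h for h in haplotypes if h in keep]

    # reduction: drop any median whose removal does not lengthen the
    # spanning total; on small networks also re-admit candidate medians
    # that strictly shorten it (terminates: (total, node count) decreases
    # lexicographically at every step)
    from itertools import combinations

    while True:
        cur = _spanning_total(haplotypes)
        removed = False
        for m in [h for h in haplotypes if h not in hap_of]:
            if _spanning_total([h for h in haplotypes if h != m]) <= cur:
                haplotypes.remove(m)
                removed = True
                break
        if removed:
            continue
        if len(haplotypes) > 20:
            break
        cands = sorted(
            {_median(a, b, c) for a, b, c in combinations(sorted(haplotypes), 3)}
            - set(haplotypes)
        )
        for m in cands:
            if _spanning_total(haplotypes + [m]) < cur:
                haplotypes.append(m)
                break
        else:
            break

    # final graph with readable labels
    names = {}
    k = 0
    for h in haplotypes:
        if h in hap_of:
            names[h] = "+".join(sorted(hap_of[h]))
        else:
            k += 1
            names[h] = f"median{k}"
    net = nx.Graph()
    for h in haplotypes:
        taxa = hap_of.get(h, [])
        size = sum((sizes or {}).get(t, 1) for t in taxa) if taxa else 0
        net.add_node(
            names[h], haplotype=h, taxa=sorted(taxa),
            is_median=h not in hap_of, size=size,
        )
    for u, v, w in _msn_edges(haplotypes, _hamming, epsilon):
        net.add_edge(names[u], names[v], weight=int(w))
    return net


def network_to_file(net: nx.Graph, path) -> None:
    """Edge-list TSV plus a node attribute table (``<path>.nodes.tsv``),
    or GML when the path ends in .gml."""
    path = str(path)
    if path.endswith(".gml"):
        out = net.copy()
        for _, data in out.nodes(data=True):
            data["taxa"] = ",".join(data.get("taxa", []))
        nx.write_gml(out, path)
        return
    with open(path, "w") as fh:
        fh.write("u\tv\tweight\n")
        for u, v, data in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{int(data['weight'])}\n")
    with open(path + ".nodes.tsv", "w") as fh:
        fh.write("node\tis_median\tsize\ttaxa\thaplotype\n")
        for node, data in sorted(net.nodes(data=True)):
            fh.write(
                f"{node}\t{int(data.get('is_median', False))}\t"
                f"{data.get('size', 0)}\t{','.join(data.get('taxa', []))}\t"
                f"{data.get('haplotype', '')}\n"
            )


def read_network(path) -> nx.Graph:
    """Round-trip reader for the TSV form written by network_to_file."""
    net = nx.Graph()
    with open(str(path) + ".nodes.tsv") as fh:
        next(fh)
        for line in fh:
            node, is_median, size, taxa, hap = line.rstrip("\n").split("\t")
            net.add_node(
                node, is_median=bool(int(is_median)), size=int(size),
                taxa=[t for t in taxa.split(",") if t], haplotype=hap,
            )
    with open(path) as fh:
        next(fh)
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            net.add_edge(u, v, weight=int(w))
    return net
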