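"""Alignment handling, distances, neighbor-joining with bootstrap, parsimony.

Trees are ``dendropy.Tree`` objects.  Internal nodes carry a ``support``
attribute (proportion in [0,1], or None) set by :func:`bootstrap_support`
or by :func:`phyloreg.seqio.read_tree`.  All trees are interpreted as
unrooted; clade criteria are evaluated edge-wise on bipartitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from . import seqio

GAP = ord("-")
_UNKNOWN_CHARS = frozenset(b"-N?")

# Fitch state masks
_BASE_BIT = {ord("A"): 1, ord("C"): 2, ord("G"): 4, ord("T"): 8}
_ACGT_MASK = 15
_GAP_BIT = 16


class PhyloError(ValueError):
    pass


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise PhyloError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise PhyloError("duplicate sequence ids in alignment")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise PhyloError("alignment rows have unequal lengths")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def array(self) -> np.ndarray:
        """(n, L) uint8 matrix of ASCII codes."""
        return np.frombuffer(
            "".join(self.rows).encode(), dtype=np.uint8
        ).reshape(self.n, self.length)

    def subset(self, ids) -> "Alignment":
        index = {i: k for k, i in enumerate(self.ids)}
        return Alignment(list(ids), [self.rows[index[i]] for i in ids])

    def slice(self, start: int, end: int) -> "Alignment":
        return Alignment(list(self.ids), [r[start:end] for r in self.rows])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        recs = seqio.read_fasta(path)
        return cls([r[0] for r in recs], [r[1] for r in recs])

    def to_fasta(self, path) -> None:
        seqio.write_fasta(zip(self.ids, self.rows), path)

    @classmethod
    def from_array(cls, ids, arr: np.ndarray) -> "Alignment":
        return cls(list(ids), [row.tobytes().decode() for row in arr])


def filter_columns(
    aln: Alignment, min_nongap_frac: float = 0.01, return_kept: bool = False
):
    """Keep exactly the columns whose non-gap fraction >= threshold.

    With ``return_kept`` also returns the retained column indices, so
    coordinates defined on the unfiltered frame can be remapped.
    """
    if aln.n == 0:
        raise PhyloError("empty alignment")
    arr = aln.array()
    nongap = (arr != GAP).mean(axis=0)
    keep = nongap >= min_nongap_frac
    if not keep.any():
        raise PhyloError("all columns removed by gap filter")
    out = Alignment.from_array(aln.ids, arr[:, keep])
    if return_kept:
        return out, np.flatnonzero(keep)
    return out


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise PhyloError("distance matrix shape mismatch")


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    valid = np.zeros(arr.shape, dtype=bool)
    for b in b"ACGT":
        valid |= arr == b
    return valid


def pairwise_distance(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise-deletion p- or Jukes-Cantor distances.

    Columns with a gap or N in either member of a pair are excluded for
    that pair.  ``jc`` applies d = -(3/4) ln(1 - 4p/3).
    """
    if aln.n < 2:
        raise PhyloError("need at least 2 sequences")
    if model not in ("p", "jc"):
        raise PhyloError(f"unknown distance model {model!r}")
    arr = aln.array()
    valid = _valid_mask(arr)
    n = aln.n
    D = np.zeros((n, n))
    chunk = 64
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        both = valid[i0:i1, None, :] & valid[None, :, :]
        diff = (arr[i0:i1, None, :] != arr[None, :, :]) & both
        nvalid = both.sum(axis=2)
        ndiff = diff.sum(axis=2)
        for ii in range(i1 - i0):
            gi = i0 + ii
            for j in range(n):
                if j == gi:
                    continue
                if nvalid[ii, j] == 0:
                    raise PhyloError(
                        f"no comparable columns between {aln.ids[gi]!r} "
                        f"and {aln.ids[j]!r}"
                    )
        with np.errstate(invalid="ignore"):
            D[i0:i1] = np.where(nvalid > 0, ndiff / np.maximum(nvalid, 1), 0.0)
    np.fill_diagonal(D, 0.0)
    if model == "jc":
        inner = np.clip(1.0 - 4.0 * D / 3.0, 1e-10, None)
        D = -0.75 * np.log(inner)
        np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(aln.ids), D)


# ---------------------------------------------------------------------------
# Neighbor-joining


def _nj_merges(D: np.ndarray):
    """Run NJ on a full distance matrix.

    Returns ``(children, lengths, root)`` where node ids 0..n-1 are leaves,
    internal nodes are appended in merge order, ``children[node]`` lists the
    children of internal nodes (the root is a trifurcation), and
    ``lengths[node]`` is the branch length above ``node``.  Ties in the Q
    matrix are broken by lexicographic pair order (first occurrence).
    """
    n = D.shape[0]
    if np.isnan(D).any():
        raise PhyloError("NaN in distance matrix")
    if n < 3:
        raise PhyloError("need >= 3 taxa for NJ")
    D = D.copy().astype(float)
    active = list(range(n))  # current matrix row -> node id
    children: dict[int, list[int]] = {}
    lengths = np.zeros(2 * n, dtype=float)
    next_node = n
    while len(active) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin == lexicographic (i, j) tie-break
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        lengths[active[i]] = max(li, 0.0)
        lengths[active[j]] = max(lj, 0.0)
        children[next_node] = [active[i], active[j]]
        new_row = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        D2[-1, -1] = 0.0
        D = D2
        active = [active[k] for k in keep] + [next_node]
        next_node += 1
    # terminal trifurcation via three-point formulas
    (a, b, c) = active
    lengths[a] = max(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]), 0.0)
    lengths[b] = max(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]), 0.0)
    lengths[c] = max(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]), 0.0)
    children[next_node] = [a, b, c]
    return children, lengths, next_node


def _merge_leafsets(children: dict[int, list[int]], n_leaves: int, root: int):
    """Leaf-index frozenset below each internal node (excluding root)."""
    leafset: dict[int, frozenset] = {i: frozenset([i]) for i in range(n_leaves)}
    for node in sorted(children):
        leafset[node] = frozenset().union(*(leafset[c] for c in children[node]))
    return leafset


def _canon_split(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def _bipartitions_of_merges(children, n, root) -> set[frozenset]:
    leafset = _merge_leafsets(children, n, root)
    universe = frozenset(range(n))
    out = set()
    for node in children:
        if node == root:
            continue
        side = _canon_split(leafset[node], universe)
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _nj_bipartitions(D: np.ndarray) -> set[frozenset]:
    children, _, root = _nj_merges(D)
    return _bipartitions_of_merges(children, D.shape[0], root)


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    children, lengths, root = _nj_merges(dist.values)
    taxa = dendropy.TaxonNamespace(dist.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, dendropy.Node] = {}
    n = len(dist.ids)
    for idx in range(n):
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(dist.ids[idx])
        nd.edge.length = float(lengths[idx])
        nd.support = None
        nodes[idx] = nd
    for node in sorted(children):
        nd = dendropy.Node()
        nd.edge.length = float(lengths[node]) if node != root else 0.0
        nd.support = None
        for c in children[node]:
            nd.add_child(nodes[c])
        nodes[node] = nd
    tree.seed_node = nodes[root]
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree):
    """Map canonical leaf-label frozenset -> node, for non-trivial edges."""
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(labels)
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = _canon_split(below, labels)
        if 2 <= len(side) <= n - 2:
            out[side] = node
    return out


def bootstrap_support(
    aln: Alignment,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    model: str = "p",
) -> dendropy.Tree:
    """NJ point-estimate tree with classical column-resampling supports.

    Support of an internal edge is the fraction of replicate NJ trees
    containing the same bipartition of leaf labels.
    """
    if reps < 1:
        raise PhyloError("reps must be >= 1")
    rng = rng or np.random.default_rng()
    arr = aln.array()
    valid = _valid_mask(arr)
    n, L = arr.shape
    point = pairwise_distance(aln, model=model)
    tree = nj_tree(point)
    idx_of = {lab: i for i, lab in enumerate(aln.ids)}
    bip_counts: dict[frozenset, int] = {}
    # precompute pairwise difference/validity as flat float32 matrices;
    # a bootstrap replicate is then one matrix-vector product with the
    # resampled column-count vector
    chunkable = n * n * L * 4 <= 1_500_000_000
    if chunkable:
        both2 = (valid[:, None, :] & valid[None, :, :]).reshape(n * n, L).astype(np.float32)
        diff2 = ((arr[:, None, :] != arr[None, :, :]).reshape(n * n, L).astype(np.float32)
                 * both2)
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        if chunkable:
            weights = np.bincount(cols, minlength=L).astype(np.float32)
            nd = (diff2 @ weights).reshape(n, n)
            nv = (both2 @ weights).reshape(n, n)
        else:  # pragma: no cover - large-n fallback
            sub = Alignment.from_array(aln.ids, arr[:, cols])
            dm = pairwise_distance(sub, model="p")
            nd, nv = dm.values, np.ones_like(dm.values)
        with np.errstate(invalid="ignore"):
            Drep = np.where(nv > 0, nd / np.maximum(nv, 1), 0.0)
        np.fill_diagonal(Drep, 0.0)
        if model == "jc":
            Drep = -0.75 * np.log(np.clip(1 - 4 * Drep / 3, 1e-10, None))
            np.fill_diagonal(Drep, 0.0)
        for bip in _nj_bipartitions(Drep):
            bip_counts[bip] = bip_counts.get(bip, 0) + 1
    universe = frozenset(range(n))
    for side, node in tree_bipartitions(tree).items():
        idx_side = _canon_split(
            frozenset(idx_of[lab] for lab in side), universe
        )
        node.support = bip_counts.get(idx_side, 0) / reps
    return tree


# ---------------------------------------------------------------------------
# Parsimony


def _leaf_masks(aln: Alignment, gaps_as_state: bool) -> np.ndarray:
    """(n, L) uint8 Fitch state masks."""
    arr = aln.array()
    masks = np.zeros(arr.shape, dtype=np.uint8)
    unknown = _ACGT_MASK | (_GAP_BIT if gaps_as_state else 0)
    for code, bit in _BASE_BIT.items():
        masks[arr == code] = bit
    if gaps_as_state:
        masks[arr == GAP] = _GAP_BIT
        masks[masks == 0] = unknown  # N and other ambiguity codes
    else:
        masks[(arr == GAP) | (masks == 0)] = _ACGT_MASK
    return masks


def fitch_score(
    aln: Alignment, tree: dendropy.Tree, gaps_as_state: bool = False
) -> int:
    """Fitch small-parsimony change count summed over columns.

    Gaps and N are union-compatible unknowns by default; with
    ``gaps_as_state`` the gap is a fifth character state (N stays unknown).
    """
    idx = {lab: i for i, lab in enumerate(aln.ids)}
    masks = _leaf_masks(aln, gaps_as_state)
    node_state: dict[int, np.ndarray] = {}
    changes = np.zeros(aln.length, dtype=np.int64)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in idx:
                raise PhyloError(f"leaf {lab!r} has no sequence in alignment")
            node_state[id(node)] = masks[idx[lab]]
            continue
        kids = node.child_nodes()
        state = node_state.pop(id(kids[0]))
        for kid in kids[1:]:
            other = node_state.pop(id(kid))
            inter = state & other
            empty = inter == 0
            changes += empty
            state = np.where(empty, state | other, inter)
        node_state[id(node)] = state
    return int(changes.sum())


# -- heuristic search on an adjacency representation ------------------------


def _score_adj(adj, leaf_masks_arr, n_leaves):
    """Fitch score of an unrooted topology given as an adjacency dict."""
    # root at the neighbor of the smallest leaf present
    leaf0 = min(k for k in adj if k < n_leaves)
    root = adj[leaf0][0]
    order = []
    stack = [(root, leaf0)]
    parent = {root: leaf0}
    while stack:
        node, par = stack.pop()
        order.append((node, par))
        for nb in adj[node]:
            if nb != par:
                parent[nb] = node
                stack.append((nb, node))
    ncols = leaf_masks_arr.shape[1]
    states = {}
    changes = np.zeros(ncols, dtype=np.int64)
    for node, par in reversed(order):
        if node < n_leaves:
            states[node] = leaf_masks_arr[node]
            continue
        kids = [nb for nb in adj[node] if nb != par]
        state = states.pop(kids[0])
        for kid in kids[1:]:
            other = states.pop(kid)
            inter = state & other
            empty = inter == 0
            changes += empty
            state = np.where(empty, state | other, inter)
        states[node] = state
    # account for the pseudo-root leaf's own state
    inter = states[root] & leaf_masks_arr[leaf0]
    changes += inter == 0
    return int(changes.sum())


def _adj_edges(adj):
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _attach(adj, edge, leaf, new_internal):
    u, v = edge
    adj[u] = [new_internal if x == v else x for x in adj[u]]
    adj[v] = [new_internal if x == u else x for x in adj[v]]
    adj[new_internal] = [u, v, leaf]
    adj[leaf] = [new_internal]


def _detach_copy(adj):
    return {k: list(v) for k, v in adj.items()}


def parsimony_search(
    aln: Alignment,
    gaps_as_state: bool = False,
    seed: int = 0,
    max_rounds: int = 50,
) -> dendropy.Tree:
    """Stepwise-addition + NNI hill-climbing maximum-parsimony tree.

    Deterministic given ``seed`` (which shuffles the addition order).
    Designed for small taxon sets (the ~11 consensus sequences).
    """
    n = aln.n
    masks = _leaf_masks(aln, gaps_as_state)
    if n < 4:
        taxa = dendropy.TaxonNamespace(aln.ids)
        tree = dendropy.Tree(taxon_namespace=taxa)
        for lab in aln.ids:
            child = dendropy.Node()
            child.taxon = taxa.get_taxon(lab)
            child.edge.length = 0.0
            tree.seed_node.add_child(child)
        tree.is_rooted = False
        return tree
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n))
    a, b, c = order[:3]
    internal = n
    adj = {internal: [a, b, c], a: [internal], b: [internal], c: [internal]}
    next_internal = n + 1
    for leaf in order[3:]:
        best = None
        for edge in sorted(_adj_edges(adj)):
            cand = _detach_copy(adj)
            _attach(cand, edge, leaf, next_internal)
            s = _score_adj(cand, masks, n)
            if best is None or s < best[0]:
                best = (s, cand)
        adj = best[1]
        next_internal += 1
    # NNI hill climbing
    best_score = _score_adj(adj, masks, n)
    for _ in range(max_rounds):
        improved = False
        for u, v in sorted(_adj_edges(adj)):
            if u < n or v < n:
                continue  # internal edges only
            u_subs = [x for x in adj[u] if x != v]
            v_subs = [x for x in adj[v] if x != u]
            if len(u_subs) < 2 or len(v_subs) < 2:
                continue
            for swap in ((0, 0), (0, 1)):
                cand = _detach_copy(adj)
                us, vs = u_subs[swap[0]], v_subs[swap[1]]
                cand[u] = [vs if x == us else x for x in cand[u]]
                cand[v] = [us if x == vs else x for x in cand[v]]
                cand[us] = [v if x == u else x for x in cand[us]]
                cand[vs] = [u if x == v else x for x in cand[vs]]
                s = _score_adj(cand, masks, n)
                if s < best_score:
                    adj, best_score, improved = cand, s, True
                    break
            if improved:
                break
        if not improved:
            break
    return _adj_to_tree(adj, aln.ids, n)


def _adj_to_tree(adj, ids, n_leaves) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(list(ids))
    root = max(adj)  # any internal node
    nodes = {}

    def build(node, parent):
        nd = dendropy.Node()
        nd.edge.length = 0.0
        nd.support = None
        if node < n_leaves:
            nd.taxon = taxa.get_taxon(ids[node])
        nodes[node] = nd
        for nb in adj[node]:
            if nb != parent:
                nd.add_child(build(nb, node))
        return nd

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = build(root, None)
    tree.is_rooted = False
    return tree


def parsimony_bootstrap(
    aln: Alignment,
    reps: int = 100,
    gaps_as_state: bool = False,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> dendropy.Tree:
    """Parsimony point tree with column-resampling bootstrap supports."""
    rng = rng or np.random.default_rng()
    tree = parsimony_search(aln, gaps_as_state=gaps_as_state, seed=seed)
    arr = aln.array()
    counts: dict[frozenset, int] = {}
    for _ in range(reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep = parsimony_search(
            Alignment.from_array(aln.ids, arr[:, cols]),
            gaps_as_state=gaps_as_state,
            seed=seed,
        )
        for side in tree_bipartitions(rep):
            counts[side] = counts.get(side, 0) + 1
    for side, node in tree_bipartitions(tree).items():
        node.support = counts.get(side, 0) / reps
    return tree


def terminal_branch_lengths(tree: dendropy.Tree) -> dict[str, float]:
    """Leaf-to-nearest-node edge lengths, unrooted-aware.

    If the tree has a degree-two root, the two root edges form one unrooted
    edge; a leaf attached there gets the summed length.
    """
    out = {}
    root_kids = tree.seed_node.child_nodes()
    for leaf in tree.leaf_node_iter():
        length = leaf.edge.length or 0.0
        if leaf.parent_node is tree.seed_node and len(root_kids) == 2:
            sibling = [c for c in root_kids if c is not leaf][0]
            length += sibling.edge.length or 0.0
        out[leaf.taxon.label] = length
    return out
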