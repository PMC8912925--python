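"""Block-wise recombination and tandem-duplication analysis.

Consensus alignments are split into contiguous sequence blocks; a tree is
inferred per block and compared with the reference (whole-sequence)
topology.  A well-supported clade in a block tree that cannot coexist
with the reference topology marks a recombination candidate.  Tandem
duplications are called from the global-alignment identity of adjacent
blocks within one consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import Align

from . import phylo
from .phylo import Alignment, PhyloError


@dataclass(frozen=True)
class BlockDefinition:
    name: str
    start: int  # 0-based, half-open columns in the alignment frame
    end: int

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"block {self.name}: bad range [{self.start},{self.end})")


@dataclass
class IncongruenceEvent:
    block: str
    clade: frozenset  # taxa on the supported, conflicting side
    block_support: float
    conflicts_with: frozenset  # one reference bipartition it cannot coexist with
    direction: str = "?"  # "donor->acceptor" when ages order the partners
    classification: str = "recombination_candidate"


def remap_blocks(blocks: list[BlockDefinition], kept_columns) -> list[BlockDefinition]:
    """Express blocks in the frame of a column-filtered alignment.

    ``kept_columns``: sorted original-frame indices of retained columns.
    Blocks left empty by the filter are dropped."""
    kept = np.asarray(kept_columns)
    out = []
    for b in sorted(blocks, key=lambda b: b.start):
        s = int(np.searchsorted(kept, b.start, side="left"))
        e = int(np.searchsorted(kept, b.end, side="left"))
        if e > s:
            out.append(BlockDefinition(b.name, s, e))
    return out


def validate_blocks(blocks: list[BlockDefinition], aln_length: int) -> None:
    ordered = sorted(blocks, key=lambda b: b.start)
    for b in ordered:
        if b.end > aln_length:
            raise ValueError(f"block {b.name} exceeds alignment length")
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"blocks {a.name} and {b.name} overlap")


def slice_blocks(
    consensus_aln: Alignment, blocks: list[BlockDefinition]
) -> dict[str, Alignment]:
    """Column slices per block; all-gap taxa are dropped (flagged absent)."""
    validate_blocks(blocks, consensus_aln.length)
    out = {}
    for b in blocks:
        sub = consensus_aln.slice(b.start, b.end)
        present_ids, present_rows = [], []
        for tid, row in zip(sub.ids, sub.rows):
            if set(row) <= {"-"}:
                warnings.warn(f"taxon {tid!r} absent (all-gap) in block {b.name}")
                continue
            present_ids.append(tid)
            present_rows.append(row)
        out[b.name] = Alignment(present_ids, present_rows)
    return out


def block_trees(
    block_slices: dict[str, Alignment],
    method: str = "nj",
    reps: int = 100,
    rng: np.random.Generator | None = None,
    fifth_state_blocks: frozenset = frozenset(),
) -> dict[str, dendropy.Tree]:
    """Bootstrap-supported tree per block.

    Gaps are unknown states by default; blocks named in
    ``fifth_state_blocks`` treat the gap as a real fifth state under
    parsimony (used for blocks that are entirely absent from some taxa).
    Blocks with fewer than four present taxa are skipped with a warning.
    """
    rng = rng or np.random.default_rng()
    out = {}
    for name, sub in block_slices.items():
        if sub.n < 4:
            warnings.warn(f"block {name}: fewer than 4 present taxa, skipped")
            continue
        if method == "nj":
            out[name] = phylo.bootstrap_support(sub, reps=reps, rng=rng)
        elif method == "parsimony":
            out[name] = phylo.parsimony_bootstrap(
                sub, reps=reps, rng=rng,
                gaps_as_state=(name in fifth_state_blocks),
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def _restrict(side: frozenset, shared: frozenset) -> frozenset:
    return side & shared


def _incompatible(a_side: frozenset, b_side: frozenset, universe: frozenset) -> bool:
    """Two bipartitions cannot coexist on one tree iff all four
    intersections of their sides are non-empty."""
    a_other = universe - a_side
    b_other = universe - b_side
    return all(
        (
            len(a_side & b_side) > 0,
            len(a_side & b_other) > 0,
            len(a_other & b_side) > 0,
            len(a_other & b_other) > 0,
        )
    )


def detect_incongruence(
    btrees: dict[str, dendropy.Tree],
    reference_tree: dendropy.Tree,
    support_min: float = 0.95,
    ages: dict | None = None,
) -> list[IncongruenceEvent]:
    """Supported block clades incompatible with supported reference clades.

    A conflict is only scored against reference bipartitions that are
    themselves supported at ``support_min`` (unsupported reference edges
    carry no evidence; trees loaded without supports are taken as given).
    Overlapping conflicting clades within one block are merged into a
    single event, so the returned count is a minimum number of
    recombination candidates.  With per-taxon ``ages`` (older = larger),
    the direction is reported as oldest-partner -> clade.
    """
    ref_labels = frozenset(lf.taxon.label for lf in reference_tree.leaf_node_iter())
    ref_bips = {
        side: node
        for side, node in phylo.tree_bipartitions(reference_tree).items()
        if getattr(node, "support", None) is None or node.support >= support_min
    }
    events: list[IncongruenceEvent] = []
    for block, btree in sorted(btrees.items()):
        blk_labels = frozenset(lf.taxon.label for lf in btree.leaf_node_iter())
        shared = blk_labels & ref_labels
        if len(shared) < 4:
            continue
        # reference bipartitions restricted to shared taxa
        ref_restricted = set()
        for side in ref_bips:
            r = phylo._canon_split(_restrict(side, shared), shared)
            if 2 <= len(r) <= len(shared) - 2:
                ref_restricted.add(r)
        block_events: list[IncongruenceEvent] = []
        for side, node in phylo.tree_bipartitions(btree).items():
            sup = getattr(node, "support", None)
            if sup is None or sup < support_min:
                continue
            r = phylo._canon_split(_restrict(side, shared), shared)
            if not 2 <= len(r) <= len(shared) - 2:
                continue
            conflict = None
            for ref_side in sorted(ref_restricted, key=lambda s: tuple(sorted(s))):
                if _incompatible(r, ref_side, shared):
                    conflict = ref_side
                    break
            if conflict is None:
                continue
            block_events.append(
                IncongruenceEvent(block, r, float(sup), conflict,
                                  direction=_infer_direction(r, ages))
            )
        events.extend(_merge_overlapping(block_events))
    return events


def _infer_direction(clade: frozenset, ages: dict | None) -> str:
    if not ages:
        return "?"
    known = [t for t in clade if t in ages]
    if len(known) < 2:
        return "?"
    ordered = sorted(known, key=lambda t: -ages[t])
    if ages[ordered[0]] == ages[ordered[1]]:
        return "?"
    return f"{ordered[0]}->{','.join(sorted(set(known) - {ordered[0]}))}"


def _merge_overlapping(events: list[IncongruenceEvent]) -> list[IncongruenceEvent]:
    """Union-find merge of events whose clades overlap (same block)."""
    merged: list[IncongruenceEvent] = []
    for ev in sorted(events, key=lambda e: (-e.block_support, tuple(sorted(e.clade)))):
        hit = None
        for m in merged:
            if ev.clade & m.clade:
                hit = m
                break
        if hit is None:
            merged.append(ev)
    return merged


def detect_duplication(
    consensus_row: str,
    blocks: list[BlockDefinition],
    block_i: str,
    block_j: str,
    min_identity: float = 0.70,
):
    """Test whether two adjacent blocks of one consensus are near-copies.

    Global alignment (match +1, mismatch -1, gap open -2, extend -1);
    identity = matches / aligned columns excluding terminal gaps.  Returns
    ``(called, identity)`` or ``None`` when a block is absent.
    """
    by_name = {b.name: b for b in blocks}
    bi, bj = by_name[block_i], by_name[block_j]
    seq_i = consensus_row[bi.start : bi.end].replace("-", "").replace("N", "")
    seq_j = consensus_row[bj.start : bj.end].replace("-", "").replace("N", "")
    if not seq_i or not seq_j:
        return None
    ordered = sorted(blocks, key=lambda b: b.start)
    idx_i, idx_j = ordered.index(bi), ordered.index(bj)
    adjacent = abs(idx_i - idx_j) == 1
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    alignment = aligner.align(seq_i, seq_j)[0]
    a, b = str(alignment[0]), str(alignment[1])
    # trim terminal gap overhangs
    start = 0
    while a[start] == "-" or b[start] == "-":
        start += 1
        if start >= len(a):
            return (False, 0.0)
    end = len(a)
    while a[end - 1] == "-" or b[end - 1] == "-":
        end -= 1
    matches = sum(1 for x, y in zip(a[start:end], b[start:end]) if x == y and x != "-")
    identity = matches / (end - start)
    return (adjacent and identity >= min_identity, identity)


def scan_breakpoints(
    consensus_aln: Alignment,
    window: int = 100,
    step: int = 25,
    support_min: float = 0.95,
    reps: int = 100,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Advisory sliding-window scan for topology changes.

    Windows are scanned left to right; supported bipartitions accumulate,
    and a window whose supported set is incompatible with an accumulated
    bipartition yields one candidate at the midpoint between the two
    conflicting windows' centers (the accumulator then restarts).  Block
    definitions remain user input.
    """
    if consensus_aln.n < 4:
        raise PhyloError("need >= 4 taxa")
    L = consensus_aln.length
    if window > L:
        raise PhyloError("window exceeds alignment length")
    rng = rng or np.random.default_rng()
    universe = frozenset(consensus_aln.ids)
    starts = list(range(0, L - window + 1, step))
    candidates = []
    seen: dict[frozenset, int] = {}  # supported bipartition -> last center
    for s in starts:
        center = s + window // 2
        sub = consensus_aln.slice(s, s + window)
        try:
            tree = phylo.bootstrap_support(sub, reps=reps, rng=rng)
        except PhyloError:
            continue
        sups = {
            side
            for side, node in phylo.tree_bipartitions(tree).items()
            if (getattr(node, "support", 0) or 0) >= support_min
        }
        clash_center = None
        for cur in sorted(sups, key=lambda x: tuple(sorted(x))):
            for prev, prev_center in seen.items():
                if _incompatible(cur, prev, universe):
                    c = prev_center if clash_center is None else clash_center
                    clash_center = max(c, prev_center)
        if clash_center is not None:
            candidates.append((clash_center + center) // 2)
            seen = {}
        for side in sups:
            seen[side] = center
    return candidates
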