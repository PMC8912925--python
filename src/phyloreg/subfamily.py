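"""Subfamily partitioning, majority-rule consensus, assignment and dating.

A subfamily is a clade of element copies descending from one amplified
progenitor.  Following the field's operational definition, a clade
qualifies when its subtending edge has bootstrap support >= ``support_min``
and length > ``branch_min`` substitutions/site, and it contains strictly
more than ``size_min`` members.  Maximal qualifying clades are taken, so
subfamilies are disjoint; everything else is "unassigned".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import edlib
import numpy as np
import pandas as pd
from scipy import stats

from . import phylo
from .phylo import Alignment, PhyloError


@dataclass
class PartitionConfig:
    support_min: float = 0.95  # bootstrap proportion
    size_min: int = 10  # clade must have strictly more members
    branch_min: float = 0.015  # subtending edge, substitutions/site

    def __post_init__(self):
        if not 0 < self.support_min <= 1:
            raise ValueError("support_min must be in (0,1]")
        if self.size_min < 2 or self.branch_min < 0:
            raise ValueError("size_min >= 2 and branch_min >= 0 required")


@dataclass
class CladeInfo:
    members: frozenset
    support: float
    branch_length: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Partition:
    assignments: dict  # element id -> subfamily name or "unassigned"
    clades: dict  # name -> CladeInfo
    nested_diagnostics: list = field(default_factory=list)

    def members(self, name: str) -> list[str]:
        return sorted(e for e, g in self.assignments.items() if g == name)

    def subfamilies(self) -> list[str]:
        return sorted(self.clades)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("element_id\tsubfamily\n")
            for eid in sorted(self.assignments):
                fh.write(f"{eid}\t{self.assignments[eid]}\n")


UNASSIGNED = "unassigned"


def partition_tree(tree: dendropy.Tree, cfg: PartitionConfig | None = None) -> Partition:
    """Partition tree leaves into subfamilies by edge-wise clade criteria.

    The criterion is evaluated per internal edge on the smaller side of
    its bipartition, so the result does not depend on rooting or leaf
    order.  Nested qualifying clades are resolved by keeping the maximal
    ones; the discarded nested candidates are kept as diagnostics.
    """
    cfg = cfg or PartitionConfig()
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    universe = frozenset(leaves)
    bips = phylo.tree_bipartitions(tree)
    if bips and all(getattr(nd, "support", None) is None for nd in bips.values()):
        raise PhyloError(
            "tree has no support values: run bootstrap_support (or load a "
            "newick with support labels) before partitioning"
        )
    candidates = []
    for side, node in bips.items():
        sup = getattr(node, "support", None)
        blen = node.edge.length or 0.0
        if sup is None or sup < cfg.support_min:
            continue
        if blen <= cfg.branch_min:
            continue
        if len(side) <= cfg.size_min:
            continue
        candidates.append(CladeInfo(side, float(sup), float(blen)))
    # a subfamily is the burst itself: a qualifying clade containing no
    # smaller qualifying clade (a super-clade spanning several bursts also
    # clears the edge criteria, but it is separated internally and is kept
    # only as a diagnostic)
    candidates.sort(key=lambda c: (c.size, tuple(sorted(c.members))))
    accepted: list[CladeInfo] = []
    nested: list[CladeInfo] = []
    for cand in candidates:
        if any(a.members <= cand.members or (cand.members & a.members)
               for a in accepted):
            nested.append(cand)
        else:
            accepted.append(cand)
    # stable naming: by first member label
    accepted.sort(key=lambda c: tuple(sorted(c.members)))
    clades = {f"S{i + 1}": c for i, c in enumerate(accepted)}
    assignments = {lab: UNASSIGNED for lab in leaves}
    for name, clade in clades.items():
        for lab in clade.members:
            assignments[lab] = name
    return Partition(assignments, clades, nested)


@dataclass
class Consensus:
    name: str
    sequence: str  # over {A,C,G,T,N}; gap-plurality columns are deleted
    frame: np.ndarray  # alignment column index of each consensus position

    def __len__(self):
        return len(self.sequence)


def consensus_row(aln: Alignment, frac: float = 0.51) -> str:
    """Aligned consensus row: per-column majority symbol, '-' when the gap
    wins, 'N' when nothing reaches ``frac``."""
    if aln.n == 0:
        raise PhyloError("empty alignment")
    arr = aln.array()
    n = aln.n
    out = np.full(aln.length, ord("N"), dtype=np.uint8)
    best_count = np.zeros(aln.length, dtype=int)
    for sym in b"ACGT-":
        cnt = (arr == sym).sum(axis=0)
        win = cnt > best_count
        out[win] = sym
        best_count[win] = cnt[win]
    out[best_count / n < frac] = ord("N")
    return out.tobytes().decode()


def majority_consensus(aln: Alignment, frac: float = 0.51, name: str = "consensus") -> Consensus:
    """51%-majority-rule consensus; sub-majority columns become 'N' and
    gap-plurality columns are deleted (consensus can be shorter than the
    alignment)."""
    row = consensus_row(aln, frac)
    keep = [i for i, ch in enumerate(row) if ch != "-"]
    seq = "".join(row[i] for i in keep)
    return Consensus(name, seq, np.array(keep, dtype=int))


def consensus_alignment(
    family_aln: Alignment, partition: Partition, frac: float = 0.51
) -> Alignment:
    """Per-subfamily consensus rows in the shared family-alignment frame."""
    ids, rows = [], []
    for name in partition.subfamilies():
        members = partition.members(name)
        if not members:
            continue
        ids.append(name)
        rows.append(consensus_row(family_aln.subset(members), frac))
    return Alignment(ids, rows)


def _pairwise_pdist(a: str, b: str) -> float:
    """p-distance over aligned non-gap columns of a global edlib alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = mismatches = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        k = int(num)
        num = ""
        if ch == "=":
            matches += k
        elif ch == "X":
            mismatches += k
    if matches + mismatches == 0:
        return 1.0
    return mismatches / (matches + mismatches)


def assign_by_similarity(sequences, consensus_set) -> dict:
    """Assign each sequence to the nearest consensus (min p-distance).

    ``sequences``: iterable of (id, seq); ``consensus_set``: mapping
    name -> sequence or list of :class:`Consensus`.  Ties break by
    consensus name order.  Returns id -> (name, distance).
    """
    if not consensus_set:
        raise ValueError("empty consensus set")
    if isinstance(consensus_set, dict):
        cons = sorted(consensus_set.items())
    else:
        cons = sorted((c.name, c.sequence) for c in consensus_set)
    out = {}
    for sid, seq in (sequences.items() if isinstance(sequences, dict) else sequences):
        clean = seq.replace("-", "")
        best = None
        for name, cseq in cons:
            d = _pairwise_pdist(clean, cseq.replace("N", "").replace("-", ""))
            if best is None or d < best[1]:
                best = (name, d)
        out[sid] = best
    return out


@dataclass
class AgeGroupResult:
    terminal: dict  # element -> terminal branch length
    groups: dict  # group -> list of lengths
    summary: pd.DataFrame
    tests: pd.DataFrame  # group_a, group_b, n_a, n_b, statistic, p, padj


def age_groups(tree: dendropy.Tree, partition: Partition, grouping: dict) -> AgeGroupResult:
    """Terminal-branch-length dating with pairwise Wilcoxon rank-sum tests.

    ``grouping`` maps subfamily names to group labels (subfamilies judged
    concomitantly active are merged).  All pairwise two-sided tests are
    Bonferroni-corrected by the number of tests performed; groups with
    fewer than two members yield NA rows.
    """
    if len(set(grouping.values())) < 2:
        raise ValueError("grouping must define at least 2 groups")
    terminal = phylo.terminal_branch_lengths(tree)
    groups: dict[str, list[float]] = {}
    for eid, sub in partition.assignments.items():
        if sub in grouping and eid in terminal:
            groups.setdefault(grouping[sub], []).append(terminal[eid])
    names = sorted(groups)
    summary = pd.DataFrame(
        {
            "group": names,
            "n": [len(groups[g]) for g in names],
            "mean": [float(np.mean(groups[g])) if groups[g] else np.nan for g in names],
            "median": [float(np.median(groups[g])) if groups[g] else np.nan for g in names],
        }
    )
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            x, y = groups[ga], groups[gb]
            if len(x) < 2 or len(y) < 2:
                rows.append((ga, gb, len(x), len(y), np.nan, np.nan))
                continue
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            rows.append((ga, gb, len(x), len(y), float(res.statistic), float(res.pvalue)))
    tests = pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "statistic", "p"]
    )
    n_tests = int(tests["p"].notna().sum())
    tests["padj"] = np.minimum(tests["p"] * max(n_tests, 1), 1.0)
    return AgeGroupResult(terminal, groups, summary, tests)


def orthology_profile(
    presence: pd.DataFrame,
    partition: Partition,
    species_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subfamily fraction of members with a 1:1 orthologous insertion
    in each species (columns ordered by divergence when given)."""
    cols = species_order or list(presence.columns)
    data = {}
    for name in partition.subfamilies():
        members = partition.members(name)
        missing = [m for m in members if m not in presence.index]
        if missing:
            warnings.warn(
                f"{len(missing)} element(s) of {name} missing from presence matrix"
            )
        members = [m for m in members if m in presence.index]
        if not members:
            data[name] = [0.0] * len(cols)
            continue
        sub = presence.loc[members, cols]
        data[name] = (sub.sum(axis=0) / len(members)).tolist()
    return pd.DataFrame(data, index=cols).T
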