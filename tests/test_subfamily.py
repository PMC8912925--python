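import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import adjusted_rand_index
from phyloreg import phylo, simulate
from phyloreg.phylo import Alignment, PhyloError
from phyloreg.subfamily import (
    UNASSIGNED,
    CladeInfo,
    Partition,
    PartitionConfig,
    age_groups,
    assign_by_similarity,
    majority_consensus,
    orthology_profile,
    partition_tree,
)


def _tree_with_clades(clades, outgroup, support=1.0, blen=0.05, tip=0.001):
    """Rooted tree: each clade is a rake under a long supported edge."""
    parts = []
    for members in clades:
        tips = ",".join(f"{m}:{tip}" for m in members)
        parts.append(f"({tips}):{blen}")
    parts.extend(f"{o}:{tip}" for o in outgroup)
    newick = "(" + ",".join(parts) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    for node in tree.preorder_node_iter():
        node.support = None if node.is_leaf() else support
        if node.edge.length is None:
            node.edge.length = 0.0
    return tree


class TestPartitionTree:
    def test_star_tree_all_unassigned(self):
        tree = _tree_with_clades([], [f"t{i}" for i in range(12)])
        part = partition_tree(tree)
        assert set(part.assignments.values()) == {UNASSIGNED}

    def test_strictly_more_than_size_min_members(self):
        ten = [f"a{i}" for i in range(10)]
        eleven = [f"b{i}" for i in range(11)]
        out = [f"o{i}" for i in range(20)]
        part = partition_tree(_tree_with_clades([ten, eleven], out))
        sizes = sorted(c.size for c in part.clades.values())
        assert sizes == [11]  # the 10-clade fails ">10"

    def test_short_edge_rejected(self):
        members = [f"a{i}" for i in range(12)]
        out = [f"o{i}" for i in range(15)]
        part = partition_tree(_tree_with_clades([members], out, blen=0.015))
        assert part.clades == {}  # 0.015 is not > 0.015

    def test_low_support_rejected(self):
        members = [f"a{i}" for i in range(12)]
        out = [f"o{i}" for i in range(15)]
        part = partition_tree(_tree_with_clades([members], out, support=0.90))
        assert part.clades == {}

    def test_no_supports_instructs_bootstrap(self):
        tree = _tree_with_clades([[f"a{i}" for i in range(12)]],
                                 [f"o{i}" for i in range(15)])
        for node in tree.preorder_node_iter():
            node.support = None
        with pytest.raises(PhyloError, match="bootstrap"):
            partition_tree(tree)

    def test_invariant_to_rerooting(self, small_truth, rng):
        aln = small_truth.alignment
        tree = phylo.bootstrap_support(aln, reps=50, rng=rng)
        p1 = partition_tree(tree)
        # reroot on a leaf edge and re-partition
        leaf = tree.leaf_nodes()[5]
        tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
        p2 = partition_tree(tree)
        groups1 = {frozenset(p1.members(n)) for n in p1.clades}
        groups2 = {frozenset(p2.members(n)) for n in p2.clades}
        assert groups1 == groups2

    def test_threshold_monotonicity(self, small_truth, rng):
        tree = phylo.bootstrap_support(small_truth.alignment, reps=50, rng=rng)
        base = len(partition_tree(tree, PartitionConfig(0.9, 5, 0.01)).clades)
        for cfg in [PartitionConfig(0.9, 7, 0.01), PartitionConfig(0.9, 5, 0.03),
                    PartitionConfig(0.95, 5, 0.01)]:
            assert len(partition_tree(tree, cfg).clades) <= base

    def test_recovers_simulated_subfamilies(self, small_truth, rng):
        tree = phylo.bootstrap_support(small_truth.alignment, reps=100, rng=rng)
        part = partition_tree(tree, PartitionConfig(size_min=5))
        ari = adjusted_rand_index(small_truth.labels, part.assignments)
        assert ari >= 0.95


class TestMajorityConsensus:
    def test_identical_sequences(self):
        aln = Alignment(list("abc"), ["ACGT"] * 3)
        assert majority_consensus(aln).sequence == "ACGT"

    def test_even_split_gives_n(self):
        aln = Alignment([f"s{i}" for i in range(10)], ["A"] * 5 + ["T"] * 5)
        assert majority_consensus(aln).sequence == "N"

    def test_gap_plurality_deletes_column(self):
        aln = Alignment(list("abc"), ["A-T", "A-T", "AAT"])
        cons = majority_consensus(aln)
        assert cons.sequence == "AT"
        assert list(cons.frame) == [0, 2]

    def test_consensus_of_single_row_is_identity(self):
        aln = Alignment(["x"], ["ACGTN"])
        assert majority_consensus(aln).sequence == "ACGTN"

    def test_empty_alignment_errors(self):
        with pytest.raises(PhyloError):
            majority_consensus(Alignment([], []))

    def test_recovers_founder(self, small_truth):
        # per true subfamily, consensus ~= founder over non-N positions
        for name in ["sf1", "sf2", "sf3"]:
            members = [e for e, s in small_truth.labels.items() if s == name]
            sub = small_truth.alignment.subset(members)
            from phyloreg.subfamily import consensus_row

            row = consensus_row(sub)
            founder = small_truth.founder_rows[name]
            pairs = [(c, f) for c, f in zip(row, founder) if c not in "N"]
            ident = sum(c == f for c, f in pairs) / len(pairs)
            assert ident >= 0.99


class TestAssignBySimilarity:
    def test_self_assignment_zero_distance(self):
        cons = {"c1": "ACGTACGTAA", "c2": "TTTTTTTTTT"}
        res = assign_by_similarity([("q", "ACGTACGTAA")], cons)
        assert res["q"] == ("c1", 0.0)

    def test_tie_breaks_by_name_order(self):
        cons = {"b": "AAAA", "a": "AAAA"}
        res = assign_by_similarity([("q", "AAAT")], cons)
        assert res["q"][0] == "a"

    def test_simulated_concordance(self, small_truth):
        cons = {
            name: majority_consensus(
                small_truth.alignment.subset(
                    [e for e, s in small_truth.labels.items() if s == name]
                ), name=name
            ).sequence.replace("N", "")
            for name in ["sf1", "sf2", "sf3"]
        }
        seqs = [(e.id, e.sequence) for e in small_truth.elements]
        res = assign_by_similarity(seqs, cons)
        hits = sum(res[e][0] == small_truth.labels[e] for e, _ in seqs)
        assert hits / len(seqs) >= 0.95


def _star_tree(lengths: dict):
    taxa = dendropy.TaxonNamespace(list(lengths))
    tree = dendropy.Tree(taxon_namespace=taxa)
    for lab, ln in lengths.items():
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nd.edge.length = ln
        tree.seed_node.add_child(nd)
    return tree


def _manual_partition(groups: dict):
    assignments = {}
    clades = {}
    for name, members in groups.items():
        for m in members:
            assignments[m] = name
        clades[name] = CladeInfo(frozenset(members), 1.0, 0.05)
    return Partition(assignments, clades)


class TestAgeGroups:
    def test_exact_wilcoxon_matches_enumeration(self):
        # x=(1,2,3), y=(4,5,6): exhaustive rank-sum two-sided p = 2/20
        lengths = {"a1": 1, "a2": 2, "a3": 3, "b1": 4, "b2": 5, "b3": 6}
        tree = _star_tree(lengths)
        part = _manual_partition({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]})
        res = age_groups(tree, part, {"A": "A", "B": "B"})
        assert res.tests.loc[0, "p"] == pytest.approx(0.1)

    def test_identical_distributions_high_padj(self, rng):
        # three identical groups: all Bonferroni-adjusted p should hover
        # near 1 (median over seeds >= 0.5)
        padjs = []
        for _ in range(100):
            vals = rng.exponential(0.01, size=60)
            lengths = {f"x{i}": v for i, v in enumerate(vals)}
            part = _manual_partition(
                {g: [f"x{i}" for i in range(k * 20, (k + 1) * 20)]
                 for k, g in enumerate("ABC")}
            )
            res = age_groups(_star_tree(lengths), part, dict(A="A", B="B", C="C"))
            padjs.extend(res.tests["padj"].tolist())
        assert np.median(padjs) >= 0.5

    def test_separated_waves_tiny_padj(self, rng):
        x = rng.exponential(0.005, 50)
        y = rng.exponential(0.02, 50)
        lengths = {f"a{i}": v for i, v in enumerate(x)}
        lengths.update({f"b{i}": v for i, v in enumerate(y)})
        part = _manual_partition(
            {"A": [f"a{i}" for i in range(50)], "B": [f"b{i}" for i in range(50)]}
        )
        res = age_groups(_star_tree(lengths), part, {"A": "A", "B": "B"})
        assert res.tests.loc[0, "padj"] < 1e-4

    def test_small_group_reports_na(self):
        lengths = {"a1": 1.0, "b1": 2.0, "b2": 3.0}
        part = _manual_partition({"A": ["a1"], "B": ["b1", "b2"]})
        res = age_groups(_star_tree(lengths), part, {"A": "A", "B": "B"})
        assert np.isnan(res.tests.loc[0, "p"])


class TestOrthologyProfile:
    def test_all_present(self):
        part = _manual_partition({"A": ["e1", "e2"]})
        pres = pd.DataFrame({"chimp": [1, 1], "gorilla": [1, 1]},
                            index=["e1", "e2"])
        prof = orthology_profile(pres, part)
        assert (prof.loc["A"] == 1.0).all()

    def test_empty_intersection_zero(self):
        part = _manual_partition({"A": ["e1"]})
        pres = pd.DataFrame({"chimp": [0]}, index=["e1"])
        assert orthology_profile(pres, part).loc["A", "chimp"] == 0.0

    def test_missing_element_warns(self):
        part = _manual_partition({"A": ["e1", "e2"]})
        pres = pd.DataFrame({"chimp": [1]}, index=["e1"])
        with pytest.warns(UserWarning, match="missing"):
            prof = orthology_profile(pres, part)
        assert prof.loc["A", "chimp"] == 1.0

    def test_uniform_age_expectation(self):
        # ages uniform in (4, 10) mya vs a 6-mya split: P(shared) = 4/6
        cfg = simulate.SimConfig(
            seed=9, n_subfamilies=1, copies_per_subfamily=100,
            activity_windows={"sf1": (10.0, 4.0)},
            species_splits={"chimp": 6.0},
        )
        truth = simulate.simulate_family(cfg)
        part = _manual_partition({"sf1": list(truth.labels)})
        prof = orthology_profile(truth.presence, part)
        assert prof.loc["sf1", "chimp"] == pytest.approx(2 / 3, abs=0.15)
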