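import itertools

import numpy as np
import pytest

import cnclone as cc
from cnclone.parsimony import (
    ROOT_STATE,
    attach_late_clusters,
    edge_length_mb,
    parsimony_tree,
    sankoff_score,
)
from cnclone.segments import SegmentTable

from conftest import make_profile


def table_from_states(states, labels, seg_len_bp=5_000_000):
    """SegmentTable with equal-length segments on one chromosome."""
    states = np.asarray(states, dtype=np.int64)
    n = states.shape[1]
    starts = np.arange(n) * seg_len_bp
    return SegmentTable(
        chromosomes=np.array(["c1"] * n, dtype=object),
        starts=starts,
        ends=starts + seg_len_bp,
        lengths_bp=np.full(n, seg_len_bp),
        states=states,
        labels=list(labels),
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def all_rooted_topologies(n):
    """All rooted binary topologies over leaves 0..n-1 (sequential grafting)."""
    def insert(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            l, r = t
            for x in insert(l, leaf):
                yield (x, r)
            for x in insert(r, leaf):
                yield (l, x)

    topos = [0]
    for leaf in range(1, n):
        topos = [t2 for t in topos for t2 in insert(t, leaf)]
    return topos


def brute_force_min_score(states, criterion, max_state=None):
    """Minimum changes over all topologies x all internal labelings.

    Exhaustive per segment: for each topology, assigns every internal node
    every possible state and counts changes, root fixed at 2.
    """
    states = np.asarray(states)
    n, nseg = states.shape
    smax = int(max(2, states.max() if max_state is None else max_state))
    domain = range(smax + 1)
    cost = (
        (lambda a, b: int(a != b))
        if criterion == "unordered"
        else (lambda a, b: abs(a - b))
    )

    def internal_nodes(t):
        return 0 if isinstance(t, int) else 1 + internal_nodes(t[0]) + internal_nodes(t[1])

    def seg_score(t, j, labeling):
        it = iter(labeling)

        def rec(node, parent_state):
            if isinstance(node, int):
                return cost(parent_state, states[node, j])
            s = next(it)
            return (
                cost(parent_state, s)
                + rec(node[0], s)
                + rec(node[1], s)
            )

        return rec(t, ROOT_STATE)

    best = np.inf
    for t in all_rooted_topologies(n):
        k = internal_nodes(t)
        total = 0
        for j in range(nseg):
            total += min(
                seg_score(t, j, lab) for lab in itertools.product(domain, repeat=k)
            )
        best = min(best, total)
    return int(best)


def independent_sankoff(tree, criterion="unordered"):
    """Plain per-segment Sankoff DP over the returned topology."""
    table = tree.table
    smax = int(max(2, table.states.max())) if table.n_segments else 2
    domain = list(range(smax + 1))
    cost = (
        (lambda a, b: int(a != b))
        if criterion == "unordered"
        else (lambda a, b: abs(a - b))
    )
    total = 0
    for j in range(table.n_segments):
        def rec(node):
            ch = tree.children[node]
            if not ch:
                leaf_state = tree.states[node][j]
                return {s: (0 if s == leaf_state else 10**9) for s in domain}
            out = {}
            child_costs = [rec(c) for c in ch]
            for s in domain:
                out[s] = sum(
                    min(cost(s, t) + cv[t] for t in domain) for cv in child_costs
                )
            return out

        costs = {
            s: sum(
                min(cost(s, t) + rec(c)[t] for t in domain)
                for c in tree.children[tree.root]
            )
            for s in domain
        }
        total += costs[ROOT_STATE]
    return total


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestEdgeLength:
    def test_identical_states_zero(self):
        t = table_from_states([[2, 3], [2, 3]], ["a", "b"])
        assert edge_length_mb([2, 3], [2, 3], t) == 0.0

    def test_single_differing_segment(self):
        t = table_from_states([[2], [3]], ["a", "b"], seg_len_bp=2_500_000)
        assert edge_length_mb([2], [3], t) == pytest.approx(2.5)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 6, size=(2, 30))
        lengths = rng.integers(1, 10, size=30) * 1_000_000
        starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        t = SegmentTable(
            chromosomes=np.array(["c1"] * 30, dtype=object),
            starts=starts,
            ends=starts + lengths,
            lengths_bp=lengths,
            states=states,
            labels=["a", "b"],
        )
        manual = sum(
            l for l, u, v in zip(lengths, states[0], states[1]) if u != v
        ) / 1e6
        assert edge_length_mb(states[0], states[1], t) == pytest.approx(manual)

    def test_length_mismatch_rejected(self):
        t = table_from_states([[2, 3], [2, 3]], ["a", "b"])
        with pytest.raises(ValueError):
            edge_length_mb([2], [2, 3], t)


class TestParsimonySearch:
    def test_single_leaf_tree(self):
        t = table_from_states([[3]], ["C1"])
        tree = parsimony_tree(t)
        assert tree.score == 1
        assert tree.leaves() == ["C1"]
        assert tree.edge_lengths["C1"] == pytest.approx(5.0)

    def test_three_leaf_example_against_enumeration(self):
        """L1=(3,2), L2=(3,4), L3=(2,2): the two 3-carrying leaves are
        sisters below an internal node at (3,2)."""
        states = [[3, 2], [3, 4], [2, 2]]
        t = table_from_states(states, ["L1", "L2", "L3"])
        for criterion, expected in (("unordered", 2), ("wagner", 3)):
            oracle = brute_force_min_score(states, criterion)
            assert oracle == expected
            tree = parsimony_tree(t, criterion=criterion)
            assert tree.score == oracle
            # L1 and L2 are sisters: same parent, carrying state (3,2)
            p1, p2 = tree.parent["L1"], tree.parent["L2"]
            assert p1 == p2
            assert tree.states[p1].tolist() == [3, 2]

    @pytest.mark.parametrize("criterion", ["unordered", "wagner"])
    def test_search_matches_full_enumeration_oracle(self, criterion):
        """4-leaf random instances vs enumeration over every topology and
        every internal labeling."""
        rng = np.random.default_rng(21)
        for _ in range(3):
            states = rng.integers(0, 4, size=(4, 4))
            t = table_from_states(states, [f"L{i}" for i in range(4)])
            tree = parsimony_tree(t, criterion=criterion)
            assert tree.score == brute_force_min_score(states, criterion)

    def test_branch_and_bound_equals_exhaustive(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            states = rng.integers(0, 6, size=(n, 10))
            t = table_from_states(states, [f"L{i}" for i in range(n)])
            ex = parsimony_tree(t, method="exhaustive")
            bb = parsimony_tree(t, method="branch-and-bound")
            assert ex.score == bb.score
            assert ex.to_newick() == bb.to_newick()  # same tie-broken tree

    def test_score_matches_independent_sankoff(self):
        rng = np.random.default_rng(23)
        states = rng.integers(0, 5, size=(5, 6))
        t = table_from_states(states, [f"L{i}" for i in range(5)])
        tree = parsimony_tree(t)
        assert tree.score == independent_sankoff(tree, "unordered")

    def test_assigned_states_realize_the_score(self):
        """Counting state changes along the labeled tree reproduces the
        reported score (the labeling is a minimum-change labeling)."""
        rng = np.random.default_rng(24)
        states = rng.integers(0, 5, size=(5, 8))
        t = table_from_states(states, [f"L{i}" for i in range(5)])
        tree = parsimony_tree(t)
        changes = sum(
            int(np.sum(tree.states[c] != tree.states[tree.parent[c]]))
            for c in tree.parent
        )
        assert changes == tree.score

    def test_root_state_is_all_diploid(self):
        rng = np.random.default_rng(25)
        states = rng.integers(0, 5, size=(4, 6))
        t = table_from_states(states, [f"L{i}" for i in range(4)])
        tree = parsimony_tree(t)
        assert np.all(tree.states[tree.root] == 2)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(26)
        states = rng.integers(2, 4, size=(5, 4))  # many ties likely
        t = table_from_states(states, [f"L{i}" for i in range(5)])
        assert parsimony_tree(t).to_newick() == parsimony_tree(t).to_newick()

    def test_too_many_leaves_refused(self):
        states = np.full((13, 2), 2)
        states[:, 0] = np.arange(13) % 5
        t = table_from_states(states, [f"L{i}" for i in range(13)])
        with pytest.raises(ValueError, match="exceeds"):
            parsimony_tree(t)

    def test_recovers_known_clone_topology(self, demo_genome):
        """Noise-free clones simulated along a known tree: the parsimony
        tree groups the two derived sisters together."""
        clones = [
            cc.CloneSpec("A", None, []),
            cc.CloneSpec("B", "A", [("chr1", 0, 20, 1)]),
            cc.CloneSpec("C", "B", [("chr2", 0, 15, 1)]),
            cc.CloneSpec("D", "B", [("chr3", 0, 10, -1)]),
            cc.CloneSpec("E", "A", [("chr5", 0, 24, 1)]),
        ]
        prof = cc.realize_clone_profiles(clones, demo_genome)
        profiles = [
            make_profile(demo_genome, prof[c], i + 1, passage=c)
            for i, c in enumerate("BCDE")
        ]
        table = cc.merge_segments(profiles, demo_genome)
        tree = parsimony_tree(table, early_labels=[p.label for p in profiles])
        # C and D share the B-branch gain; E split off independently
        pc, pd = tree.parent["C_C2"], tree.parent["D_C3"]
        rc = tree.root_distance("C_C2")
        assert tree.root_distance("E_C4") == pytest.approx(120.0)  # 24 x 5 Mb
        # C and D coalesce below the same internal node carrying B's gain
        assert pc == pd or tree.parent[pc] == pd or tree.parent[pd] == pc


class TestRootDistance:
    def test_root_is_zero(self):
        t = table_from_states([[3]], ["C1"])
        tree = parsimony_tree(t)
        assert tree.root_distance(tree.root) == 0.0

    def test_path_additivity(self, small_genome):
        a = make_profile(small_genome, [3, 3, 2, 2], 1)
        b = make_profile(small_genome, [3, 3, 3, 2], 2)
        table = cc.merge_segments([a, b], small_genome)
        tree = parsimony_tree(table)
        for leaf in tree.leaves():
            # brute-force path walk
            d, node = 0.0, leaf
            while node != tree.root:
                d += tree.edge_lengths[node]
                node = tree.parent[node]
            assert tree.root_distance(leaf) == pytest.approx(d)

    def test_unknown_node_rejected(self):
        tree = parsimony_tree(table_from_states([[3]], ["C1"]))
        with pytest.raises(ValueError):
            tree.root_distance("nope")


class TestAttachment:
    def _early_tree(self, genome):
        e1 = make_profile(genome, np.full(genome.n_bins, 2), 1, passage="P3")
        states2 = np.full(genome.n_bins, 2)
        states2[:20] = 3
        e2 = make_profile(genome, states2, 2, passage="P3")
        est = cc.ParsimonyPhylogeny().fit([e1, e2])
        return est, [e1, e2]

    def test_identical_late_cluster_attaches_at_zero(self, demo_genome):
        est, early = self._early_tree(demo_genome)
        states2 = np.full(demo_genome.n_bins, 2)
        states2[:20] = 3
        late = [make_profile(demo_genome, states2, 1, passage="P14")]
        tree, log = attach_late_clusters(est.tree_, late, early, demo_genome)
        assert log.records == [("P14_C1", "P3_C2", 0.0)]
        assert tree.parent["P14_C1"] == "P3_C2"
        assert tree.root_distance("P14_C1") == tree.root_distance("P3_C2")

    def test_late_chain_attaches_in_distance_order(self, demo_genome):
        """A late cluster closer to another late cluster than to any early
        leaf must wait until that late cluster is placed."""
        est, early = self._early_tree(demo_genome)
        base = np.full(demo_genome.n_bins, 2)
        base[:20] = 3
        l1 = base.copy()
        l1[50:60] = 4  # 10 bins from P3_C2
        l2 = l1.copy()
        l2[100:102] = 1  # 2 bins from late1, 12 from P3_C2
        late = [
            make_profile(demo_genome, l1, 1, passage="P14"),
            make_profile(demo_genome, l2, 2, passage="P14"),
        ]
        tree, log = attach_late_clusters(est.tree_, late, early, demo_genome)
        assert [r[0] for r in log.records] == ["P14_C1", "P14_C2"]
        assert log.records[0][1] == "P3_C2"
        assert log.records[1][1] == "P14_C1"
        assert log.records[1][2] == pytest.approx(10.0)  # 2 x 5 Mb bins
        # oracle: full pairwise distance matrix confirms the greedy order
        bl = demo_genome.bin_lengths
        d = lambda x, y: float(bl[x != y].sum() / 1e6)
        assert d(l2, l1) < min(d(l2, early[0].state_cn), d(l2, early[1].state_cn))

    def test_each_step_achieves_global_minimum(self, demo_genome):
        rng = np.random.default_rng(31)
        early = []
        for i in range(3):
            s = np.full(demo_genome.n_bins, 2)
            s[rng.integers(0, 150) : :][:20] += 1
            early.append(make_profile(demo_genome, s, i + 1, passage="P3"))
        est = cc.ParsimonyPhylogeny().fit(early)
        late = []
        for i in range(3):
            s = np.full(demo_genome.n_bins, 2)
            s[rng.integers(0, 150) : :][:25] += rng.choice([1, 2])
            late.append(make_profile(demo_genome, s, i + 1, passage="P14"))
        tree, log = attach_late_clusters(est.tree_, late, early, demo_genome)
        joint = tree.joint_table
        for (x, y, dist), (A, B) in zip(log.records, log.snapshots):
            pairs = [
                edge_length_mb(joint.states_of(a), joint.states_of(b), joint)
                for a in A
                for b in B
            ]
            assert dist == pytest.approx(min(pairs))

    def test_attachment_preserves_early_tree(self, demo_genome):
        est, early = self._early_tree(demo_genome)
        before_newick = est.tree_.to_newick()
        before_states = {k: v.copy() for k, v in est.tree_.states.items()}
        late = [
            make_profile(
                demo_genome,
                np.full(demo_genome.n_bins, 3),
                1,
                passage="P14",
            )
        ]
        tree, _ = attach_late_clusters(est.tree_, late, early, demo_genome)
        assert est.tree_.to_newick() == before_newick
        for k, v in before_states.items():
            assert np.array_equal(tree.states[k], v)
            assert tree.edge_lengths.get(k) == est.tree_.edge_lengths.get(k)

    def test_tie_breaks_are_deterministic(self, demo_genome):
        est, early = self._early_tree(demo_genome)
        mk = lambda cid: make_profile(
            demo_genome, np.full(demo_genome.n_bins, 2), cid, passage="P14"
        )
        late = [mk(2), mk(1)]  # both identical to early leaf P3_C1
        _, log1 = attach_late_clusters(est.tree_, late, early, demo_genome)
        _, log2 = attach_late_clusters(est.tree_, late, early, demo_genome)
        assert log1.records == log2.records
        assert log1.records[0][0] == "P14_C1"  # smallest label wins the tie


class TestNewick:
    def test_root_only_tree(self):
        tree = cc.ParsimonyTree(table_from_states([[2, 2]], ["x"]).__class__(
            chromosomes=np.array([], dtype=object),
            starts=np.array([], dtype=np.int64),
            ends=np.array([], dtype=np.int64),
            lengths_bp=np.array([], dtype=np.int64),
            states=np.zeros((0, 0), dtype=np.int64),
            labels=[],
        ))
        assert tree.to_newick() == "diploid;"

    def test_round_trip_three_leaves(self, tmp_path, small_genome):
        a = make_profile(small_genome, [3, 3, 2, 2], 1)
        b = make_profile(small_genome, [3, 3, 3, 2], 2)
        c = make_profile(small_genome, [1, 2, 2, 2], 3)
        tree = parsimony_tree(cc.merge_segments([a, b, c], small_genome))
        path = tmp_path / "t.nwk"
        cc.write_newick(tree, path)
        import dendropy

        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        leaves = {l.taxon.label for l in parsed.leaf_node_iter()}
        assert leaves == set(tree.leaves())
        for leaf in parsed.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(
                tree.edge_lengths[leaf.taxon.label], abs=1e-9
            )

    def test_randomized_round_trips(self, demo_genome):
        import dendropy

        rng = np.random.default_rng(33)
        for trial in range(20):
            n = int(rng.integers(2, 6))
            profiles = []
            for i in range(n):
                s = np.full(demo_genome.n_bins, 2)
                s[rng.integers(0, 150) : :][:15] += int(rng.choice([-1, 1, 2]))
                profiles.append(
                    make_profile(demo_genome, np.clip(s, 0, None), i + 1)
                )
            tree = parsimony_tree(cc.merge_segments(profiles, demo_genome))
            parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
            # identical leaf sets and root-to-leaf path lengths
            for leaf in parsed.leaf_node_iter():
                depth = leaf.distance_from_root()
                assert depth == pytest.approx(
                    tree.root_distance(leaf.taxon.label), abs=1e-6
                )


class TestHierarchyAgreement:
    def test_closest_pair_agrees_between_methods(self, demo_genome):
        """On clean clone profiles the pair with the smallest Canberra
        distance is also the pair with the smallest Mb distance."""
        rng = np.random.default_rng(34)
        profiles = []
        for i in range(4):
            s = np.full(demo_genome.n_bins, 2)
            s[i * 30 : i * 30 + 10 * (i + 1)] += 1
            profiles.append(make_profile(demo_genome, s, i + 1))
        table = cc.merge_segments(profiles, demo_genome)
        from scipy.spatial.distance import squareform

        res = cc.hierarchical_check(profiles)
        D_canb = squareform(res.distances)
        n = len(profiles)
        D_mb = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                D_mb[i, j] = edge_length_mb(
                    table.states_of(profiles[i].label),
                    table.states_of(profiles[j].label),
                    table,
                )
        iu = np.triu_indices(n, 1)
        assert np.argmin(D_canb[iu]) == np.argmin(D_mb[iu])
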