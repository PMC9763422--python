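"""Diploid-rooted maximum-parsimony trees over copy-number segment states.

The characters are the merged segments of a :class:`~cnclone.segments.SegmentTable`,
each with an integer copy-number state per cluster. The tree is rooted at a
copy-number-neutral diploid ancestor (state 2 everywhere), a fixed anchor
above the searched topology. Under the default *unordered* criterion any
state-to-state change costs 1 (the score counts state changes); a *wagner*
mode costs changes by |delta CN| for sensitivity analysis.

The search is exact: exhaustive enumeration of rooted binary topologies for
small leaf sets and branch-and-bound (with the partial-tree score as lower
bound) above, both scored by Sankoff dynamic programming vectorized over
segments. Edge lengths are genomic, not change counts: the summed length of
all segments whose state differs across the edge, in megabases.

Late-passage clusters are not part of the search; they are attached
greedily, each step picking the globally closest (late, placed) pair under
the megabase metric, mirroring serial observation of the same culture.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genome import BinnedGenome
from .segments import SegmentTable, merge_segments

__all__ = [
    "ParsimonyTree",
    "AttachmentLog",
    "ParsimonyPhylogeny",
    "parsimony_tree",
    "edge_length_mb",
    "attach_late_clusters",
    "root_distance",
    "sankoff_score",
    "write_newick",
]

_BIG = np.float64(1e12)
ROOT_LABEL = "diploid"
ROOT_STATE = 2


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------

class ParsimonyTree:
    """Rooted tree with per-node integer CN states and Mb edge lengths.

    Nodes are identified by string names; the root is the diploid anchor
    ``"diploid"``. ``states[name]`` is the per-segment state vector of a
    node on ``table`` (late-attached leaves instead carry states on
    ``joint_table`` in ``joint_states``). ``edge_lengths[name]`` is the
    length in megabases of the edge above ``name``.
    """

    def __init__(self, table: SegmentTable, score: int = 0):
        self.table = table
        self.score = int(score)
        self.root = ROOT_LABEL
        self.parent: dict = {}
        self.children: dict = {self.root: []}
        self.states: dict = {
            self.root: np.full(table.n_segments, ROOT_STATE, dtype=np.int64)
        }
        self.edge_lengths: dict = {}
        self.joint_table: SegmentTable | None = None
        self.joint_states: dict = {}

    def add_node(self, name: str, parent: str, states, length_mb: float) -> None:
        if name in self.children:
            raise ValueError(f"duplicate node name {name!r}")
        if parent not in self.children:
            raise ValueError(f"unknown parent {parent!r}")
        self.parent[name] = parent
        self.children[parent].append(name)
        self.children[name] = []
        if states is not None:
            self.states[name] = np.asarray(states, dtype=np.int64)
        self.edge_lengths[name] = float(length_mb)

    @property
    def nodes(self) -> list:
        return list(self.children.keys())

    def leaves(self) -> list:
        return [n for n, ch in self.children.items() if not ch and n != self.root]

    def root_distance(self, node: str) -> float:
        """Summed edge length (Mb) along the path from the root to a node."""
        if node not in self.children:
            raise ValueError(f"unknown node {node!r}")
        d = 0.0
        while node != self.root:
            d += self.edge_lengths[node]
            node = self.parent[node]
        return d

    # -- Newick ------------------------------------------------------------

    def _newick_of(self, node: str) -> str:
        ch = self.children[node]
        label = node
        if not ch:
            return label
        inner = ",".join(
            f"{self._newick_of(c)}:{self.edge_lengths[c]:.6f}" for c in ch
        )
        return f"({inner}){label}"

    def to_newick(self) -> str:
        return self._newick_of(self.root) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


@dataclass
class AttachmentLog:
    """Trace of the greedy late-cluster attachment.

    One record per iteration: the attached cluster, its host node, the Mb
    distance, and snapshots of the unplaced (A) and placed (B) sets at the
    moment of the choice.
    """

    records: list = field(default_factory=list)  # (cluster, host, distance_mb)
    snapshots: list = field(default_factory=list)  # (set A, set B)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["attached_cluster", "host_node", "distance_mb"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Megabase edge metric
# ---------------------------------------------------------------------------

def edge_length_mb(state_u, state_v, table: SegmentTable) -> float:
    """Genomic span (Mb) of segments whose copy number differs.

    Sums ``length_bp`` over segments where the two state vectors disagree
    and divides by 1e6. Symmetric; zero iff the states are identical.
    """
    u = np.asarray(state_u, dtype=np.int64)
    v = np.asarray(state_v, dtype=np.int64)
    if u.shape != v.shape or u.size != table.n_segments:
        raise ValueError(
            f"state vectors ({u.size}, {v.size}) must both match the "
            f"table's {table.n_segments} segments"
        )
    return float(table.lengths_bp[u != v].sum() / 1e6)


# ---------------------------------------------------------------------------
# Sankoff dynamic programming, vectorized over segments
# ---------------------------------------------------------------------------

def _cost_matrix(n_states: int, criterion: str) -> np.ndarray:
    s = np.arange(n_states)
    if criterion == "unordered":
        return (s[:, None] != s[None, :]).astype(np.float64)
    if criterion == "wagner":
        return np.abs(s[:, None] - s[None, :]).astype(np.float64)
    raise ValueError(f"unknown criterion {criterion!r}")


def _leaf_cost(states: np.ndarray, n_states: int) -> np.ndarray:
    """(n_states, n_segments) leaf cost: 0 at the observed state, inf else."""
    nseg = states.size
    out = np.full((n_states, nseg), _BIG)
    out[states, np.arange(nseg)] = 0.0
    return out


def _child_contrib(child_cost: np.ndarray, C: np.ndarray, unordered: bool) -> np.ndarray:
    """min over child states of transition cost + child subtree cost."""
    if unordered:
        cheapest = child_cost.min(axis=0) + 1.0
        return np.minimum(child_cost, cheapest)
    return (C[:, :, None] + child_cost[None, :, :]).min(axis=1)


def _topology_cost(topo, leaf_costs, C, unordered) -> np.ndarray:
    if isinstance(topo, (int, np.integer)):
        return leaf_costs[topo]
    left = _topology_cost(topo[0], leaf_costs, C, unordered)
    right = _topology_cost(topo[1], leaf_costs, C, unordered)
    return _child_contrib(left, C, unordered) + _child_contrib(right, C, unordered)


def _score_topology(topo, leaf_costs, C, unordered) -> int:
    """Parsimony score of a topology hung below the fixed diploid anchor."""
    top = _topology_cost(topo, leaf_costs, C, unordered)
    rooted = C[ROOT_STATE][:, None] + top
    return int(round(rooted.min(axis=0).sum()))


def sankoff_score(tree: ParsimonyTree, criterion: str = "unordered") -> int:
    """Independent parsimony score of a *given* tree topology.

    Runs Sankoff DP over the tree's own structure (ignoring its stored
    internal states), minimizing over internal labelings with the root
    fixed at the diploid state. Usable as a cross-check of the search.
    """
    table = tree.table
    n_states = int(max(ROOT_STATE, table.states.max() if table.n_segments else 0)) + 1
    C = _cost_matrix(n_states, criterion)
    unordered = criterion == "unordered"

    def rec(node: str) -> np.ndarray:
        ch = tree.children[node]
        if not ch:
            return _leaf_cost(tree.states[node], n_states)
        total = np.zeros((n_states, table.n_segments))
        for c in ch:
            total += _child_contrib(rec(c), C, unordered)
        return total

    if table.n_segments == 0:
        return 0
    total = np.zeros((n_states, table.n_segments))
    for c in tree.children[tree.root]:
        total += _child_contrib(rec(c), C, unordered)
    return int(round(total[ROOT_STATE].sum()))


# ---------------------------------------------------------------------------
# Topology enumeration and search
# ---------------------------------------------------------------------------

def _insert_everywhere(topo, leaf):
    """All topologies obtained by grafting ``leaf`` onto one edge of ``topo``."""
    yield (topo, leaf)  # above the current (sub)tree root
    if isinstance(topo, tuple):
        left, right = topo
        for t in _insert_everywhere(left, leaf):
            yield (t, right)
        for t in _insert_everywhere(right, leaf):
            yield (left, t)


def _canonical(topo):
    """(ordered topology, min leaf, leaf sequence) with children sorted by min leaf."""
    if isinstance(topo, (int, np.integer)):
        return topo, topo, (topo,)
    l, lmin, lseq = _canonical(topo[0])
    r, rmin, rseq = _canonical(topo[1])
    if lmin <= rmin:
        return (l, r), lmin, lseq + rseq
    return (r, l), rmin, rseq + lseq


def _search_topologies(n_leaves, leaf_costs, C, unordered, exhaustive: bool):
    """Return (best score, list of optimal topologies).

    Leaves are inserted in index order; with ``exhaustive=False`` a branch
    is pruned when the partial tree's own score already exceeds the best
    complete score (the score is monotone under leaf addition), which keeps
    every tie.
    """
    best = {"score": np.inf, "topos": []}
    if not exhaustive:
        # greedy stepwise-addition tree as the initial upper bound
        topo = 0
        for k in range(1, n_leaves):
            topo = min(
                _insert_everywhere(topo, k),
                key=lambda t: _score_topology(t, leaf_costs, C, unordered),
            )
        best["score"] = _score_topology(topo, leaf_costs, C, unordered)

    def rec(topo, k):
        s = _score_topology(topo, leaf_costs, C, unordered)
        if not exhaustive and s > best["score"]:
            return
        if k == n_leaves:
            if s < best["score"]:
                best["score"], best["topos"] = s, [topo]
            elif s == best["score"]:
                best["topos"].append(topo)
            return
        for t in _insert_everywhere(topo, k):
            rec(t, k + 1)

    rec(0, 1)
    return int(best["score"]), best["topos"]


def _assign_states(topo, leaf_costs, C, unordered, table, labels):
    """Build a ParsimonyTree from an optimal topology.

    Internal states come from the Sankoff backtrace, top-down from the
    diploid anchor; among minimum-cost states the one closest to the parent
    state is taken, then the smallest, which keeps labelings deterministic
    and biased toward gradual change.
    """
    n_states = C.shape[0]
    nseg = table.n_segments
    counter = itertools.count(1)

    # bottom-up cost vectors, memoized per sub-topology position
    def costs(t):
        if isinstance(t, (int, np.integer)):
            return leaf_costs[t]
        return _child_contrib(costs(t[0]), C, unordered) + _child_contrib(
            costs(t[1]), C, unordered
        )

    def choose(cost_vec, parent_state):
        # per segment: argmin of transition+subtree cost, ties by |s-p| then s
        tot = C[parent_state].T + cost_vec  # (n_states, nseg)
        m = tot.min(axis=0)
        s = np.arange(n_states)
        penalty = np.abs(s[:, None] - parent_state[None, :]) * (n_states + 1) + s[:, None]
        key = np.where(tot <= m + 1e-9, penalty, np.inf)
        return key.argmin(axis=0).astype(np.int64)

    score = _score_topology(topo, leaf_costs, C, unordered)
    tree = ParsimonyTree(table, score=score)
    root_state = tree.states[tree.root]

    def build(t, parent_name, parent_state):
        if isinstance(t, (int, np.integer)):
            name = labels[t]
            st = table.states_of(name)
            tree.add_node(name, parent_name, st, edge_length_mb(parent_state, st, table))
            return
        st = choose(costs(t), parent_state)
        name = f"N{next(counter)}"
        tree.add_node(name, parent_name, st, edge_length_mb(parent_state, st, table))
        build(t[0], name, st)
        build(t[1], name, st)

    build(topo, tree.root, root_state)
    return tree


def parsimony_tree(
    table: SegmentTable,
    early_labels=None,
    criterion: str = "unordered",
    method: str = "auto",
    max_exhaustive: int = 7,
    max_leaves: int = 12,
) -> ParsimonyTree:
    """Exact maximum-parsimony tree of the early-passage clusters.

    Parameters
    ----------
    table :
        Merged segment table; rows named in ``early_labels`` become leaves.
    early_labels :
        Cluster labels to place (default: all rows of the table).
    criterion : {"unordered", "wagner"}
        Unordered (any change costs 1, the default) or ordered by |delta|.
    method : {"auto", "exhaustive", "branch-and-bound"}
        ``auto`` enumerates exhaustively up to ``max_exhaustive`` leaves and
        uses branch-and-bound above; both are exact.

    Ties in score are broken by the lexicographically smallest canonical
    leaf-label sequence, so results are reproducible.
    """
    labels = list(early_labels) if early_labels is not None else list(table.labels)
    for lab in labels:
        if lab not in table.labels:
            raise ValueError(f"unknown cluster label {lab!r}")
    n = len(labels)
    if n < 1:
        raise ValueError("need at least one early cluster")
    if n > max_leaves:
        raise ValueError(
            f"{n} leaves exceeds the exact-search limit of {max_leaves}; "
            "reduce the cluster count or raise max_leaves"
        )
    labels = sorted(labels)  # canonical leaf ordering

    if table.n_segments == 0:
        # degenerate: no heterogeneity; star of zero-length edges at the root
        tree = ParsimonyTree(table, score=0)
        empty = np.zeros(0, dtype=np.int64)
        for lab in labels:
            tree.add_node(lab, tree.root, empty, 0.0)
        return tree

    n_states = int(max(ROOT_STATE, table.states.max())) + 1
    C = _cost_matrix(n_states, criterion)
    unordered = criterion == "unordered"
    leaf_costs = [_leaf_cost(table.states_of(lab), n_states) for lab in labels]

    if method == "auto":
        exhaustive = n <= max_exhaustive
    elif method == "exhaustive":
        exhaustive = True
    elif method == "branch-and-bound":
        exhaustive = False
    else:
        raise ValueError(f"unknown method {method!r}")

    _, topos = _search_topologies(n, leaf_costs, C, unordered, exhaustive)
    best_topo = min(topos, key=lambda t: _canonical(t)[2])
    ordered, _, _ = _canonical(best_topo)
    return _assign_states(ordered, leaf_costs, C, unordered, table, labels)


# ---------------------------------------------------------------------------
# Greedy attachment of late-passage clusters
# ---------------------------------------------------------------------------

def attach_late_clusters(
    tree: ParsimonyTree, late_profiles, early_profiles, genome: BinnedGenome
):
    """Attach late-passage clusters to an early tree by minimal Mb distance.

    Early and late cluster profiles are re-segmented jointly so their state
    vectors are comparable; distances use :func:`edge_length_mb` on that
    joint table. Set A holds unplaced late clusters, set B the placed leaf
    clusters; each iteration the globally closest pair (x in A, y in B) is
    attached (x becomes a daughter of y), x moves to B, until A is empty.
    Ties pick the smallest (x label, y label) pair. The early tree's
    topology, states and edge lengths are not modified; the returned tree is
    a copy carrying the new leaves and the joint segmentation.
    """
    late_profiles = list(late_profiles)
    early_profiles = list(early_profiles)
    joint = merge_segments(early_profiles + late_profiles, genome)

    out = copy.deepcopy(tree)
    out.joint_table = joint
    early_leaves = sorted(out.leaves())
    for lab in early_leaves:
        out.joint_states[lab] = joint.states_of(lab)

    log = AttachmentLog()
    A = sorted(p.label for p in late_profiles)
    B = list(early_leaves)
    while A:
        pairs = [
            (edge_length_mb(joint.states_of(x), out.joint_states[y], joint), x, y)
            for x in A
            for y in B
        ]
        d, x, y = min(pairs)  # tuple order = distance, then (x, y) labels
        log.snapshots.append((tuple(A), tuple(B)))
        log.records.append((x, y, d))
        out.add_node(x, y, None, d)
        out.joint_states[x] = joint.states_of(x)
        A.remove(x)
        B.append(x)
        B.sort()
    return out, log


def root_distance(tree: ParsimonyTree, node: str) -> float:
    """Megabase path length from the diploid root to ``node``."""
    return tree.root_distance(node)


def write_newick(tree: ParsimonyTree, path) -> None:
    tree.write_newick(path)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class ParsimonyPhylogeny(BaseEstimator):
    """Fit a diploid-rooted maximum-parsimony phylogeny to cluster profiles.

    ``fit`` merges the early-passage cluster profiles into segments, runs
    the exact parsimony search and stores the tree; ``attach`` adds
    late-passage clusters greedily.

    Attributes
    ----------
    table_ : SegmentTable of the early profiles (merged + filtered)
    tree_ : the fitted ParsimonyTree
    score_ : parsimony score (total state changes)
    attachment_log_ : AttachmentLog, set by :meth:`attach`
    """

    def __init__(
        self,
        criterion: str = "unordered",
        method: str = "auto",
        max_exhaustive: int = 7,
        max_leaves: int = 12,
    ):
        self.criterion = criterion
        self.method = method
        self.max_exhaustive = max_exhaustive
        self.max_leaves = max_leaves

    def fit(self, X, y=None):
        """X: list of early-passage ClusterProfile (sharing one genome)."""
        profiles = list(X)
        if not profiles:
            raise ValueError("need at least one early cluster profile")
        genome = profiles[0].genome
        if genome is None:
            raise ValueError("cluster profiles must carry their genome")
        self.early_profiles_ = profiles
        self.genome_ = genome
        early_labels = [p.label for p in profiles]
        if len(profiles) == 1:
            # merge against a diploid anchor so segments are scored vs root
            from .cnmatrix import ClusterProfile

            diploid = ClusterProfile(
                cluster_id=0,
                cell_count=1,
                mean_cn=np.full(genome.n_bins, 2.0),
                state_cn=np.full(genome.n_bins, 2, dtype=np.int64),
                chromosome_estimate=2.0 * len(genome.chromosome_slices()),
                passage_label="root",
                genome=genome,
            )
            self.table_ = merge_segments(profiles + [diploid], genome)
        else:
            self.table_ = merge_segments(profiles, genome)
        self.tree_ = parsimony_tree(
            self.table_,
            early_labels=early_labels,
            criterion=self.criterion,
            method=self.method,
            max_exhaustive=self.max_exhaustive,
            max_leaves=self.max_leaves,
        )
        self.score_ = self.tree_.score
        return self

    def attach(self, late_profiles):
        tree, log = attach_late_clusters(
            self.tree_, late_profiles, self.early_profiles_, self.genome_
        )
        self.tree_ = tree
        self.attachment_log_ = log
        return tree
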