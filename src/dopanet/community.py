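"""Community detection for weighted connectivity graphs.

Implements modularity maximisation with the Louvain heuristic on dense
non-negative weight matrices, plus the agreement-matrix consensus-clustering
loop used to stabilise the stochastic partitions, and Sorensen-Dice overlap
scoring for comparing node sets.

Modularity of a partition M on a weighted graph with weights w_ij is

    Q = (1/v) * sum_ij (w_ij - gamma * s_i * s_j / v) * delta(M_i, M_j)

where v = sum_ij w_ij (both orderings counted), s_i = sum_j w_ij, and gamma
is the resolution parameter (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Partition", "OverlapResult", "ConsensusError",
    "modularity", "louvain_partition", "consensus_partition",
    "agreement_matrix", "group_consensus", "dice_overlap",
    "zero_negative_weights", "label_networks",
]


class ConsensusError(RuntimeError):
    pass


@dataclass
class Partition:
    """Node -> community assignment with its modularity score."""

    labels: np.ndarray
    q: float = np.nan
    gamma: float = 1.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def canonical(self) -> np.ndarray:
        """Labels renumbered 0..k-1 in order of first appearance."""
        _, first = np.unique(self.labels, return_index=True)
        order = self.labels[np.sort(first)]
        remap = {int(c): i for i, c in enumerate(order)}
        return np.array([remap[int(c)] for c in self.labels], dtype=np.int64)

    def community_members(self) -> dict[int, np.ndarray]:
        canon = self.canonical()
        return {int(c): np.flatnonzero(canon == c)
                for c in range(canon.max() + 1)}


@dataclass
class OverlapResult:
    dsc: float
    size_x: int
    size_y: int
    intersection: int


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative (zero negatives upstream)")
    return w


def zero_negative_weights(z: np.ndarray) -> np.ndarray:
    """Non-negative graph from a signed matrix: negatives and diagonal to 0."""
    w = np.array(z, dtype=float, copy=True)
    w[~np.isfinite(w)] = 0.0
    w[w < 0] = 0.0
    np.fill_diagonal(w, 0.0)
    return 0.5 * (w + w.T)


def modularity(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Exact evaluation of Q for a labelling of a non-negative graph."""
    w = _check_weights(w)
    labels = np.asarray(labels)
    if len(labels) != w.shape[0]:
        raise ValueError("partition must cover every node")
    v = w.sum()
    if v <= 0:
        raise ValueError("graph has zero total strength")
    s = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        m = labels == c
        q += w[np.ix_(m, m)].sum() - gamma * s[m].sum() ** 2 / v
    return float(q / v)


def _one_level(w: np.ndarray, gamma: float,
               rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Louvain local-moving phase: best-gain moves, seeded node order.

    `w` may carry self-loops (aggregated levels); the gain of moving node i
    to community c is proportional to w_{i->c} - gamma * s_i * Sigma_c / v
    with i removed from its community first.
    """
    n = w.shape[0]
    labels = np.arange(n)
    s = w.sum(axis=1)
    v = w.sum()
    sigma = s.copy()                      # community total strengths
    moved_any = False
    while True:
        moved = False
        for i in rng.permutation(n):
            li = labels[i]
            row = w[i].copy()
            row[i] = 0.0                  # self-loop never crosses communities
            w_to = np.bincount(labels, weights=row, minlength=n)
            sigma[li] -= s[i]
            gains = w_to - gamma * s[i] * sigma / v
            best = int(np.argmax(gains))  # ties -> lowest community index
            if gains[best] <= gains[li] + 1e-12:
                best = li
            labels[i] = best
            sigma[best] += s[i]
            if best != li:
                moved = True
        if not moved:
            break
        moved_any = True
    return labels, moved_any


def _aggregate(w: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    comms, inv = np.unique(labels, return_inverse=True)
    k = len(comms)
    onehot = np.eye(k)[inv]
    return onehot.T @ w @ onehot, inv


def louvain_partition(w: np.ndarray, gamma: float = 1.0,
                      seed: int = 0) -> Partition:
    """Two-phase greedy Louvain; deterministic given the seed.

    The returned Q is never below that of the single-community partition
    (zero at gamma = 1).
    """
    w = _check_weights(w)
    if w.sum() <= 0:
        raise ValueError("graph has zero total strength")
    rng = np.random.default_rng(seed)
    n = w.shape[0]
    node_labels = np.arange(n)          # original node -> current agg node
    w_level = np.array(w, copy=True)
    prev_q = -np.inf
    while True:
        labels, moved = _one_level(w_level, gamma, rng)
        if not moved:
            break
        w_level, inv = _aggregate(w_level, labels)
        node_labels = inv[node_labels]  # inv: agg node -> compact community
        q = modularity(w, node_labels, gamma)
        if q < prev_q - 1e-9:
            raise AssertionError("Louvain decreased modularity across levels")
        prev_q = q
        if w_level.shape[0] == 1:
            break
    q = modularity(w, node_labels, gamma)
    single = np.zeros(n, dtype=np.int64)
    q_single = modularity(w, single, gamma)
    if q < q_single:
        return Partition(single, q=q_single, gamma=gamma)
    canon = Partition(node_labels, q=q, gamma=gamma)
    return Partition(canon.canonical(), q=q, gamma=gamma)


def agreement_matrix(label_sets: list[np.ndarray]) -> np.ndarray:
    """Proportion of partitions co-assigning each node pair."""
    if not label_sets:
        raise ValueError("need at least one partition")
    n = len(label_sets[0])
    d = np.zeros((n, n))
    for labels in label_sets:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("partitions cover different node sets")
        d += labels[:, None] == labels[None, :]
    return d / len(label_sets)


def _sub_seed(seed: int, round_idx: int, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), int(round_idx), int(k)])


def consensus_partition(w: np.ndarray, n_iter: int = 1000,
                        threshold: float = 0.5, gamma: float = 1.0,
                        seed: int = 0, max_rounds: int = 50) -> Partition:
    """Agreement-matrix consensus clustering of a weighted graph.

    Each round runs `n_iter` seeded Louvain partitions; if they disagree,
    their agreement matrix (entries strictly below `threshold` zeroed) is
    re-clustered. Iterates until a round is unanimous. The returned Q is
    evaluated on the *input* graph.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if max_rounds < 1:
        raise ConsensusError("no consensus possible in fewer than 1 rounds")
    w = _check_weights(w)
    current = np.array(w, copy=True)
    np.fill_diagonal(current, 0.0)
    for round_idx in range(max_rounds):
        parts = []
        for k in range(n_iter):
            rng_seed = _sub_seed(seed, round_idx, k)
            parts.append(louvain_partition(
                current, gamma=gamma,
                seed=np.random.default_rng(rng_seed).integers(2**31)))
        canon = [p.canonical() for p in parts]
        if all(np.array_equal(canon[0], c) for c in canon[1:]):
            labels = canon[0]
            return Partition(labels, q=modularity(w, labels, gamma),
                             gamma=gamma)
        d = agreement_matrix(canon)
        d[d < threshold] = 0.0
        np.fill_diagonal(d, 0.0)
        if d.sum() <= 0:
            raise ConsensusError(
                f"round {round_idx}: agreement matrix empty after "
                f"thresholding at {threshold}")
        current = d
    stats = {c.tobytes(): 0 for c in canon}
    for c in canon:
        stats[c.tobytes()] += 1
    raise ConsensusError(
        f"no consensus after {max_rounds} rounds; final round had "
        f"{len(stats)} distinct partitions over {n_iter} runs")


def group_consensus(subject_partitions: list[Partition], n_iter: int = 1000,
                    threshold: float = 0.5, gamma: float = 1.0,
                    seed: int = 0, max_rounds: int = 50) -> Partition:
    """Group partition from the mean subject co-assignment matrix."""
    n = subject_partitions[0].n_nodes
    if any(p.n_nodes != n for p in subject_partitions):
        raise ValueError("subject partitions cover different node sets")
    d = agreement_matrix([p.labels for p in subject_partitions])
    return consensus_partition(d, n_iter=n_iter, threshold=threshold,
                               gamma=gamma, seed=seed, max_rounds=max_rounds)


def dice_overlap(set_x, set_y) -> OverlapResult:
    """Sorensen-Dice coefficient DSC = 2|X n Y| / (|X| + |Y|)."""
    x, y = set(set_x), set(set_y)
    if not x and not y:
        raise ValueError("both sets are empty")
    inter = len(x & y)
    return OverlapResult(dsc=2.0 * inter / (len(x) + len(y)),
                         size_x=len(x), size_y=len(y), intersection=inter)


def label_networks(partition: Partition, apriori_dmn: np.ndarray,
                   node_ids: list[str] | None = None) -> dict:
    """Assign each empirical community to 'DMN' or 'TPN' by maximal DSC.

    `apriori_dmn` is a boolean node mask of the a-priori default-mode set;
    its complement is the a-priori task-positive set. Returns the per-node
    network labels, the empirical DMN mask, and the DSC of the empirical
    DMN/TPN node sets against the a-priori ones.
    """
    apriori_dmn = np.asarray(apriori_dmn, dtype=bool)
    if len(apriori_dmn) != partition.n_nodes:
        raise ValueError("a-priori mask does not match the partition")
    dmn_nodes = np.flatnonzero(apriori_dmn)
    tpn_nodes = np.flatnonzero(~apriori_dmn)
    network = np.empty(partition.n_nodes, dtype=object)
    for _, members in partition.community_members().items():
        d_dmn = dice_overlap(members, dmn_nodes).dsc
        d_tpn = dice_overlap(members, tpn_nodes).dsc
        if d_dmn == d_tpn:
            raise ValueError(
                "community overlaps a-priori DMN and TPN equally; "
                "cannot assign a network label")
        network[members] = "DMN" if d_dmn > d_tpn else "TPN"
    emp_dmn = network == "DMN"
    result = {
        "network": network,
        "dmn_mask": emp_dmn,
        "dsc_dmn": dice_overlap(np.flatnonzero(emp_dmn), dmn_nodes).dsc,
        "dsc_tpn": dice_overlap(np.flatnonzero(~emp_dmn), tpn_nodes).dsc,
    }
    if node_ids is not None:
        result["node_ids"] = list(node_ids)
    return result
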