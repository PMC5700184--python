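"""Module detection by Louvain maximisation of global modularity Q.

Global modularity of a partition into modules ``s = 1..m`` is

    Q = sum_s [ l_ins / L - (k_s / 2L)^2 ]

where ``l_ins`` is the (weighted) number of edges inside module *s*, ``L``
the total number of edges (total weight) in the network, and ``k_s`` the
total degree (strength) of the nodes in module *s*. The first term is the
observed fraction of within-module edges, the second the fraction expected
under the configuration null model; Q > 0.3 is the conventional indication
of modular structure.

The Louvain procedure starts from the all-singletons partition and
alternates (i) a greedy local-move phase, sweeping nodes in a seeded random
order and reassigning each to the neighbouring module with the largest
modularity gain (ties broken toward the lowest module id), with (ii) an
aggregation phase that collapses each module into a meta-node, until a full
cycle yields no further improvement. :func:`brute_force_max_q` provides an
exhaustive oracle for graphs of up to 10 nodes.
"""

from __future__ import annotations

import numpy as np

from .core import BrainGraph, ModulePartition, relabel_contiguous

__all__ = ["modularity_q", "louvain", "brute_force_max_q"]

_MAX_BRUTE_NODES = 10


def _as_labels(partition) -> np.ndarray:
    if isinstance(partition, ModulePartition):
        return partition.labels
    return np.asarray(partition, dtype=int)


def modularity_q(graph: BrainGraph, partition) -> float:
    """Global modularity Q of a partition on a (binary or weighted) graph.

    For weighted graphs, edge counts and degrees are replaced by weight
    sums and strengths. Raises on an empty graph (Q is undefined when
    L = 0).
    """
    labels = _as_labels(partition)
    adj = graph.adjacency
    if labels.shape != (adj.shape[0],):
        raise ValueError("partition labels must cover every node exactly once")
    m2 = adj.sum()  # = 2L (or twice the total weight)
    if m2 == 0:
        raise ValueError("modularity is undefined for a graph with no edges")
    same = labels[:, None] == labels[None, :]
    within = (adj * same).sum() / m2  # sum_s 2*l_ins / 2L
    strengths = adj.sum(axis=1)
    tot = np.bincount(labels, weights=strengths)
    expected = np.sum((tot / m2) ** 2)
    return float(within - expected)


def _one_level(
    neigh_idx: list[np.ndarray],
    neigh_w: list[np.ndarray],
    self_w: np.ndarray,
    rng: np.random.Generator,
    tol: float,
) -> tuple[np.ndarray, bool]:
    """Greedy local-move phase on one (possibly aggregated) graph level."""
    n = len(neigh_idx)
    strength = np.array([w.sum() for w in neigh_w]) + self_w
    m2 = strength.sum()
    labels = np.arange(n)
    tot = strength.copy()
    moved_any = False
    while True:
        gain_total = 0.0
        for i in rng.permutation(n):
            idx, w = neigh_idx[i], neigh_w[i]
            if idx.size == 0:
                continue  # isolated node stays a singleton module
            c_old = labels[i]
            tot[c_old] -= strength[i]
            # weight from i to each neighbouring community
            comm_w: dict[int, float] = {}
            for j, wij in zip(idx, w):
                cj = labels[j]
                comm_w[cj] = comm_w.get(cj, 0.0) + wij
            stay = comm_w.get(c_old, 0.0) - tot[c_old] * strength[i] / m2
            best_c, best_gain = c_old, stay
            # candidates visited in ascending module id, and only a strictly
            # larger gain replaces the incumbent: ties go to the lowest id,
            # and staying put wins a tie with any candidate
            for c in sorted(comm_w):
                if c == c_old:
                    continue
                gain = comm_w[c] - tot[c] * strength[i] / m2
                if gain > best_gain + 1e-15:
                    best_c, best_gain = c, gain
            if best_c != c_old:
                labels[i] = best_c
                moved_any = True
                gain_total += 2.0 * (best_gain - stay) / m2
            tot[labels[i]] += strength[i]
        if gain_total < tol:
            break
    return labels, moved_any


def _aggregate(
    neigh_idx: list[np.ndarray],
    neigh_w: list[np.ndarray],
    self_w: np.ndarray,
    labels: np.ndarray,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Collapse each module into a meta-node with self-loop bookkeeping."""
    m = int(labels.max()) + 1
    agg = np.zeros((m, m))
    for i in range(len(neigh_idx)):
        li = labels[i]
        np.add.at(agg[li], labels[neigh_idx[i]], neigh_w[i])
        agg[li, li] += self_w[i]
    new_self = np.diag(agg).copy()
    new_idx, new_w = [], []
    for a in range(m):
        row = agg[a].copy()
        row[a] = 0.0
        nz = np.flatnonzero(row)
        new_idx.append(nz)
        new_w.append(row[nz])
    return new_idx, new_w, new_self


def _refine(
    adj: np.ndarray, labels: np.ndarray, rng: np.random.Generator, tol: float
) -> np.ndarray:
    """One extra local-move sweep on the *original* graph starting from the
    coarse partition: single nodes may leave a merged module, which the
    aggregated meta-graph can no longer express."""
    n = adj.shape[0]
    neigh_idx = [np.flatnonzero(adj[i]) for i in range(n)]
    neigh_w = [adj[i, neigh_idx[i]] for i in range(n)]
    strength = adj.sum(axis=1)
    m2 = strength.sum()
    labels = labels.copy()
    # allow escapes to fresh singleton modules as well
    free_label = int(labels.max()) + 1
    tot = np.bincount(labels, weights=strength, minlength=free_label + 1)
    while True:
        gain_total = 0.0
        for i in rng.permutation(n):
            idx, w = neigh_idx[i], neigh_w[i]
            if idx.size == 0:
                continue
            c_old = labels[i]
            tot[c_old] -= strength[i]
            comm_w: dict[int, float] = {}
            for j, wij in zip(idx, w):
                cj = labels[j]
                comm_w[cj] = comm_w.get(cj, 0.0) + wij
            comm_w.setdefault(free_label, 0.0)
            stay = comm_w.get(c_old, 0.0) - tot[c_old] * strength[i] / m2
            best_c, best_gain = c_old, stay
            for c in sorted(comm_w):
                if c == c_old:
                    continue
                gain = comm_w[c] - tot[c] * strength[i] / m2
                if gain > best_gain + 1e-15:
                    best_c, best_gain = c, gain
            if best_c != c_old:
                labels[i] = best_c
                gain_total += 2.0 * (best_gain - stay) / m2
                if best_c == free_label:
                    free_label = int(labels.max()) + 1
                    if free_label >= tot.size:
                        tot = np.append(tot, 0.0)
            tot[labels[i]] += strength[i]
        if gain_total < tol:
            break
    return relabel_contiguous(labels)


def _q_fast(adj: np.ndarray, strengths: np.ndarray, m2: float, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    tot = np.bincount(labels, weights=strengths)
    return float((adj * same).sum() / m2 - np.sum((tot / m2) ** 2))


def _kl_refine(adj: np.ndarray, labels: np.ndarray, max_rounds: int = 50) -> np.ndarray:
    """Kernighan-Lin-style refinement: sequences of single-node moves that
    may be individually Q-decreasing, keeping the best prefix.

    Greedy local moves cannot cross "valleys" (e.g. a chain whose optimal
    cut was absorbed into an early pairwise merge); allowing each node one
    move per round, always taking the currently best move even when
    negative, and rolling back to the best state seen escapes such traps.
    Cost is O(rounds * n^3), so this is reserved for small graphs.
    """
    n = adj.shape[0]
    strengths = adj.sum(axis=1)
    m2 = strengths.sum()
    labels = labels.copy()
    best_q = _q_fast(adj, strengths, m2, labels)
    for _ in range(max_rounds):
        work = labels.copy()
        locked = np.zeros(n, dtype=bool)
        states: list[np.ndarray] = []
        qs: list[float] = []
        for _step in range(n):
            best_move, best_q_move = None, -np.inf
            free = int(work.max()) + 1
            for i in range(n):
                if locked[i] or strengths[i] == 0:
                    continue
                c_old = work[i]
                candidates = set(work[np.flatnonzero(adj[i])].tolist())
                candidates.add(free)
                candidates.discard(c_old)
                for c in sorted(candidates):
                    trial = work.copy()
                    trial[i] = c
                    q = _q_fast(adj, strengths, m2, trial)
                    if q > best_q_move + 1e-15:
                        best_move, best_q_move = (i, c), q
            if best_move is None:
                break
            i, c = best_move
            work[i] = c
            locked[i] = True
            states.append(work.copy())
            qs.append(best_q_move)
        if not qs or max(qs) <= best_q + 1e-12:
            break
        best_idx = int(np.argmax(qs))
        labels = relabel_contiguous(states[best_idx])
        best_q = qs[best_idx]
    return labels


# graphs at or below this size get the Kernighan-Lin refinement pass
_KL_REFINE_MAX_NODES = 32


def _louvain_once(adj: np.ndarray, rng: np.random.Generator, tol: float) -> np.ndarray:
    n0 = adj.shape[0]
    neigh_idx = [np.flatnonzero(adj[i]) for i in range(n0)]
    neigh_w = [adj[i, neigh_idx[i]] for i in range(n0)]
    self_w = np.zeros(n0)
    assignment = np.arange(n0)
    while True:
        labels, moved = _one_level(neigh_idx, neigh_w, self_w, rng, tol)
        labels = relabel_contiguous(labels)
        assignment = labels[assignment]
        if not moved:
            break
        neigh_idx, neigh_w, self_w = _aggregate(neigh_idx, neigh_w, self_w, labels)
    assignment = _refine(adj, relabel_contiguous(assignment), rng, tol)
    if n0 <= _KL_REFINE_MAX_NODES:
        assignment = _kl_refine(adj, assignment)
    return relabel_contiguous(assignment)


def louvain(
    graph: BrainGraph,
    seed: int | None = None,
    n_restarts: int = 5,
    tol: float = 1e-10,
) -> ModulePartition:
    """Louvain partition of a graph, best of ``n_restarts`` seeded runs.

    The local-move sweep order is a fresh random permutation each pass (a
    fixed order can get stuck systematically); the greedy procedure only
    finds a local maximum of Q, so a handful of restarts with
    seed-derived substreams is run and the highest-Q partition returned.
    The same seed always yields the same partition. Isolated nodes remain
    singleton modules and contribute 0 to Q.
    """
    if graph.adjacency.sum() == 0:
        raise ValueError("Louvain is undefined for a graph with no edges")
    if n_restarts < 1:
        raise ValueError("n_restarts must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    adj = graph.adjacency
    candidates = [_louvain_once(adj, np.random.default_rng(child), tol)
                  for child in ss.spawn(n_restarts)]
    if graph.n_nodes <= _KL_REFINE_MAX_NODES:
        # deterministic extra starts: greedy restarts share the singleton
        # initialisation and can all fall into the same basin; refining the
        # one-module and all-singletons partitions explores from the other
        # extremes at negligible cost
        n = graph.n_nodes
        candidates.append(relabel_contiguous(_kl_refine(adj, np.zeros(n, dtype=int))))
        candidates.append(relabel_contiguous(_kl_refine(adj, np.arange(n))))
    best_labels, best_q = None, -np.inf
    for labels in candidates:
        q = modularity_q(graph, labels)
        if q > best_q:
            best_labels, best_q = labels, q
    return ModulePartition(labels=best_labels, q=best_q)


def _iter_set_partitions(n: int):
    """All set partitions of {0..n-1} as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_label: int):
        if i == n:
            yield labels
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    if n == 0:
        return
    yield from rec(1, 0)


def brute_force_max_q(graph: BrainGraph) -> ModulePartition:
    """Globally optimal-Q partition by exhaustive set-partition enumeration.

    Only feasible for tiny graphs (Bell-number growth); refuses more than
    10 nodes. Intended as an independent oracle for testing heuristics.
    """
    n = graph.n_nodes
    if n > _MAX_BRUTE_NODES:
        raise ValueError(
            f"brute-force enumeration limited to {_MAX_BRUTE_NODES} nodes, got {n}"
        )
    adj = graph.adjacency
    m2 = adj.sum()
    if m2 == 0:
        raise ValueError("modularity is undefined for a graph with no edges")
    iu, ju = np.triu_indices(n, 1)
    w = adj[iu, ju]
    nz = w > 0
    iu, ju, w = iu[nz], ju[nz], w[nz]
    strengths = adj.sum(axis=1)
    best_q, best_labels = -np.inf, None
    for labels in _iter_set_partitions(n):
        within = 2.0 * w[labels[iu] == labels[ju]].sum() / m2
        tot = np.bincount(labels, weights=strengths)
        q = within - np.sum((tot / m2) ** 2)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels.copy()
    return ModulePartition(labels=relabel_contiguous(best_labels), q=float(best_q))
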