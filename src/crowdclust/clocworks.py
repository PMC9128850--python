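"""Co-selection networks and community-based clustering of crowd answers.

For each dimension pair a *pair network* is built over the data points: the
weight of edge (u, v) is the fraction of stage-answers on that pair in
which u and v were selected together, out of the stage-answers in which
both were shown.  Communities of these networks (found with the Louvain
modularity heuristic) are groups of points the crowd consistently selected
together — cluster candidates that owe nothing to the raw coordinates.

Two aggregation modes are provided, because per-pair partitioning and
partitioning a single averaged ("summary") network are both defensible
readings of the design:

* ``per_pair`` (default): Louvain on each pair network; communities become
  subspace-tagged candidates merged by the two-phase aggregation of
  :mod:`.hubclique` under relaxed thresholds (lower overlap requirement,
  any shared dimension is compatible);
* ``summary``: Louvain once on the element-wise average of all pair
  networks; communities become final clusters directly.

The same machinery runs directly on externally supplied weighted networks
(e.g. simulated stochastic-block-model graphs standing in for the
crowd-derived networks), treating each graph like one pair network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .crowd_sim import Solution
from .hubclique import (CandidateCluster, UNASSIGNED, compatible_share_any,
                        phase1, phase2)
from .puzzle_engine import Puzzle


@dataclass
class PairNetwork:
    """Dense co-selection matrix for one dimension pair.

    ``weight[u, v]`` is the co-selection frequency; ``defined[u, v]`` marks
    pairs that co-appeared in at least one stage-answer (a frequency of 0.0
    is a real observation only where ``defined`` is True).
    """

    dims: tuple[int, int]
    weight: np.ndarray
    defined: np.ndarray

    def to_graph(self) -> nx.Graph:
        """Weighted graph over all points; zero-weight pairs carry no edge."""
        n = self.weight.shape[0]
        g = nx.Graph()
        g.add_nodes_from(range(n))
        iu, ju = np.nonzero(np.triu(self.weight, k=1))
        g.add_weighted_edges_from(
            zip(iu.tolist(), ju.tolist(), self.weight[iu, ju].tolist()))
        return g


@dataclass
class Partition:
    """Node -> community assignment plus the weighted modularity achieved."""

    membership: dict[int, int]
    modularity: float

    def communities(self) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for node, comm in self.membership.items():
            out.setdefault(comm, set()).add(node)
        return [out[k] for k in sorted(out)]


def build_pair_network(solutions: list[Solution], puzzles: list[Puzzle],
                       dims: tuple[int, int], n_points: int | None = None) -> PairNetwork:
    """Co-selection frequencies for one dimension pair, over all stages of
    that pair in all puzzles."""
    dims = (min(dims), max(dims))
    by_id = {pz.puzzle_id: pz for pz in puzzles}
    if n_points is None:
        n_points = 1 + max(int(pz.point_ids.max()) for pz in puzzles)
    co_app = np.zeros((n_points, n_points), dtype=np.float32)
    co_sel = np.zeros((n_points, n_points), dtype=np.float32)
    for sol in solutions:
        pz = by_id[sol.puzzle_id]
        for st, sel in zip(pz.stages, sol.selections):
            if sel is None or (min(st.dims), max(st.dims)) != dims:
                continue
            ids = pz.point_ids
            co_app[np.ix_(ids, ids)] += 1
            s = np.array(sorted(sel), dtype=int)
            if len(s):
                co_sel[np.ix_(s, s)] += 1
    defined = co_app > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        weight = np.where(defined, co_sel / np.maximum(co_app, 1), 0.0)
    np.fill_diagonal(weight, 0.0)
    np.fill_diagonal(defined, False)
    return PairNetwork(dims, weight.astype(np.float64), defined)


def summary_network(pair_networks: list[PairNetwork]) -> PairNetwork:
    """Element-wise mean over the networks in which each pair is defined."""
    if not pair_networks:
        raise ValueError("need at least one pair network")
    n = pair_networks[0].weight.shape[0]
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for pn in pair_networks:
        total += np.where(pn.defined, pn.weight, 0.0)
        count += pn.defined
    defined = count > 0
    weight = np.where(defined, total / np.maximum(count, 1), 0.0)
    return PairNetwork((-1, -1), weight, defined)


def louvain(graph: nx.Graph, seed: int = 0) -> Partition:
    """Seeded Louvain modularity maximization on a weighted graph."""
    if graph.number_of_nodes() < 1:
        raise ValueError("network must have at least one node")
    if graph.number_of_edges() == 0:
        return Partition({node: k for k, node in enumerate(sorted(graph))}, 0.0)
    comms = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    membership = {node: k for k, comm in enumerate(comms) for node in comm}
    mod = nx.community.modularity(graph, [set(c) for c in comms], weight="weight")
    return Partition(membership, float(mod))


def _average_graphs(networks: list[nx.Graph]) -> nx.Graph:
    """Mean edge weight over the networks in which each edge is present."""
    total: dict[tuple[int, int], float] = {}
    count: dict[tuple[int, int], int] = {}
    nodes: set = set()
    for g in networks:
        nodes.update(g.nodes)
        for u, v, d in g.edges(data=True):
            key = (min(u, v), max(u, v))
            total[key] = total.get(key, 0.0) + d.get("weight", 1.0)
            count[key] = count.get(key, 0) + 1
    out = nx.Graph()
    out.add_nodes_from(sorted(nodes))
    out.add_weighted_edges_from(
        (u, v, total[(u, v)] / count[(u, v)]) for (u, v) in total)
    return out


def _labels_from_candidates(candidates: list[CandidateCluster], n_points: int,
                            theta_merge: float) -> np.ndarray:
    merged = phase1(candidates, theta_merge, compatible=compatible_share_any)
    return phase2(merged, n_points)


def run_clocworks(solutions: list[Solution], puzzles: list[Puzzle],
                  n_points: int, *, mode: str = "per_pair",
                  theta_merge: float = 0.25, min_community: int = 3,
                  seed: int = 0) -> np.ndarray:
    """Cluster data points from a crowd solution log alone.

    Returns a per-point label vector; points in no (sufficiently large)
    community are :data:`~crowdclust.hubclique.UNASSIGNED`.
    """
    if mode not in ("per_pair", "summary"):
        raise ValueError("mode must be 'per_pair' or 'summary'")
    if not solutions:
        warnings.warn("empty solution log: every point left unassigned")
        return np.full(n_points, UNASSIGNED, dtype=int)
    all_dims = sorted({(min(st.dims), max(st.dims))
                       for pz in puzzles for st in pz.stages})
    if mode == "summary":
        pns = [build_pair_network(solutions, puzzles, d, n_points) for d in all_dims]
        part = louvain(summary_network(pns).to_graph(), seed=seed)
        return _labels_from_partition(part, n_points, min_community)
    candidates: list[CandidateCluster] = []
    for dims in all_dims:
        pn = build_pair_network(solutions, puzzles, dims, n_points)
        part = louvain(pn.to_graph(), seed=seed)
        for comm in part.communities():
            if len(comm) >= min_community:
                candidates.append(CandidateCluster(frozenset(dims), set(comm)))
    return _labels_from_candidates(candidates, n_points, theta_merge)


def _labels_from_partition(part: Partition, n_points: int,
                           min_community: int) -> np.ndarray:
    labels = np.full(n_points, UNASSIGNED, dtype=int)
    next_id = 0
    for comm in part.communities():
        if len(comm) >= min_community:
            labels[sorted(comm)] = next_id
            next_id += 1
    return labels


def consensus_partition(partitions: list[Partition], n_points: int,
                        seed: int = 0) -> Partition:
    """Aggregate replicate partitions through their co-association network.

    The co-association weight of a point pair is the fraction of the
    replicate partitions that place the two points in one community — the
    same frequency-averaging step the summary-network construction applies
    to raw selections, applied here to partition indicators.  The consensus
    network is then partitioned once.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    co = np.zeros((n_points, n_points), dtype=np.float32)
    for part in partitions:
        for comm in part.communities():
            idx = np.array(sorted(comm))
            co[np.ix_(idx, idx)] += 1
    co /= len(partitions)
    np.fill_diagonal(co, 0.0)
    g = nx.Graph()
    g.add_nodes_from(range(n_points))
    iu, ju = np.nonzero(np.triu(co, k=1))
    g.add_weighted_edges_from(zip(iu.tolist(), ju.tolist(), co[iu, ju].tolist()))
    return louvain(g, seed=seed)


def run_clocworks_on_networks(networks: list[nx.Graph], n_points: int, *,
                              mode: str = "per_network",
                              min_community: int = 3, seed: int = 0) -> np.ndarray:
    """Run the community-clustering stage directly on weighted networks.

    Replicate networks stand in for the per-stage co-selection
    observations.  ``per_network`` (default) partitions each replicate
    separately and aggregates the partitions through their co-association
    consensus (:func:`consensus_partition`); ``average`` mirrors the
    summary-network reading, averaging the replicates edge-wise (mean
    weight over the networks in which an edge is present) and partitioning
    the result once.
    """
    if mode not in ("average", "per_network"):
        raise ValueError("mode must be 'average' or 'per_network'")
    if not networks:
        return np.full(n_points, UNASSIGNED, dtype=int)
    if mode == "average":
        part = louvain(_average_graphs(networks), seed=seed)
        return _labels_from_partition(part, n_points, min_community)
    parts = [louvain(g, seed=seed + k) for k, g in enumerate(networks)]
    consensus = consensus_partition(parts, n_points, seed=seed)
    return _labels_from_partition(consensus, n_points, min_community)


def write_partition_csv(labels: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("node,community\n")
        for node, comm in enumerate(labels):
            fh.write(f"{node},{int(comm)}\n")
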