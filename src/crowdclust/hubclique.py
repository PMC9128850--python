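"""Crowd-weighted bottom-up subspace clustering (CLIQUE family).

The classic CLIQUE recipe — grid the space, keep dense cells, grow dense
regions into higher-dimensional subspaces — is run here with two twists:

* primitive subspaces are **two-dimensional** (the projections annotators
  actually saw), not one-dimensional;
* cell density is a **weighted** point count, each point contributing its
  crowd selection frequency W(x), so regions the crowd never grouped fade
  out of the grid.

Candidate clusters from every subspace level are then aggregated in two
phases: phase 1 resolves overlaps between candidates (merging nestable
pairs that overlap strongly, otherwise removing the contested points from
the lower-priority candidate), and phase 2 greedily converts the surviving
candidates into a single disjoint labelling, highest (dimensionality, size)
first.  Points claimed by no candidate stay unassigned.

With all weights equal to 1 and no solution filtering the pipeline is the
plain 2-D-primitive CLIQUE baseline (:func:`run_clique2d`); the crowd
signal is the only difference between the two entry points.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .crowd_sim import SelectionStats, Solution, acs_filter, selection_stats
from .datagen import Dataset
from .puzzle_engine import Puzzle

#: Output label for points no cluster claims.
UNASSIGNED = -1


@dataclass(frozen=True)
class GridUnit:
    """One dense cell of a 2-D grid: subspace dims, cell index, members."""

    dims: tuple[int, int]
    cell: tuple[int, int]
    point_ids: tuple[int, ...]
    density: float


@dataclass
class CandidateCluster:
    """A point set tagged with the subspace it is dense in.

    Priority (used throughout for ordering) is (|subspace|, |points|),
    larger first; ties break on the subspace tuple then the smallest
    member id, keeping every ordering deterministic.
    """

    subspace: frozenset[int]
    points: set[int]

    def sort_key(self) -> tuple:
        return (-len(self.subspace), -len(self.points),
                tuple(sorted(self.subspace)), min(self.points) if self.points else -1)


def impute_weights(stats: SelectionStats | None, n_points: int) -> np.ndarray:
    """Per-point weight vector in [0, 1].

    Observed points get W(x); points never shown to any annotator get the
    mean observed weight (they carry no signal either way); with no
    observations at all the vector degenerates to all ones, i.e. to the
    unweighted CLIQUE baseline.
    """
    if stats is None:
        return np.ones(n_points)
    w = stats.weights
    if len(w) < n_points:
        w = np.concatenate([w, np.full(n_points - len(w), np.nan)])
    w = w[:n_points].astype(float).copy()
    observed = ~np.isnan(w)
    if not observed.any():
        return np.ones(n_points)
    w[~observed] = w[observed].mean()
    return np.clip(w, 0.0, 1.0)


def dense_units_2d(dataset: Dataset, weights: np.ndarray, dims: tuple[int, int],
                   xi: int = 10, tau: float = 2.0) -> list[GridUnit]:
    """Dense cells of the xi-by-xi grid over the (dims[0], dims[1]) projection.

    Each dimension's observed range is cut into ``xi`` equal bins (last bin
    closed).  A cell is dense when its weighted point mass reaches
    ``tau * total_weight / xi**2`` — i.e. ``tau`` times the mass a uniform
    spread would put in one cell, making the threshold comparable between
    weighted and unweighted runs.
    """
    if xi < 1:
        raise ValueError("xi must be >= 1")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    weights = np.asarray(weights, dtype=float)
    bins = []
    for d in dims:
        x = dataset.points[:, d]
        lo, hi = x.min(), x.max()
        if hi == lo:
            bins.append(np.zeros(len(x), dtype=int))
        else:
            bins.append(np.minimum(((x - lo) / (hi - lo) * xi).astype(int), xi - 1))
    flat = bins[0] * xi + bins[1]
    density = np.bincount(flat, weights=weights, minlength=xi * xi)
    threshold = tau * weights.sum() / (xi * xi)
    units = []
    for cell_flat in np.nonzero(density >= threshold)[0]:
        if density[cell_flat] <= 0:
            continue
        members = np.nonzero(flat == cell_flat)[0]
        units.append(GridUnit(tuple(dims), (int(cell_flat // xi), int(cell_flat % xi)),
                              tuple(members.tolist()), float(density[cell_flat])))
    return units


def units_to_clusters(units: list[GridUnit]) -> list[CandidateCluster]:
    """Connected components of dense cells under shared-edge adjacency.

    Cells touching only at a corner belong to different components.  Each
    component's member points form one candidate in the units' subspace.
    """
    if not units:
        return []
    dims = units[0].dims
    if any(u.dims != dims for u in units):
        raise ValueError("all units must share one subspace")
    by_cell = {u.cell: u for u in units}
    seen: set[tuple[int, int]] = set()
    clusters = []
    for start in sorted(by_cell):
        if start in seen:
            continue
        comp, queue = [], [start]
        seen.add(start)
        while queue:
            cell = queue.pop()
            comp.append(cell)
            a, b = cell
            for nb in ((a - 1, b), (a + 1, b), (a, b - 1), (a, b + 1)):
                if nb in by_cell and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        points: set[int] = set()
        for cell in comp:
            points.update(by_cell[cell].point_ids)
        clusters.append(CandidateCluster(frozenset(dims), points))
    return clusters


def join_subspaces(clusters: list[CandidateCluster]) -> list[CandidateCluster]:
    """One CLIQUE join step: K-dim candidates -> (K+1)-dim candidates.

    Every pair of candidates whose K-dim subspaces share exactly K-1
    dimensions and whose point sets intersect yields a candidate on the
    union subspace containing the intersection.  Duplicates (same subspace
    and points) are emitted once.  No coverage-based pruning is applied:
    low-coverage subspaces may still be part of a larger solution.
    """
    if not clusters:
        return []
    k = len(clusters[0].subspace)
    if any(len(c.subspace) != k for c in clusters):
        raise ValueError("all candidates must live in subspaces of one size")
    out: dict[tuple, CandidateCluster] = {}
    for a, b in combinations(clusters, 2):
        if len(a.subspace & b.subspace) != k - 1:
            continue
        inter = a.points & b.points
        if not inter:
            continue
        sub = a.subspace | b.subspace
        key = (tuple(sorted(sub)), tuple(sorted(inter)))
        if key not in out:
            out[key] = CandidateCluster(sub, inter)
    return sorted(out.values(), key=CandidateCluster.sort_key)


def _nestable(a: frozenset[int], b: frozenset[int]) -> bool:
    """Default phase-1 subspace compatibility: one subspace contains the
    other, or they differ by a single dimension on the smaller side."""
    shared = len(a & b)
    return shared >= 1 and shared >= min(len(a), len(b)) - 1


def compatible_share_any(a: frozenset[int], b: frozenset[int]) -> bool:
    """Relaxed compatibility: any shared dimension (network-candidate mode)."""
    return len(a & b) >= 1


def phase1(candidates: list[CandidateCluster], theta_merge: float = 0.5,
           compatible=_nestable) -> list[CandidateCluster]:
    """Resolve overlaps between candidates, highest priority first.

    Walking the priority-sorted list: when a lower-priority candidate
    overlaps a higher one by at least ``theta_merge`` of its own size and
    the subspaces are compatible, the two merge (union subspace,
    intersection points) into the higher candidate's lineage; any other
    overlap strips the contested points from the lower candidate.  Emptied
    candidates disappear.
    """
    items = [CandidateCluster(c.subspace, set(c.points)) for c in candidates if c.points]
    items.sort(key=CandidateCluster.sort_key)
    i = 0
    while i < len(items):
        si = items[i]
        j = i + 1
        while j < len(items):
            sj = items[j]
            inter = si.points & sj.points
            if not inter:
                j += 1
                continue
            if len(inter) / len(sj.points) >= theta_merge and compatible(si.subspace, sj.subspace):
                si = CandidateCluster(si.subspace | sj.subspace, inter)
                items[i] = si
                del items[j]
            else:
                sj.points -= inter
                if sj.points:
                    j += 1
                else:
                    del items[j]
        i += 1
    return items


def phase2(candidates: list[CandidateCluster], n_points: int) -> np.ndarray:
    """Convert candidates into one disjoint labelling.

    Repeatedly: sort the remaining candidates by (|subspace|, |points|)
    descending, assign the head's points a fresh cluster id, and delete
    those points from every remaining candidate.  Points never claimed end
    up :data:`UNASSIGNED`; cluster ids are contiguous from 0.
    """
    labels = np.full(n_points, UNASSIGNED, dtype=int)
    pool = [CandidateCluster(c.subspace, set(c.points)) for c in candidates if c.points]
    next_id = 0
    while pool:
        pool.sort(key=CandidateCluster.sort_key)
        head = pool.pop(0)
        labels[sorted(head.points)] = next_id
        next_id += 1
        survivors = []
        for c in pool:
            c.points -= head.points
            if c.points:
                survivors.append(c)
        pool = survivors
    return labels


def collect_candidates(dataset: Dataset, weights: np.ndarray, *,
                       xi: int = 10, tau: float = 2.0) -> list[CandidateCluster]:
    """All candidates from 2-D grids up through the full dimensionality."""
    level: list[CandidateCluster] = []
    for dims in combinations(range(dataset.n_features), 2):
        level.extend(units_to_clusters(dense_units_2d(dataset, weights, dims, xi, tau)))
    all_cands = list(level)
    for _ in range(2, dataset.n_features):
        level = join_subspaces(level)
        if not level:
            break
        all_cands.extend(level)
    return all_cands


def run_hubclique(dataset: Dataset, solutions: list[Solution],
                  puzzles: list[Puzzle], *, xi: int = 10, tau: float = 2.0,
                  theta_merge: float = 0.5, use_acs: bool = True) -> np.ndarray:
    """Full crowd-weighted pipeline: filter -> weights -> grids -> joins ->
    phase 1 -> phase 2.  Returns a per-point label vector."""
    if solutions:
        log = acs_filter(solutions)[0] if use_acs else solutions
        stats = selection_stats(log, puzzles, dataset.n_points)
        weights = impute_weights(stats, dataset.n_points)
    else:
        weights = np.ones(dataset.n_points)
    cands = collect_candidates(dataset, weights, xi=xi, tau=tau)
    return phase2(phase1(cands, theta_merge), dataset.n_points)


def run_clique2d(dataset: Dataset, *, xi: int = 10, tau: float = 2.0,
                 theta_merge: float = 0.5) -> np.ndarray:
    """Unweighted 2-D-primitive CLIQUE baseline (all weights 1, no filter)."""
    weights = np.ones(dataset.n_points)
    cands = collect_candidates(dataset, weights, xi=xi, tau=tau)
    return phase2(phase1(cands, theta_merge), dataset.n_points)
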