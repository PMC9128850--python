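"""Micro-averaged F1 evaluation and the clustering benchmark harness.

Predicted cluster ids are arbitrary, so before pooling error counts the
predicted clusters are aligned to the planted ones with an optimal
injective (Hungarian) assignment maximizing matched points.  Micro F1 then
pools globally: TP are points whose mapped prediction equals their true
cluster, FP are labelled points whose mapped prediction differs (including
any prediction on a background-noise point), FN are true-cluster points
left unassigned or mismatched, and F1 = 2TP / (2TP + FP + FN).

Because planted clusters live in subspaces of different sizes, subgroup
scores restrict the counts to points whose true cluster is in the high-
or low-dimensional group, reported alongside the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import (DBSCAN, AffinityPropagation,
                             AgglomerativeClustering, KMeans, MeanShift,
                             estimate_bandwidth)
from sklearn.mixture import GaussianMixture

from .datagen import Dataset, NOISE
from .hubclique import run_clique2d, run_hubclique
from .clocworks import run_clocworks


@dataclass
class EvalReport:
    micro_f1_total: float
    micro_f1_highdim: float
    micro_f1_lowdim: float
    contingency: pd.DataFrame
    mapping: dict[int, int] = field(default_factory=dict)


def _f1_from_masks(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray,
                   keep: np.ndarray) -> float:
    t, p, n = int(tp[keep].sum()), int(fp[keep].sum()), int(fn[keep].sum())
    denom = 2 * t + p + n
    return 2 * t / denom if denom else 0.0


def micro_f1(pred: np.ndarray, truth: np.ndarray,
             high_clusters: list[int] | None = None,
             low_clusters: list[int] | None = None) -> EvalReport:
    """Micro-averaged F1 of a predicted labelling against planted truth.

    ``pred`` uses -1 for unassigned points; ``truth`` uses -1 (NOISE) for
    background points, which belong to no recoverable cluster — any
    prediction on them counts as a false positive.  Subgroup F1 values are
    computed over points whose true cluster is in the given id lists; when
    a group is not specified its F1 is reported as the total.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    pred_ids = np.unique(pred[pred >= 0])
    true_ids = np.unique(truth[truth >= 0])
    cont = np.zeros((len(pred_ids), len(true_ids)), dtype=int)
    p_index = {c: k for k, c in enumerate(pred_ids)}
    t_index = {c: k for k, c in enumerate(true_ids)}
    for p, t in zip(pred, truth):
        if p >= 0 and t >= 0:
            cont[p_index[p], t_index[t]] += 1
    mapping: dict[int, int] = {}
    if cont.size:
        rows, cols = linear_sum_assignment(-cont)
        mapping = {int(pred_ids[r]): int(true_ids[c]) for r, c in zip(rows, cols)}
    mapped = np.array([mapping.get(p, -2) if p >= 0 else -2 for p in pred])

    tp = (truth >= 0) & (mapped == truth)
    fp = (pred >= 0) & (mapped != truth)
    fn = (truth >= 0) & (mapped != truth)

    everywhere = np.ones(len(pred), dtype=bool)
    total = _f1_from_masks(tp, fp, fn, everywhere)
    high = total if high_clusters is None else _f1_from_masks(
        tp, fp, fn, np.isin(truth, high_clusters))
    low = total if low_clusters is None else _f1_from_masks(
        tp, fp, fn, np.isin(truth, low_clusters))
    table = pd.DataFrame(cont, index=pred_ids, columns=true_ids)
    return EvalReport(total, high, low, table, mapping)


def dimension_groups(dataset: Dataset, high_min_dims: int = 4
                     ) -> tuple[list[int], list[int]]:
    """Split planted cluster ids into high-/low-dimensional groups by the
    size of their home subspace (>= ``high_min_dims`` counts as high)."""
    high = [k for k, s in enumerate(dataset.specs) if len(s.subspace) >= high_min_dims]
    low = [k for k, s in enumerate(dataset.specs) if len(s.subspace) < high_min_dims]
    return high, low


def elbow_k(points_or_dataset, k_max: int = 10, seed: int = 0) -> int:
    """Elbow estimate of the number of clusters.

    Runs KMeans for k = 1..k_max and returns the k with the largest second
    difference of inertia (discrete curvature); ties go to the smallest k.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = points_or_dataset.points if isinstance(points_or_dataset, Dataset) else np.asarray(points_or_dataset)
    inertia = [float(KMeans(n_clusters=k, n_init=4, random_state=seed).fit(X).inertia_)
               for k in range(1, k_max + 1)]
    best_k, best_curv = 2, -np.inf
    for k in range(2, k_max):
        curv = inertia[k - 2] - 2 * inertia[k - 1] + inertia[k]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    return best_k


KNOWN_ALGORITHMS = ("hubclique", "clocworks", "clique2d", "kmeans", "ward",
                    "gmm", "dbscan", "meanshift", "affinity")


def run_benchmark(dataset: Dataset, puzzles=None, solutions=None,
                  algorithms: list[str] = ("clique2d", "kmeans", "gmm", "dbscan"),
                  *, seed: int = 0, gmm_runs: int = 50, k_max: int = 10,
                  xi: int = 10, tau: float = 2.0) -> pd.DataFrame:
    """Score a set of algorithms on one dataset; one row per algorithm with
    total/high-dim/low-dim micro F1 (GMM rows add mean-over-runs sd)."""
    for name in algorithms:
        if name not in KNOWN_ALGORITHMS:
            raise ValueError(f"unknown algorithm {name!r}")
    X, truth = dataset.points, dataset.labels
    high, low = dimension_groups(dataset)
    k_est = elbow_k(dataset, k_max=k_max, seed=seed)
    rows = []
    for name in algorithms:
        sd = np.nan
        if name == "hubclique":
            pred = run_hubclique(dataset, solutions or [], puzzles or [], xi=xi, tau=tau)
        elif name == "clique2d":
            pred = run_clique2d(dataset, xi=xi, tau=tau)
        elif name == "clocworks":
            pred = run_clocworks(solutions or [], puzzles or [], dataset.n_points, seed=seed)
        elif name == "kmeans":
            pred = KMeans(n_clusters=k_est, n_init=10, random_state=seed).fit_predict(X)
        elif name == "ward":
            pred = AgglomerativeClustering(n_clusters=k_est).fit_predict(X)
        elif name == "gmm":
            f1s = []
            for r in range(gmm_runs):
                p = GaussianMixture(n_components=k_est, random_state=seed + r).fit_predict(X)
                f1s.append(micro_f1(p, truth, high, low).micro_f1_total)
            f1s = np.asarray(f1s)
            pred = GaussianMixture(n_components=k_est, random_state=seed).fit_predict(X)
            sd = float(f1s.std())
        elif name == "dbscan":
            # eps from the median 4-NN distance, the usual k-distance heuristic
            from sklearn.neighbors import NearestNeighbors
            d, _ = NearestNeighbors(n_neighbors=5).fit(X).kneighbors(X)
            pred = DBSCAN(eps=float(np.median(d[:, -1])), min_samples=5).fit_predict(X)
        elif name == "meanshift":
            bw = estimate_bandwidth(X, quantile=0.2, random_state=seed)
            pred = MeanShift(bandwidth=bw if bw > 0 else None).fit_predict(X)
        elif name == "affinity":
            pred = AffinityPropagation(random_state=seed).fit_predict(X)
        rep = micro_f1(pred, truth, high, low)
        if name == "gmm":
            total = float(np.mean(f1s))
            rows.append({"algorithm": name, "f1_total": total,
                         "f1_highdim": rep.micro_f1_highdim,
                         "f1_lowdim": rep.micro_f1_lowdim, "f1_total_sd": sd})
        else:
            rows.append({"algorithm": name, "f1_total": rep.micro_f1_total,
                         "f1_highdim": rep.micro_f1_highdim,
                         "f1_lowdim": rep.micro_f1_lowdim, "f1_total_sd": sd})
    return pd.DataFrame(rows).set_index("algorithm")
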