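"""Scoring of a player's per-stage cluster selections.

A stage answer is a single selected point set on a two-dimensional view.
Its score combines three signals:

* **Qual** — how good the selection looks to standard cluster-validity
  indices (Silhouette, Dunn, S_Dbw), each evaluated on the two-block
  partition {selection, complement} and normalized empirically: the raw
  value is mapped to the fraction of a pre-recorded reference distribution
  of machine-found sample clusters that score strictly worse, putting all
  three indices on a common [0, 1] scale.  Qual is the best of the three
  normalized values.
* **Cons** — the fraction of the current selection that was also selected
  on the previous stage, rewarding clusters that persist across views.
* **DCC** — a density correction in [-1, 1] from a Gaussian kernel density
  estimate over the stage: the percentile of the selection's mean density
  among all stage points, shifted and mapped to [-1, 1], discouraging
  selections in sparse regions.

The stage score is ``(alpha * Qual + (1 - alpha) * Cons) * (1 + DCC) / 2``
with ``alpha`` defaulting to 0.8; on the first stage (no previous
selection) the convex combination collapses to Qual alone.  The puzzle
score is the sum of its stage scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.metrics import silhouette_score

from .datagen import Dataset
from .puzzle_engine import rescale_stage

#: Orientation of each validity index (True = larger raw value is better).
INDEX_ORIENTATION = {"silhouette": True, "dunn": True, "sdbw": False}


class DegenerateSelectionError(ValueError):
    """Raised when a selection is empty or covers the whole stage."""


def _as_mask(selection, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[sorted(selection)] = True
    return mask


def validity_indices(stage_coords: np.ndarray, selection) -> tuple[float, float, float]:
    """Raw (silhouette, dunn, sdbw) of the two-block partition
    {selection, complement} under Euclidean distance on display coords.

    ``selection`` indexes rows of ``stage_coords`` and must be a proper
    non-empty subset.
    """
    X = np.asarray(stage_coords, dtype=float)
    n = len(X)
    mask = _as_mask(selection, n)
    k = int(mask.sum())
    if k == 0 or k == n:
        raise DegenerateSelectionError("selection must be a proper non-empty subset")
    labels = mask.astype(int)
    sil = float(silhouette_score(X, labels))
    a, b = X[mask], X[~mask]
    inter = float(cdist(a, b).min())
    diam = max(float(pdist(a).max()) if len(a) > 1 else 0.0,
               float(pdist(b).max()) if len(b) > 1 else 0.0)
    dunn = float(np.inf) if diam == 0 else inter / diam
    return sil, dunn, _sdbw(X, [a, b])


def _sdbw(X: np.ndarray, clusters: list[np.ndarray]) -> float:
    """S_Dbw validity (scatter + between-cluster density); lower is better."""
    c = len(clusters)
    sigma_x = np.linalg.norm(X.var(axis=0))
    if sigma_x == 0:
        return 0.0
    norms = [np.linalg.norm(ci.var(axis=0)) for ci in clusters]
    scatt = float(np.mean(norms)) / sigma_x
    stdev = float(np.mean([np.sqrt(s) for s in norms]))
    centroids = [ci.mean(axis=0) for ci in clusters]

    def density(point: np.ndarray, members: np.ndarray) -> int:
        if stdev == 0:
            return len(members)
        return int((np.linalg.norm(members - point, axis=1) <= stdev).sum())

    dens = 0.0
    n_pairs = 0
    for i in range(c):
        for j in range(i + 1, c):
            union = np.vstack([clusters[i], clusters[j]])
            mid = (centroids[i] + centroids[j]) / 2
            peak = max(density(centroids[i], union), density(centroids[j], union))
            dens += density(mid, union) / peak if peak else 0.0
            n_pairs += 1
    dens_bw = dens / n_pairs if n_pairs else 0.0
    return scatt + dens_bw


@dataclass
class ReferenceDistributions:
    """Sorted raw-score samples per index, used for empirical normalization."""

    dists: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.dists.items():
            if name not in INDEX_ORIENTATION:
                raise ValueError(f"unknown index {name!r}")
            arr = np.sort(np.asarray(arr, dtype=float))
            if len(arr) == 0:
                raise ValueError(f"empty reference distribution for {name!r}")
            self.dists[name] = arr

    def to_json(self, path: str | Path) -> None:
        payload = {"dists": {k: v.tolist() for k, v in self.dists.items()},
                   "metadata": self.metadata,
                   "orientation": INDEX_ORIENTATION}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceDistributions":
        payload = json.loads(Path(path).read_text())
        return cls({k: np.asarray(v) for k, v in payload["dists"].items()},
                   payload.get("metadata", {}))


def build_reference_distributions(dataset: Dataset, n_stages: int = 200,
                                  clusters_per_stage: int = 10, seed: int = 0,
                                  stage_size: int = 100) -> ReferenceDistributions:
    """Record raw index values of machine-found sample clusters.

    Samples ``n_stages`` random stages (random dimension pair and point
    sample), partitions each with KMeans and spectral clustering at varying
    k, and records the raw value of every index for each resulting cluster
    (as a two-block partition against its complement).  Done once per
    dataset family; the resulting distributions serve every later scoring
    call.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, list[float]] = {"silhouette": [], "dunn": [], "sdbw": []}
    F, N = dataset.n_features, dataset.n_points
    for _ in range(n_stages):
        i, j = rng.choice(F, size=2, replace=False)
        ids = rng.choice(N, size=min(stage_size, N), replace=False)
        coords = rescale_stage(dataset.points[np.ix_(ids, [i, j])])
        harvested = 0
        for algo, k in _clusterer_cycle():
            if harvested >= clusters_per_stage:
                break
            rs = int(rng.integers(0, 2**31 - 1))
            if algo == "kmeans":
                labels = KMeans(n_clusters=k, n_init=2, random_state=rs).fit_predict(coords)
            else:
                labels = SpectralClustering(
                    n_clusters=k, random_state=rs, affinity="nearest_neighbors",
                    n_neighbors=10, assign_labels="discretize").fit_predict(coords)
            for c in np.unique(labels):
                sel = np.nonzero(labels == c)[0]
                if 0 < len(sel) < len(coords):
                    sil, dunn, sdbw = validity_indices(coords, sel)
                    out["silhouette"].append(sil)
                    out["dunn"].append(dunn if np.isfinite(dunn) else 1e6)
                    out["sdbw"].append(sdbw)
                    harvested += 1
    meta = {"n_stages": n_stages, "clusters_per_stage": clusters_per_stage,
            "seed": seed, "generators": ["kmeans", "spectral"]}
    return ReferenceDistributions({k: np.asarray(v) for k, v in out.items()}, meta)


def _clusterer_cycle():
    for k in (2, 3, 4):
        yield "kmeans", k
    for k in (2, 3):
        yield "spectral", k


def normalize_index(raw: float, dist: np.ndarray, higher_is_better: bool) -> float:
    """Fraction of the reference sample that scores strictly worse than raw."""
    dist = np.asarray(dist)
    if len(dist) == 0:
        raise ValueError("reference distribution is empty")
    if higher_is_better:
        worse = int(np.searchsorted(dist, raw, side="left"))
    else:
        worse = len(dist) - int(np.searchsorted(dist, raw, side="right"))
    return worse / len(dist)


def qual(stage_coords: np.ndarray, selection,
         refdists: ReferenceDistributions) -> float:
    """Best normalized validity value of the selection (in [0, 1])."""
    raw = dict(zip(("silhouette", "dunn", "sdbw"),
                   validity_indices(stage_coords, selection)))
    return max(normalize_index(raw[name], refdists.dists[name], INDEX_ORIENTATION[name])
               for name in refdists.dists)


def conservation(prev_selection, cur_selection) -> float | None:
    """|prev ∩ cur| / |cur|; None on the first stage (no previous answer)."""
    if not cur_selection:
        raise ValueError("current selection must be non-empty")
    if prev_selection is None:
        return None
    return len(set(prev_selection) & set(cur_selection)) / len(set(cur_selection))


def dcc(stage_coords: np.ndarray, selection, shift: float = 0.0) -> float:
    """Kernel-density correction coefficient in [-1, 1].

    Fits a Gaussian KDE (Scott bandwidth) to all stage points; with r the
    fraction of stage points whose density falls below the mean density of
    the selected points, returns ``clip(2 * (r + shift) - 1, -1, 1)``, so a
    shift of magnitude 1 saturates the coefficient regardless of the data.
    A selection in a typical-density region scores near 0, a selection of
    the densest area near +1.  Degenerate stages (singular KDE) score 0.
    """
    X = np.asarray(stage_coords, dtype=float)
    sel = np.asarray(sorted(selection), dtype=int)
    if len(sel) == 0:
        raise DegenerateSelectionError("selection must be non-empty")
    try:
        kde = gaussian_kde(X.T)
        dens = kde(X.T)
    except np.linalg.LinAlgError:
        return 0.0
    r = float((dens < dens[sel].mean()).mean())
    return float(np.clip(2 * (r + shift) - 1, -1.0, 1.0))


@dataclass(frozen=True)
class StageScoreBreakdown:
    qual: float
    cons: float | None
    dcc: float
    alpha: float
    score: float


def stage_score(qual_value: float, cons_value: float | None, dcc_value: float,
                alpha: float = 0.8) -> StageScoreBreakdown:
    """Combine the three signals into the final stage score in [0, 1]."""
    if not 0.0 <= qual_value <= 1.0:
        raise ValueError("qual must be in [0, 1]")
    if cons_value is not None and not 0.0 <= cons_value <= 1.0:
        raise ValueError("cons must be in [0, 1] or None")
    if not -1.0 <= dcc_value <= 1.0:
        raise ValueError("dcc must be in [-1, 1]")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    base = qual_value if cons_value is None else alpha * qual_value + (1 - alpha) * cons_value
    return StageScoreBreakdown(qual_value, cons_value, dcc_value, alpha,
                               base * (1 + dcc_value) / 2)


def puzzle_score(breakdowns: list[StageScoreBreakdown]) -> float:
    """Total puzzle score: the sum over its stage scores."""
    return float(sum(b.score for b in breakdowns))


def score_solution(puzzle, solution, refdists: ReferenceDistributions,
                   alpha: float = 0.8, shift: float = 0.0) -> list[StageScoreBreakdown]:
    """Score every answered stage of one solution, in stage order.

    Degenerate or missing answers score 0 and break the conservation chain.
    """
    breakdowns = []
    prev = None
    for st, sel in zip(puzzle.stages, solution.selections):
        if sel is None or len(sel) == 0 or len(sel) >= len(st.point_ids):
            breakdowns.append(StageScoreBreakdown(0.0, None, 0.0, alpha, 0.0))
            prev = None
            continue
        pos = {pid: k for k, pid in enumerate(st.point_ids.tolist())}
        rows = [pos[pid] for pid in sorted(sel)]
        q = qual(st.display_coords, rows, refdists)
        c = conservation(prev, sel)
        d = dcc(st.display_coords, rows, shift=shift)
        breakdowns.append(stage_score(q, c, d, alpha=alpha))
        prev = sel
    return breakdowns
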