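"""Synthetic benchmark generators.

Two families of inputs are produced here, both fully seeded:

* **Subspace-Gaussian point datasets** — clusters that are Gaussian-dense
  only inside a random subset of the feature dimensions and uniform noise
  everywhere else.  These emulate the high-dimensional gating problem the
  crowd annotates: a cluster is visible only when the viewer happens to
  look at (a projection of) its home subspace.
* **Weighted stochastic-block-model networks** — co-selection-style graphs
  with planted communities, used to probe the network-clustering half of
  the pipeline under controlled sparsity.

Separation between planted clusters is enforced with a Manhattan-distance
rule: two clusters that share at least one dimension must have subspace
means farther apart (L1) than the L1 norm of the sum of their per-dimension
variance vectors, so planted clusters never blur into each other in any
shared view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Reserved label for points that belong to no planted cluster.
NOISE = -1

#: Global coordinate range for every feature; cluster means are sampled
#: strictly inside it and off-subspace/noise coordinates are uniform over it.
DATA_RANGE = (0.0, 10.0)


class GenerationError(RuntimeError):
    """Rejection sampling could not place a cluster under the separation rule."""


@dataclass(frozen=True)
class ClusterSpec:
    """Description of one planted subspace-Gaussian cluster.

    ``subspace`` holds the (sorted, distinct, 0-based) dimensions in which
    the cluster is dense; ``mean`` and ``cov`` are aligned with it, ``cov``
    being per-dimension variances (axis-aligned ellipsoid).
    """

    subspace: tuple[int, ...]
    size: int
    mean: tuple[float, ...]
    cov: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.subspace)) != len(self.subspace):
            raise ValueError("subspace dimensions must be distinct")
        if len(self.subspace) < 2:
            raise ValueError("subspace must span at least two dimensions")
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if len(self.mean) != len(self.subspace) or len(self.cov) != len(self.subspace):
            raise ValueError("mean/cov must align with the subspace")
        if any(v < 0 for v in self.cov):
            raise ValueError("variances must be non-negative")


@dataclass
class Dataset:
    """An N x F point matrix with per-point labels and the generating specs.

    Labels are planted-cluster indices (into ``specs``); :data:`NOISE`
    marks background points.
    """

    points: np.ndarray
    labels: np.ndarray
    specs: list[ClusterSpec] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D matrix")
        if len(self.labels) != self.points.shape[0]:
            raise ValueError("labels must have one entry per point")
        if np.isnan(self.points).any():
            raise ValueError("points must not contain missing values")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.points.shape[1])]

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_features(self) -> int:
        return self.points.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.points, columns=self.feature_names)
        df["label"] = ["noise" if l == NOISE else str(l) for l in self.labels]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, specs: list[ClusterSpec] | None = None) -> "Dataset":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("dataset CSV must have a 'label' column")
        raw = df.pop("label").astype(str)
        labels = np.array([NOISE if v == "noise" else int(v) for v in raw])
        return cls(df.to_numpy(float), labels, specs or [], list(df.columns))


def specs_to_json(specs: Sequence[ClusterSpec], path: str | Path) -> None:
    payload = [
        {"subspace": list(s.subspace), "size": s.size,
         "mean": list(s.mean), "cov": list(s.cov)}
        for s in specs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def specs_from_json(path: str | Path) -> list[ClusterSpec]:
    payload = json.loads(Path(path).read_text())
    return [
        ClusterSpec(tuple(d["subspace"]), int(d["size"]),
                    tuple(d["mean"]), tuple(d["cov"]))
        for d in payload
    ]


def manhattan_separation_ok(mean1, cov1, mean2, cov2) -> bool:
    """Check the Manhattan separation rule on a shared subspace.

    Returns True iff ``distMan(mean1, mean2) > distMan(0, cov1 + cov2)``,
    i.e. the L1 distance between the two means strictly exceeds the L1 norm
    of the element-wise sum of the two variance vectors.  All four vectors
    must be restricted to the dimensions the clusters share.
    """
    m1, m2 = np.asarray(mean1, float), np.asarray(mean2, float)
    c1, c2 = np.asarray(cov1, float), np.asarray(cov2, float)
    if not (m1.shape == m2.shape == c1.shape == c2.shape):
        raise ValueError("mean/cov vectors must share one length (the shared dims)")
    return float(np.abs(m1 - m2).sum()) > float(np.abs(c1 + c2).sum())


def _spec_pair_separated(a: ClusterSpec, b: ClusterSpec) -> bool:
    """True if a and b satisfy the separation rule on their shared dims.

    Pairs with no shared dimension are unconstrained and return True.
    """
    shared = sorted(set(a.subspace) & set(b.subspace))
    if not shared:
        return True
    ia = [a.subspace.index(d) for d in shared]
    ib = [b.subspace.index(d) for d in shared]
    return manhattan_separation_ok(
        np.asarray(a.mean)[ia], np.asarray(a.cov)[ia],
        np.asarray(b.mean)[ib], np.asarray(b.cov)[ib],
    )


def check_separation(specs: Sequence[ClusterSpec]) -> bool:
    """Post-hoc check that every spec pair sharing a dimension is separated."""
    return all(
        _spec_pair_separated(specs[i], specs[j])
        for i in range(len(specs)) for j in range(i + 1, len(specs))
    )


def generate_subspace_dataset(
    n_clusters: int,
    approx_size: int,
    n_features: int,
    noise_ratio: float,
    seed: int,
    *,
    max_subspace: int | None = None,
    mean_range: tuple[float, float] = (1.0, 9.0),
    var_range: tuple[float, float] = (0.05, 0.3),
    retry_cap: int = 10_000,
) -> Dataset:
    """Generate a labelled subspace-Gaussian dataset.

    Each cluster draws its subspace dimensionality uniformly from
    ``[2, max_subspace]`` (default: all of ``[2, n_features]``, with
    replacement across clusters), its dimensions without replacement, its
    mean uniformly inside ``mean_range`` and its per-dimension variances
    from ``var_range``.  Cluster placement is rejection-sampled until every
    pair sharing a dimension passes :func:`manhattan_separation_ok`; after
    ``retry_cap`` failed attempts for one cluster a
    :class:`GenerationError` is raised advising a looser configuration.

    Cluster points are multivariate normal inside the subspace; every
    off-subspace coordinate is uniform over the global data range, so the
    cluster is invisible outside its home subspace.  Finally
    ``round(noise_ratio * total_cluster_points)`` background points,
    uniform over the full space, are appended with label :data:`NOISE`.
    """
    if n_features < 2:
        raise ValueError("need at least two features")
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if not 0.0 <= noise_ratio <= 1.0:
        raise ValueError("noise_ratio must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hi_dim = n_features if max_subspace is None else min(max_subspace, n_features)
    lo, hi = DATA_RANGE

    base = approx_size / n_clusters
    sizes = [max(1, int(round(base * rng.uniform(0.95, 1.05)))) for _ in range(n_clusters)]

    specs: list[ClusterSpec] = []
    for size in sizes:
        for _ in range(retry_cap):
            d = int(rng.integers(2, hi_dim + 1))
            dims = tuple(sorted(rng.choice(n_features, size=d, replace=False).tolist()))
            mean = tuple(rng.uniform(*mean_range, size=d).tolist())
            cov = tuple(rng.uniform(*var_range, size=d).tolist())
            cand = ClusterSpec(dims, size, mean, cov)
            if all(_spec_pair_separated(cand, s) for s in specs):
                specs.append(cand)
                break
        else:
            raise GenerationError(
                "could not place a separated cluster within the retry cap; "
                "use fewer clusters, more dimensions, or smaller variances"
            )

    total = sum(sizes)
    points = rng.uniform(lo, hi, size=(total, n_features))
    labels = np.empty(total, dtype=int)
    row = 0
    for idx, spec in enumerate(specs):
        block = slice(row, row + spec.size)
        sub = np.asarray(spec.mean) + rng.standard_normal((spec.size, len(spec.subspace))) * np.sqrt(spec.cov)
        for k, dim in enumerate(spec.subspace):
            points[block, dim] = sub[:, k]
        labels[block] = idx
        row += spec.size

    n_noise = int(round(noise_ratio * total))
    if n_noise:
        noise_pts = rng.uniform(lo, hi, size=(n_noise, n_features))
        points = np.vstack([points, noise_pts])
        labels = np.concatenate([labels, np.full(n_noise, NOISE)])

    return Dataset(points, labels, specs)


# ---------------------------------------------------------------------------
# Weighted stochastic block model networks
# ---------------------------------------------------------------------------

@dataclass
class SBMConfig:
    """Configuration of the weighted SBM network generator.

    Nodes are split into ``len(community_sizes)`` planted communities plus
    ``n_noise`` background nodes.  Each node pair gets an edge independently
    with the probability of its class — intra-community, inter-community,
    or noise (any pair touching a background node) — and every realised
    edge carries a weight drawn from a normal with the class mean
    (``w_intra``/``w_inter``/``w_noise``) and standard deviation ``sigma``,
    truncated to [0, 1] because weights model selection frequencies.
    """

    community_sizes: list[int]
    p_intra: float
    p_inter: float
    p_noise: float = 0.2
    w_intra: float = 0.8
    w_inter: float = 0.4
    w_noise: float = 0.1
    sigma: float = 0.1
    n_noise: int = 0
    n_networks: int = 15

    def __post_init__(self) -> None:
        if not self.community_sizes or any(s < 1 for s in self.community_sizes):
            raise ValueError("community_sizes must be positive integers")
        for name in ("p_intra", "p_inter", "p_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")

    @property
    def n_nodes(self) -> int:
        return sum(self.community_sizes) + self.n_noise

    def block_labels(self) -> np.ndarray:
        """Per-node planted community id; background nodes get NOISE."""
        parts = [np.full(s, k) for k, s in enumerate(self.community_sizes)]
        parts.append(np.full(self.n_noise, NOISE))
        return np.concatenate(parts)


def generate_sbm_networks(cfg: SBMConfig, seed: int) -> list[nx.Graph]:
    """Draw ``cfg.n_networks`` weighted SBM graphs over the same node layout.

    Every graph contains all ``cfg.n_nodes`` nodes (isolated nodes kept) and
    symmetric, self-loop-free weighted edges with weights in [0, 1].
    """
    blocks = cfg.block_labels()
    n = cfg.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    bi, bj = blocks[iu], blocks[ju]
    noise_pair = (bi == NOISE) | (bj == NOISE)
    intra_pair = (~noise_pair) & (bi == bj)
    probs = np.where(noise_pair, cfg.p_noise, np.where(intra_pair, cfg.p_intra, cfg.p_inter))
    means = np.where(noise_pair, cfg.w_noise, np.where(intra_pair, cfg.w_intra, cfg.w_inter))

    networks: list[nx.Graph] = []
    children = np.random.SeedSequence(seed).spawn(cfg.n_networks)
    for child in children:
        rng = np.random.default_rng(child)
        present = rng.random(len(iu)) < probs
        w = rng.normal(means[present], cfg.sigma)
        np.clip(w, 0.0, 1.0, out=w)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_weighted_edges_from(zip(iu[present].tolist(), ju[present].tolist(), w.tolist()))
        networks.append(g)
    return networks


def write_network_tsv(g: nx.Graph, path: str | Path) -> None:
    """Edge list ``u<TAB>v<TAB>weight`` with u < v."""
    with open(path, "w") as fh:
        for u, v, w in sorted((min(u, v), max(u, v), d.get("weight", 1.0))
                              for u, v, d in g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def read_network_tsv(path: str | Path, n_nodes: int | None = None) -> nx.Graph:
    g = nx.Graph()
    if n_nodes is not None:
        g.add_nodes_from(range(n_nodes))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u, v, w = line.split("\t")
            g.add_edge(int(u), int(v), weight=float(w))
    return g
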