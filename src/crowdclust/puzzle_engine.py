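"""Decompose a dataset into puzzles of two-dimensional stages.

A *puzzle* is a fixed random sample of ``n`` data points; it is played as a
sequence of *stages*, one per unordered pair of feature dimensions, each
showing the sample projected onto that pair (min-max rescaled to the unit
square, as on a screen).  With at most six features a puzzle has at most
C(6,2) = 15 stages, the cap the annotation workflow is designed around.

Coverage accounting: with ``P`` puzzles of ``n`` points over an ``N``-point
dataset, each point appears in ``P*n/N`` puzzles on average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .datagen import Dataset

#: Maximum dataset dimensionality the stage decomposition supports.
MAX_FEATURES = 6
MAX_STAGES = 15


class UnsupportedDimensionalityError(ValueError):
    pass


def rescale_stage(points: np.ndarray) -> np.ndarray:
    """Min-max rescale an (n, 2) coordinate block to the unit square.

    A constant axis (zero range) maps to 0.5 on that axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("expected an (n, 2) matrix with n >= 1")
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    out = np.empty_like(pts)
    for axis in range(2):
        if span[axis] == 0:
            out[:, axis] = 0.5
        else:
            out[:, axis] = (pts[:, axis] - lo[axis]) / span[axis]
    return out


@dataclass
class Stage:
    """One two-dimensional view (dims i, j) of a puzzle's point sample."""

    dims: tuple[int, int]
    point_ids: np.ndarray
    display_coords: np.ndarray

    def __post_init__(self) -> None:
        if self.dims[0] == self.dims[1]:
            raise ValueError("stage dims must be distinct")


@dataclass
class Puzzle:
    puzzle_id: str
    point_ids: np.ndarray
    stages: list[Stage] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.point_ids)


def build_puzzles(dataset: Dataset, n_puzzles: int, points_per_puzzle: int,
                  seed: int) -> list[Puzzle]:
    """Sample ``n_puzzles`` puzzles of ``points_per_puzzle`` points each.

    Points are drawn uniformly without replacement, independently per
    puzzle; each puzzle gets one stage per unordered dimension pair, in a
    per-puzzle shuffled order.  Deterministic per seed.
    """
    F = dataset.n_features
    if F > MAX_FEATURES:
        raise UnsupportedDimensionalityError(
            f"datasets are limited to {MAX_FEATURES} dimensions "
            f"({MAX_STAGES} stages); reduce dimensionality upstream"
        )
    if points_per_puzzle > dataset.n_points:
        raise ValueError("points_per_puzzle cannot exceed the dataset size")
    pairs = list(combinations(range(F), 2))
    rng = np.random.default_rng(seed)
    puzzles = []
    for p in range(n_puzzles):
        ids = np.sort(rng.choice(dataset.n_points, size=points_per_puzzle, replace=False))
        order = rng.permutation(len(pairs))
        stages = []
        for k in order:
            i, j = pairs[k]
            coords = rescale_stage(dataset.points[np.ix_(ids, [i, j])])
            stages.append(Stage((i, j), ids, coords))
        puzzles.append(Puzzle(f"pz{p:04d}", ids, stages))
    return puzzles


@dataclass
class CoverageStats:
    mean: float
    min: int
    max: int
    counts: np.ndarray


def coverage_stats(puzzles: list[Puzzle], n_points: int) -> CoverageStats:
    """Per-point puzzle-appearance summary; mean is (sum of puzzle sizes)/N."""
    if not puzzles:
        raise ValueError("need at least one puzzle")
    counts = np.zeros(n_points, dtype=int)
    total = 0
    for pz in puzzles:
        counts[pz.point_ids] += 1
        total += pz.n_points
    return CoverageStats(total / n_points, int(counts.min()), int(counts.max()), counts)


def puzzles_to_json(puzzles: list[Puzzle], path: str | Path) -> None:
    payload = [
        {
            "puzzle_id": pz.puzzle_id,
            "point_ids": pz.point_ids.tolist(),
            "stages": [{"dims": list(st.dims), "order_index": k}
                       for k, st in enumerate(pz.stages)],
        }
        for pz in puzzles
    ]
    Path(path).write_text(json.dumps(payload))


def puzzles_from_json(path: str | Path, dataset: Dataset) -> list[Puzzle]:
    """Load puzzles; display coordinates are recomputed from the dataset."""
    payload = json.loads(Path(path).read_text())
    puzzles = []
    for d in payload:
        ids = np.asarray(d["point_ids"], dtype=int)
        stages = []
        for st in sorted(d["stages"], key=lambda s: s["order_index"]):
            i, j = st["dims"]
            coords = rescale_stage(dataset.points[np.ix_(ids, [i, j])])
            stages.append(Stage((i, j), ids, coords))
        puzzles.append(Puzzle(d["puzzle_id"], ids, stages))
    return puzzles
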