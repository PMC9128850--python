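"""Simulated annotators, solution logs, and per-point selection statistics.

A *solution* is one player's answer to one puzzle: one selected point set
per stage (``None`` where an answer is missing or was filtered out).  The
simulator stands in for a live crowd with three behavioural knobs:

* ``fidelity`` — probability that a stage answer is anchored on a planted
  cluster rather than a random circular blob;
* ``flip_rate`` — per-point membership noise applied to faithful answers;
* ``oversize_players`` — fraction of players who inflate every selection by
  at least 3x, emulating the large-cluster bias that the average-cluster-
  size (ACS) filter is designed to remove.

From a solution log we derive, for every data point x, how often it was
shown (``N_appeared``) and how often it was inside a selection
(``f_clustered``); the ratio ``W(x) = f_clustered / N_appeared`` is the
crowd's per-point cluster-membership signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datagen import Dataset, NOISE
from .puzzle_engine import Puzzle


class MalformedSolutionError(ValueError):
    pass


@dataclass
class Solution:
    """One player's per-stage selections for one puzzle.

    ``selections`` aligns with the puzzle's stage order; each entry is a set
    of selected point ids, or ``None`` for a missing/removed answer.
    """

    player_id: str
    puzzle_id: str
    selections: list[set[int] | None] = field(default_factory=list)


@dataclass
class SelectionStats:
    """Per-point exposure and selection tallies over a solution log."""

    f_clustered: np.ndarray
    n_appeared: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        """W(x) = f_clustered / N_appeared; NaN where a point was never shown."""
        with np.errstate(invalid="ignore", divide="ignore"):
            w = self.f_clustered / self.n_appeared
        return np.where(self.n_appeared > 0, w, np.nan)


def simulate_solutions(
    dataset: Dataset,
    puzzles: list[Puzzle],
    n_players: int,
    fidelity: float,
    flip_rate: float = 0.0,
    oversize_players: float = 0.0,
    seed: int = 0,
) -> list[Solution]:
    """Generate a deterministic synthetic solution log.

    For every stage a player either (with probability ``fidelity``) selects
    the stage-restricted point set of a visible planted cluster — chosen at
    random among the visible ones with probability proportional to the
    compactness (inverse variance) of its projection, so that co-located
    clusters all receive answers — then flips each stage point's membership
    with probability ``flip_rate``; or selects a random circular blob on the
    display square.  Players flagged as oversized inflate every selection to
    at least three times its size.  Selections are never empty.
    """
    for name, val in (("fidelity", fidelity), ("flip_rate", flip_rate),
                      ("oversize_players", oversize_players)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    oversized = rng.random(n_players) < oversize_players

    # per (puzzle, stage): visible planted clusters, their stage point sets
    # and selection probabilities (compactness-weighted)
    stage_info = []
    for pz in puzzles:
        per_stage = []
        labels = dataset.labels[pz.point_ids]
        for st in pz.stages:
            options, weights = [], []
            for cid in np.unique(labels):
                if cid == NOISE:
                    continue
                mask = labels == cid
                if mask.sum() < 3:
                    continue
                coords = st.display_coords[mask]
                spread = float(coords.var(axis=0).sum())
                options.append(set(pz.point_ids[mask].tolist()))
                weights.append(1.0 / max(spread, 1e-6))
            probs = None
            if options:
                w = np.asarray(weights)
                probs = w / w.sum()
            per_stage.append((options, probs))
        stage_info.append(per_stage)

    id_pos = {pz.puzzle_id: k for k, pz in enumerate(puzzles)}
    solutions: list[Solution] = []
    for p in range(n_players):
        player = f"p{p:04d}"
        for pz in puzzles:
            sels: list[set[int] | None] = []
            for s_idx, st in enumerate(pz.stages):
                n_stage = len(st.point_ids)
                if n_stage == 0:
                    warnings.warn(f"empty stage {s_idx} in {pz.puzzle_id}; skipped")
                    sels.append(None)
                    continue
                options, probs = stage_info[id_pos[pz.puzzle_id]][s_idx]
                faithful = options and rng.random() < fidelity
                if faithful:
                    choice = int(rng.choice(len(options), p=probs))
                    selected = set(options[choice])
                    if flip_rate > 0:
                        flips = rng.random(n_stage) < flip_rate
                        for pid, fl in zip(st.point_ids.tolist(), flips):
                            if fl:
                                selected.symmetric_difference_update({pid})
                else:
                    center = rng.uniform(0, 1, size=2)
                    radius = rng.uniform(0.05, 0.3)
                    dist = np.linalg.norm(st.display_coords - center, axis=1)
                    selected = set(st.point_ids[dist < radius].tolist())
                    if not selected:
                        selected = {int(st.point_ids[int(np.argmin(dist))])}
                if not selected:  # flips can empty a faithful answer
                    selected = {int(rng.choice(st.point_ids))}
                if oversized[p]:
                    factor = rng.uniform(3.0, 6.0)
                    target = min(int(round(factor * len(selected))), n_stage)
                    pool = np.array(sorted(set(st.point_ids.tolist()) - selected))
                    extra = target - len(selected)
                    if extra > 0 and len(pool):
                        selected |= set(rng.choice(pool, size=min(extra, len(pool)),
                                                   replace=False).tolist())
                sels.append(selected)
            solutions.append(Solution(player, pz.puzzle_id, sels))
    return solutions


def selection_stats(solutions: list[Solution], puzzles: list[Puzzle],
                    n_points: int | None = None) -> SelectionStats:
    """Tally per-point exposures and selections over all stage-answers.

    A stage-answer counts as one exposure for every point of its puzzle;
    answers that are ``None`` (removed/missing) count neither exposures nor
    selections.
    """
    by_id = {pz.puzzle_id: pz for pz in puzzles}
    if n_points is None:
        n_points = 1 + max(int(pz.point_ids.max()) for pz in puzzles)
    f = np.zeros(n_points, dtype=int)
    n = np.zeros(n_points, dtype=int)
    for sol in solutions:
        pz = by_id.get(sol.puzzle_id)
        if pz is None:
            raise MalformedSolutionError(f"unknown puzzle {sol.puzzle_id!r}")
        id_set = set(pz.point_ids.tolist())
        for sel in sol.selections:
            if sel is None:
                continue
            if not sel <= id_set:
                raise MalformedSolutionError(
                    f"selection for {sol.puzzle_id!r} contains points outside the puzzle"
                )
            n[pz.point_ids] += 1
            f[sorted(sel)] += 1
    return SelectionStats(f, n)


def acs_filter(solutions: list[Solution]) -> tuple[list[Solution], list[tuple[str, str, int]]]:
    """Remove each player's abnormally large selections (large-cluster bias).

    Per player, selections with size >= mean + 2 * population std of that
    player's selection sizes are dropped (replaced by ``None``), and the
    trim is repeated until stable so the filter is idempotent.  Players with
    fewer than five live selections, or zero size spread, are left alone.
    Returns the filtered log and a report of (player, puzzle, stage) drops.
    """
    kept = [replace(sol, selections=list(sol.selections)) for sol in solutions]
    by_player: dict[str, list[tuple[int, int]]] = {}
    for k, sol in enumerate(kept):
        for s_idx, sel in enumerate(sol.selections):
            if sel is not None:
                by_player.setdefault(sol.player_id, []).append((k, s_idx))
    report: list[tuple[str, str, int]] = []
    for player, slots in by_player.items():
        live = list(slots)
        while True:
            sizes = np.array([len(kept[k].selections[s]) for k, s in live])
            if len(sizes) < 5:
                break
            mean, std = sizes.mean(), sizes.std()  # population std
            if std == 0:
                break
            offenders = [ls for ls, sz in zip(live, sizes) if sz >= mean + 2 * std]
            if not offenders:
                break
            for k, s in offenders:
                report.append((player, kept[k].puzzle_id, s))
                kept[k].selections[s] = None
            live = [ls for ls in live if ls not in offenders]
    return kept, report


# ---------------------------------------------------------------------------
# JSON-lines solution log IO
# ---------------------------------------------------------------------------

def write_solutions(solutions: list[Solution], path: str | Path) -> None:
    """One record per answered stage:
    ``{"player_id", "puzzle_id", "stage_index", "selected": [...]}``."""
    with open(path, "w") as fh:
        for sol in solutions:
            for s_idx, sel in enumerate(sol.selections):
                if sel is None:
                    continue
                rec = {"player_id": sol.player_id, "puzzle_id": sol.puzzle_id,
                       "stage_index": s_idx, "selected": sorted(sel)}
                fh.write(json.dumps(rec) + "\n")


def read_solutions(path: str | Path, puzzles: list[Puzzle]) -> list[Solution]:
    """Read a solution log; tolerates both the per-stage record dialect and a
    per-puzzle grouped dialect ``{"player_id", "puzzle_id", "selections":
    [[...], null, ...]}``."""
    n_stages = {pz.puzzle_id: len(pz.stages) for pz in puzzles}
    acc: dict[tuple[str, str], list[set[int] | None]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            key = (str(rec["player_id"]), str(rec["puzzle_id"]))
            if key[1] not in n_stages:
                raise MalformedSolutionError(f"unknown puzzle {key[1]!r}")
            slots = acc.setdefault(key, [None] * n_stages[key[1]])
            if "selections" in rec:  # grouped dialect
                for s_idx, sel in enumerate(rec["selections"]):
                    if sel is not None:
                        slots[s_idx] = set(int(i) for i in sel)
            else:
                slots[int(rec["stage_index"])] = set(int(i) for i in rec["selected"])
    return [Solution(player, pzid, sels) for (player, pzid), sels in acc.items()]
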