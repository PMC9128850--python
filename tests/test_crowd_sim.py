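import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crowdclust.datagen import NOISE
from crowdclust.crowd_sim import (MalformedSolutionError, Solution, acs_filter,
                                  read_solutions, selection_stats,
                                  simulate_solutions, write_solutions)
from crowdclust.puzzle_engine import Puzzle, Stage, rescale_stage


def _toy_puzzle(pid, ids, n_stages=2):
    ids = np.asarray(ids)
    coords = rescale_stage(np.column_stack([ids, ids % 3]).astype(float))
    stages = [Stage((0, 1), ids, coords) for _ in range(n_stages)]
    return Puzzle(pid, ids, stages)


class TestSimulateSolutions:
    def test_noiseless_limit_reproduces_planted_clusters(self, small_dataset,
                                                         small_puzzles,
                                                         faithful_solutions):
        by_id = {pz.puzzle_id: pz for pz in small_puzzles}
        planted = {
            cid: set(np.nonzero(small_dataset.labels == cid)[0].tolist())
            for cid in range(len(small_dataset.specs))
        }
        for sol in faithful_solutions:
            pz = by_id[sol.puzzle_id]
            sample = set(pz.point_ids.tolist())
            for sel in sol.selections:
                assert any(sel == planted[cid] & sample for cid in planted)

    def test_every_visible_planted_cluster_gets_selected(self, small_dataset,
                                                         small_puzzles,
                                                         faithful_solutions):
        # compactness-weighted sampling must not starve co-located clusters
        selected_clusters = set()
        planted = {cid: set(np.nonzero(small_dataset.labels == cid)[0].tolist())
                   for cid in range(len(small_dataset.specs))}
        by_id = {pz.puzzle_id: pz for pz in small_puzzles}
        for sol in faithful_solutions:
            sample = set(by_id[sol.puzzle_id].point_ids.tolist())
            for sel in sol.selections:
                for cid in planted:
                    if sel == planted[cid] & sample:
                        selected_clusters.add(cid)
        assert selected_clusters == set(planted)

    def test_zero_fidelity_answers_carry_no_label_signal(self, small_dataset,
                                                         small_puzzles):
        from crowdclust.clocworks import build_pair_network
        sols = simulate_solutions(small_dataset, small_puzzles, 6,
                                  fidelity=0.0, seed=5)
        pn = build_pair_network(sols, small_puzzles, (0, 1),
                                small_dataset.n_points)
        lab = small_dataset.labels
        iu, ju = np.nonzero(np.triu(pn.defined, 1))
        keep = (lab[iu] != NOISE) & (lab[ju] != NOISE)
        same = lab[iu] == lab[ju]
        w = pn.weight[iu, ju]
        intra, inter = w[keep & same].mean(), w[keep & ~same].mean()
        # random blobs co-select spatial neighbours, so a small geometric
        # residue remains; the planted-label contrast must be weak
        assert intra < inter + 0.1

    def test_oversized_players_inflate_selections(self, small_dataset,
                                                  small_puzzles):
        plain = simulate_solutions(small_dataset, small_puzzles, 4,
                                   fidelity=1.0, seed=13)
        fat = simulate_solutions(small_dataset, small_puzzles, 4,
                                 fidelity=1.0, oversize_players=1.0, seed=13)
        stage_n = small_puzzles[0].n_points
        mean_plain = np.mean([len(s) for sol in plain for s in sol.selections])
        mean_fat = np.mean([len(s) for sol in fat for s in sol.selections])
        assert mean_fat >= min(3 * mean_plain, 0.9 * stage_n)

    def test_selections_never_empty_and_within_puzzle(self, small_dataset,
                                                      small_puzzles):
        sols = simulate_solutions(small_dataset, small_puzzles, 3,
                                  fidelity=0.5, flip_rate=0.3, seed=21)
        by_id = {pz.puzzle_id: pz for pz in small_puzzles}
        for sol in sols:
            sample = set(by_id[sol.puzzle_id].point_ids.tolist())
            for sel in sol.selections:
                assert sel and sel <= sample

    def test_determinism(self, small_dataset, small_puzzles):
        a = simulate_solutions(small_dataset, small_puzzles, 3, 0.7, 0.1, 0.2, seed=8)
        b = simulate_solutions(small_dataset, small_puzzles, 3, 0.7, 0.1, 0.2, seed=8)
        assert [(s.player_id, s.puzzle_id, s.selections) for s in a] == \
            [(s.player_id, s.puzzle_id, s.selections) for s in b]

    def test_out_of_range_parameters_rejected(self, small_dataset, small_puzzles):
        with pytest.raises(ValueError):
            simulate_solutions(small_dataset, small_puzzles, 2, fidelity=1.5)


class TestSelectionStats:
    def test_direct_ratio(self):
        pz = _toy_puzzle("a", [0, 1, 2], n_stages=2)
        sols = [Solution("p1", "a", [{0, 1}, {0}]),
                Solution("p2", "a", [{0, 2}, {1}])]
        stats = selection_stats(sols, [pz], 3)
        assert stats.n_appeared[0] == 4 and stats.f_clustered[0] == 3
        assert stats.weights[0] == pytest.approx(0.75)

    def test_never_selected_point_has_zero_weight(self):
        pz = _toy_puzzle("a", [0, 1], n_stages=1)
        stats = selection_stats([Solution("p", "a", [{0}])], [pz], 3)
        assert stats.weights[1] == 0.0

    def test_never_shown_point_is_undefined(self):
        pz = _toy_puzzle("a", [0, 1], n_stages=1)
        stats = selection_stats([Solution("p", "a", [{0}])], [pz], 3)
        assert np.isnan(stats.weights[2])

    def test_matches_bruteforce_tally(self, small_dataset, small_puzzles,
                                      faithful_solutions):
        stats = selection_stats(faithful_solutions, small_puzzles,
                                small_dataset.n_points)
        by_id = {pz.puzzle_id: pz for pz in small_puzzles}
        for x in range(0, small_dataset.n_points, 17):
            n_app = f_cl = 0
            for sol in faithful_solutions:
                pz = by_id[sol.puzzle_id]
                present = x in set(pz.point_ids.tolist())
                for sel in sol.selections:
                    if sel is None:
                        continue
                    n_app += present
                    f_cl += x in sel
            assert stats.n_appeared[x] == n_app
            assert stats.f_clustered[x] == f_cl

    def test_exposure_conservation(self, small_dataset, small_puzzles,
                                   faithful_solutions):
        stats = selection_stats(faithful_solutions, small_puzzles,
                                small_dataset.n_points)
        by_id = {pz.puzzle_id: pz for pz in small_puzzles}
        expected = sum(by_id[s.puzzle_id].n_points
                       for s in faithful_solutions
                       for sel in s.selections if sel is not None)
        assert stats.n_appeared.sum() == expected

    def test_foreign_point_rejected(self):
        pz = _toy_puzzle("a", [0, 1], n_stages=1)
        with pytest.raises(MalformedSolutionError):
            selection_stats([Solution("p", "a", [{0, 9}])], [pz], 10)


class TestAcsFilter:
    @staticmethod
    def _log_with_sizes(sizes, player="p"):
        n = max(sizes) + 1
        pz = _toy_puzzle("a", list(range(n)), n_stages=len(sizes))
        sols = [Solution(player, "a", [set(range(s)) for s in sizes])]
        return sols, pz

    def test_hand_computed_outlier_dropped(self):
        sols, _ = self._log_with_sizes([10, 10, 10, 10, 50])
        kept, report = acs_filter(sols)
        # mean 18, population std 16 -> 50 >= 18 + 32 is dropped
        assert [r[2] for r in report] == [4]
        assert kept[0].selections[4] is None
        assert all(kept[0].selections[i] is not None for i in range(4))

    def test_equal_sizes_untouched(self):
        sols, _ = self._log_with_sizes([7] * 6)
        kept, report = acs_filter(sols)
        assert report == []
        assert all(s is not None for s in kept[0].selections)

    def test_small_players_skipped(self):
        sols, _ = self._log_with_sizes([1, 1, 1, 30])
        _, report = acs_filter(sols)
        assert report == []

    def test_empty_log(self):
        kept, report = acs_filter([])
        assert kept == [] and report == []

    def test_input_log_not_mutated(self):
        sols, _ = self._log_with_sizes([10, 10, 10, 10, 50])
        acs_filter(sols)
        assert all(sel is not None for sel in sols[0].selections)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(1, 40), min_size=1, max_size=25),
           st.integers(0, 10**6))
    def test_idempotent(self, sizes, salt):
        sols, _ = self._log_with_sizes(sizes, player=f"p{salt}")
        once, _ = acs_filter(sols)
        twice, report2 = acs_filter(once)
        assert report2 == []
        assert [s.selections for s in twice] == [s.selections for s in once]


class TestSolutionIO:
    def test_jsonl_roundtrip(self, small_dataset, small_puzzles,
                             faithful_solutions, tmp_path):
        path = tmp_path / "sols.jsonl"
        write_solutions(faithful_solutions, path)
        back = read_solutions(path, small_puzzles)
        orig = {(s.player_id, s.puzzle_id): s.selections for s in faithful_solutions}
        assert len(back) == len(faithful_solutions)
        for sol in back:
            assert sol.selections == orig[(sol.player_id, sol.puzzle_id)]

    def test_grouped_dialect(self, small_puzzles, tmp_path):
        import json
        pz = small_puzzles[0]
        sels = [sorted(pz.point_ids[:3].tolist())] + [None] * (len(pz.stages) - 1)
        path = tmp_path / "grouped.jsonl"
        path.write_text(json.dumps({"player_id": "p0", "puzzle_id": pz.puzzle_id,
                                    "selections": sels}) + "\n")
        back = read_solutions(path, small_puzzles)
        assert back[0].selections[0] == set(pz.point_ids[:3].tolist())
        assert back[0].selections[1] is None

    def test_unknown_puzzle_rejected(self, small_puzzles, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"player_id": "p", "puzzle_id": "nope", '
                        '"stage_index": 0, "selected": [1]}\n')
        with pytest.raises(MalformedSolutionError):
            read_solutions(path, small_puzzles)
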