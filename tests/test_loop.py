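"""Active-learning loop: initialization, selection, iteration, convergence."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import alscreen as als
from alscreen.loop import ScreenError


def tiny_config(seed=0, **kw):
    defaults = dict(
        n_train_init=150, n_test_init=300, n_select_top=50, n_select_random=50,
        max_iterations=10, rescore_top_k=30, seed=seed,
        surrogate=als.SurrogateConfig(
            hidden_sizes=(32, 32), max_epochs=8, patience=3, batch_size=128,
            learning_rate=3e-3, seed=seed,
        ),
    )
    defaults.update(kw)
    return als.ScreenConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_campaign(tiny_library):
    records, truth = tiny_library
    oracle = als.make_synthetic_oracle(truth.reference_fps, depth=12.0, noise_sd=1.0, seed=1)
    config = tiny_config(seed=1)
    state = als.init_screen(records, oracle, config)
    for _ in range(3):
        als.run_iteration(state, records, oracle, config)
    return records, truth, oracle, config, state


class TestInitScreen:
    def test_counts_and_disjointness(self, tiny_library):
        records, truth = tiny_library
        oracle = als.make_synthetic_oracle(truth.reference_fps, seed=0)
        config = tiny_config()
        state = als.init_screen(records, oracle, config)
        assert state.n_docked == 450  # 150 train + 300 test
        assert not set(state.train_ids) & set(state.test_ids)
        assert state.iteration == 1
        assert state.cutoff_history[0][0] == 10.0

    def test_same_seed_reproduces_samples(self, tiny_library):
        records, truth = tiny_library
        oracle = als.make_synthetic_oracle(truth.reference_fps, seed=0)
        a = als.init_screen(records, oracle, tiny_config(seed=3))
        b = als.init_screen(records, oracle, tiny_config(seed=3))
        assert a.train_ids == b.train_ids
        assert a.test_ids == b.test_ids

    def test_library_too_small_raises(self, tiny_library):
        records, truth = tiny_library
        oracle = als.make_synthetic_oracle(truth.reference_fps)
        with pytest.raises(ScreenError):
            als.init_screen(records[:100], oracle, tiny_config())


class TestSelectNextBatch:
    def test_greedy_part_equals_full_sort_argmax(self, tiny_campaign):
        records, _, _, config, state = (
            tiny_campaign[0], tiny_campaign[1], tiny_campaign[2],
            tiny_campaign[3], tiny_campaign[4],
        )
        selection = als.select_next_batch(state.model, records, state, config)
        undocked = [r for r in records if r.id not in state.docked]
        fps = np.stack([r.fingerprint for r in undocked])
        probs = als.predict_library(state.model, fps)
        ids = np.array([r.id for r in undocked])
        order = np.lexsort((ids, -probs))
        expected_greedy = [str(x) for x in ids[order[: config.n_select_top]]]
        assert selection[: config.n_select_top] == expected_greedy
        # random part: undocked, not in greedy, no duplicates
        rand = selection[config.n_select_top :]
        assert len(rand) == config.n_select_random
        assert not set(rand) & set(expected_greedy)
        assert len(set(selection)) == len(selection)

    def test_fully_docked_library_returns_empty(self, tiny_library):
        records, truth = tiny_library
        small = records[:460]
        oracle = als.make_synthetic_oracle(truth.reference_fps, seed=0)
        config = tiny_config()
        state = als.init_screen(small, oracle, config)
        for r in small:  # mark everything docked
            if r.id not in state.docked:
                state.docked[r.id] = als.DockResult(r.id, -1.0, als.PoseProperties())
        assert als.select_next_batch(state.model, small, state, config) == []

    def test_truncation_when_fewer_remain_than_requested(self, tiny_library):
        records, truth = tiny_library
        small = records[:500]  # 450 docked at init, 50 undocked < 100 requested
        oracle = als.make_synthetic_oracle(truth.reference_fps, seed=0)
        config = tiny_config()
        state = als.init_screen(small, oracle, config)
        selection = als.select_next_batch(state.model, small, state, config)
        assert len(selection) == 50
        assert state.truncated


class TestRunIteration:
    def test_docked_set_growth_bounded_and_monotone(self, tiny_campaign):
        *_, config, state = tiny_campaign
        assert state.iteration == 4
        assert state.n_docked <= 450 + 3 * (config.n_select_top + config.n_select_random)
        assert state.n_docked > 450

    def test_cutoff_history_follows_schedule_and_tightens(self, tiny_campaign):
        *_, state = tiny_campaign
        percents = [p for p, _ in state.cutoff_history]
        expected = [als.schedule_percent(i) for i in range(1, len(percents) + 1)]
        assert percents == pytest.approx(expected)
        cutoffs = [c for _, c in state.cutoff_history]
        assert all(a >= b for a, b in zip(cutoffs, cutoffs[1:]))

    def test_best_dG_history_non_increasing(self, tiny_campaign):
        *_, state = tiny_campaign
        hist = state.best_dG_history
        assert all(a >= b for a, b in zip(hist, hist[1:]))

    def test_top_percentile_summary_non_increasing(self, tiny_campaign):
        *_, state = tiny_campaign
        tp = state.top_percentile_dG
        assert all(a >= b - 1e-9 for a, b in zip(tp, tp[1:]))


class TestConvergence:
    def test_max_iterations_reached(self):
        config = tiny_config(max_iterations=10)
        state = als.IterationState(iteration=10, dG={"a": -5.0})
        state.best_dG_history = [-5.0] * 10
        assert als.check_convergence(state, config)

    def test_strongly_improving_history_not_converged(self):
        config = tiny_config()
        state = als.IterationState(iteration=4)
        state.best_dG_history = [-5.0, -6.0, -7.0, -8.0]
        assert not als.check_convergence(state, config)

    def test_flat_history_converges_after_patience(self):
        config = tiny_config()  # tolerance 0.1, patience 2
        state = als.IterationState(iteration=3)
        state.best_dG_history = [-7.0, -7.0, -7.0]
        assert als.check_convergence(state, config)
        state.best_dG_history = [-7.0, -7.0, -7.05]
        assert als.check_convergence(state, config)  # below tolerance


class TestRescoreTop:
    def test_k_zero_empty_table(self, tiny_campaign):
        records, _, oracle, config, state = tiny_campaign
        df = als.rescore_top(state, records, oracle, 0, config)
        assert len(df) == 0

    def test_noise_free_oracle_rescoring_permutes_same_ids(self, tiny_library):
        records, truth = tiny_library
        oracle = als.make_synthetic_oracle(truth.reference_fps, noise_sd=0.0, seed=0)
        config = tiny_config()
        state = als.init_screen(records, oracle, config)
        before = set(sorted(state.dG, key=lambda i: (state.dG[i], i))[:30])
        df = als.rescore_top(state, records, oracle, 30, config)
        assert set(df["compound_id"]) == before

    def test_high_precision_rescoring_improves_rank_fidelity(self, tiny_library):
        records, truth = tiny_library
        oracle = als.make_synthetic_oracle(
            truth.reference_fps, depth=12.0, noise_sd=2.0, seed=5
        )
        config = tiny_config(seed=5)
        state = als.init_screen(records, oracle, config)
        k = 100
        top_ids = sorted(state.dG, key=lambda i: (state.dG[i], i))[:k]
        truth_dh = {r.id: truth.true_dH[r.id] for r in records}
        express_rho = spearmanr(
            [state.docked[i].dH for i in top_ids], [truth_dh[i] for i in top_ids]
        ).statistic
        als.rescore_top(state, records, oracle, k, config)
        high_rho = spearmanr(
            [state.docked[i].dH for i in top_ids], [truth_dh[i] for i in top_ids]
        ).statistic
        assert high_rho > express_rho

    def test_k_exceeding_docked_raises(self, tiny_campaign):
        records, _, oracle, config, state = tiny_campaign
        with pytest.raises(ScreenError):
            als.rescore_top(state, records, oracle, state.n_docked + 1, config)


class TestManifestReplay:
    def test_campaign_replays_bit_for_bit(self, tiny_library):
        records, truth = tiny_library
        oracle = als.make_synthetic_oracle(truth.reference_fps, noise_sd=1.0, seed=2)
        config = tiny_config(seed=2, max_iterations=3)
        first = als.run_campaign(records, oracle, config)
        replay = als.run_from_manifest(records, oracle, first.manifest)
        assert first.state.selection_history == replay.state.selection_history
        assert first.state.cutoff_history == replay.state.cutoff_history
        assert first.manifest["model_hashes"] == replay.manifest["model_hashes"]
        assert first.final_ranking.equals(replay.final_ranking)

    def test_manifest_roundtrips_through_json(self, tmp_path, tiny_library):
        records, truth = tiny_library
        oracle = als.make_synthetic_oracle(truth.reference_fps, seed=2)
        config = tiny_config(seed=2, max_iterations=2)
        result = als.run_campaign(records, oracle, config, rescore=False)
        path = tmp_path / "manifest.json"
        als.save_manifest(result.manifest, str(path))
        loaded = als.load_manifest(str(path))
        replay = als.run_from_manifest(records, oracle, loaded)
        assert result.state.selection_history == replay.state.selection_history
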