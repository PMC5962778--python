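"""Closed-loop stepping, schedules, success estimators and the test phase."""

import numpy as np
import pytest

from handregard import world as gw
from handregard.encoding import TEST_CASES, TRAINING_CASE
from handregard.experiment import test_case_run as evaluate_case
from handregard.experiment import (
    RunConfig,
    Simulation,
    SuccessSeries,
    baseline_success_probability,
    ensemble_average,
    paired_series,
    run_suite,
    seed_streams,
    servo_convergence,
    train,
)
from handregard.network import init_network
from handregard.rtrl import RTRLTrainer, motor_errors


def tiny_run_config(**overrides):
    base = dict(
        total_steps=4_000,
        checkpoint_period=1_000,
        train_obs_interval=1_000,
        train_obs_window=200,
        reposition_period=1_000,
        other_move_period=50,
        test_window=2_000,
        test_placements=2,
        n_seeds=2,
    )
    base.update(overrides)
    return RunConfig(**base)


def make_sim(cfg, seed=0, case=TRAINING_CASE, run_config=None, training=True):
    streams = seed_streams(seed)
    net = init_network(streams["network"], cfg.layout.total, cfg.network, cfg.layout.cd)
    trainer = RTRLTrainer(net, cfg.trainer) if training else None
    return Simulation(
        cfg.geometry, cfg.layout, net, case,
        run_config or tiny_run_config(), streams["world"], cfg.decoder, trainer,
    )


class TestRunConfig:
    def test_paper_schedule_arithmetic(self, full_cfg):
        run = full_cfg.run
        assert run.total_steps // run.checkpoint_period == 55
        assert run.test_window // run.reposition_period == run.test_placements
        # observation window from the 3h/week observation ratio: 5e5 * 3/168 ~ 1e4
        assert run.train_obs_interval * 3 / 168 == pytest.approx(
            run.train_obs_window, rel=0.12
        )

    def test_inconsistent_test_window_rejected(self):
        with pytest.raises(ValueError):
            tiny_run_config(test_window=1_500)

    def test_success_series_validation(self):
        with pytest.raises(ValueError):
            SuccessSeries(np.array([0, 0]), np.array([0.1, 0.2]), "training")
        with pytest.raises(ValueError):
            SuccessSeries(np.array([0, 1]), np.array([0.1, 1.2]), "training")

    def test_paired_series_averages_window_pairs(self):
        raw = SuccessSeries(
            np.array([100, 200, 300, 400, 500]),
            np.array([0.1, 0.3, 0.5, 0.7, 0.2]),
            "training",
        )
        paired = paired_series(raw)
        np.testing.assert_array_equal(paired.steps, [150, 350])
        np.testing.assert_allclose(paired.rates, [0.2, 0.6])


class TestStepLoop:
    def test_replay_equality_under_fixed_seed(self, scaled_cfg):
        logs = []
        for _ in range(2):
            sim = make_sim(scaled_cfg, seed=5)
            log = []
            for _ in range(2_000):
                sim.step()
                log.append(
                    (sim.world.left_hand, sim.world.right_hand, tuple(sim.world.others))
                )
            logs.append(log)
        assert logs[0] == logs[1]

    def test_untrained_outputs_cannot_cross_threshold_early(self, scaled_cfg):
        # init weights in [-0.1, 0.1] keep |activity difference| << 0.8,
        # so the hands stay put until learning saturates the outputs
        sim = make_sim(scaled_cfg, seed=1, training=False)
        start = (sim.world.left_hand, sim.world.right_hand)
        for _ in range(500):
            sim.step()
        assert (sim.world.left_hand, sim.world.right_hand) == start

    def test_inline_errors_match_cm_frame_equations(self, scaled_cfg):
        """The fast block-index error path equals Eqs-style cm computation."""
        sim = make_sim(scaled_cfg, seed=2)
        g = scaled_cfg.geometry
        for _ in range(300):
            pre_left, pre_right = sim.world.left_hand, sim.world.right_hand
            sim.step()
            expected = motor_errors(
                gw.perceived_block(pre_left, g),
                gw.perceived_block(pre_right, g),
                g,
            )
            np.testing.assert_array_equal(sim.last_errors, expected)

    def test_positions_stay_inside_area_under_training(self, scaled_cfg):
        sim = make_sim(scaled_cfg, seed=3)
        for _ in range(3_000):
            sim.step()
            assert scaled_cfg.geometry.contains(sim.world.left_hand)
            assert scaled_cfg.geometry.contains(sim.world.right_hand)

    def test_reposition_fires_on_schedule(self, scaled_cfg):
        rc = tiny_run_config(reposition_period=100, test_window=200, test_placements=2)
        sim = make_sim(scaled_cfg, seed=4, run_config=rc, training=False)
        # hands cannot move (untrained); any change must come from repositioning
        changes = []
        last = sim.world.left_hand
        for t in range(1, 501):
            sim.step()
            if sim.world.left_hand != last:
                changes.append(t)
                last = sim.world.left_hand
        # the re-placement at t = 100k is first observable after the
        # step that begins at that t (the 100k+1-th step call)
        assert changes and all((c - 1) % 100 == 0 for c in changes)


class TestTraining:
    def test_checkpoint_count_and_window_scoring(self, scaled_cfg):
        rc = tiny_run_config()
        res = train(
            scaled_cfg.geometry, scaled_cfg.layout, scaled_cfg.network, rc,
            scaled_cfg.trainer, seed=0,
        )
        assert sorted(res.checkpoints) == [0, 1000, 2000, 3000, 4000]
        assert len(res.window_series.rates) == 4
        assert len(res.series.rates) == 2
        assert ((res.window_series.rates >= 0) & (res.window_series.rates <= 1)).all()

    def test_training_is_seed_deterministic(self, scaled_cfg):
        rc = tiny_run_config()
        runs = [
            train(
                scaled_cfg.geometry, scaled_cfg.layout, scaled_cfg.network, rc,
                scaled_cfg.trainer, seed=9,
            )
            for _ in range(2)
        ]
        assert runs[0].network.weights_hash() == runs[1].network.weights_hash()
        np.testing.assert_array_equal(runs[0].window_series.rates,
                                      runs[1].window_series.rates)

    def test_servo_converges_on_scaled_network(self, scaled_cfg):
        steps = servo_convergence(
            scaled_cfg.geometry, scaled_cfg.layout, scaled_cfg.network,
            scaled_cfg.trainer, seed=0, max_steps=20_000,
        )
        assert steps is not None and steps <= 20_000


class TestTestPhase:
    def test_weights_frozen_through_test_run(self, scaled_cfg):
        sim = make_sim(scaled_cfg, seed=6, case=TEST_CASES[1], training=False)
        before = sim.net.weights_hash()
        for _ in range(2_000):
            sim.step()
        assert sim.net.weights_hash() == before

    def test_untrained_baseline_matches_analytic(self, scaled_cfg):
        """Motionless hands: success = P(>=1 of 2 uniform hands in center)."""
        p = baseline_success_probability(scaled_cfg.geometry)
        assert p == pytest.approx(1 - (1 - 9 / 81) ** 2)
        rc = tiny_run_config(
            test_window=100_000, test_placements=100, total_steps=100_000,
            checkpoint_period=100_000, train_obs_interval=100_000,
            train_obs_window=100,
        )
        streams = seed_streams(11)
        net = init_network(
            streams["network"], scaled_cfg.layout.total, scaled_cfg.network,
            scaled_cfg.layout.cd,
        )
        rate = evaluate_case(
            net, 1, scaled_cfg.geometry, scaled_cfg.layout, rc, world_seed=11
        )
        se = np.sqrt(p * (1 - p) / rc.test_placements)
        assert abs(rate - p) <= 3 * se

    def test_all_cases_see_identical_worlds_at_a_seed(self, scaled_cfg):
        """Paired comparison: the world stream is independent of the case."""
        rc = tiny_run_config()
        worlds = {}
        for cid in (1, 4):
            streams = seed_streams(12)
            net = init_network(
                streams["network"], scaled_cfg.layout.total, scaled_cfg.network,
                scaled_cfg.layout.cd,
            )
            rng = np.random.default_rng(np.random.PCG64(np.random.SeedSequence(99)))
            sim = Simulation(
                scaled_cfg.geometry, scaled_cfg.layout, net, TEST_CASES[cid], rc,
                rng, scaled_cfg.decoder, None,
            )
            log = []
            for _ in range(300):
                sim.step()
                log.append((sim.world.left_hand, sim.world.right_hand))
            worlds[cid] = log
        assert worlds[1] == worlds[4]

    def test_unknown_case_id_rejected(self, scaled_cfg):
        streams = seed_streams(0)
        net = init_network(
            streams["network"], scaled_cfg.layout.total, scaled_cfg.network,
            scaled_cfg.layout.cd,
        )
        with pytest.raises(KeyError):
            evaluate_case(
                net, 99, scaled_cfg.geometry, scaled_cfg.layout, tiny_run_config(),
                world_seed=0,
            )


class TestSuite:
    def test_result_table_shape_and_ensemble(self, scaled_cfg):
        rc = tiny_run_config(total_steps=2_000, checkpoint_period=1_000)
        results = [
            train(
                scaled_cfg.geometry, scaled_cfg.layout, scaled_cfg.network, rc,
                scaled_cfg.trainer, seed=s,
            )
            for s in range(2)
        ]
        table = run_suite(
            results, scaled_cfg.geometry, scaled_cfg.layout, rc, cases=(1, 7)
        )
        assert len(table) == 2 * 3 * 2  # seeds x checkpoints(0,1000,2000) x cases
        assert set(table.columns) == {"seed", "step", "case", "rate"}
        avg = ensemble_average(table)
        assert len(avg) == 3 * 2
        manual = table[(table.step == 1000) & (table.case == 1)].rate.mean()
        got = avg[(avg.step == 1000) & (avg.case == 1)].rate.iloc[0]
        assert got == pytest.approx(manual)
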