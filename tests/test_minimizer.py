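"""Metropolis engine: decisions, bookkeeping, temperature, stages, fold."""

import hashlib

import numpy as np
import pytest

from ssefold.config import RunConfig, StageSchedule, TemperatureSettings
from ssefold.minimizer import (
    MinimizerError, TemperatureController, _update_temperature_counts, fold,
    initial_model, metropolis_decide, run_stage, step_bookkeeping,
    update_temperature,
)
from ssefold.moves import build_move_set
from ssefold.pool import PoolEntry, SSEPool


class TestMetropolisDecide:
    def test_downhill_always_improves(self):
        rng = np.random.default_rng(0)
        for temperature in (1e-3, 1.0, 1e6):
            assert metropolis_decide(-1.0, 0.0, temperature, rng) == "improved"

    def test_acceptance_probability_half_at_kT_ln2(self):
        """dE = kT ln 2 gives acceptance probability exactly 0.5."""
        rng = np.random.default_rng(123)
        temperature = 50.0
        de = temperature * np.log(2.0)
        n = 100_000
        accepted = sum(
            metropolis_decide(de, 0.0, temperature, rng) == "accepted"
            for _ in range(n)
        )
        sigma = np.sqrt(n * 0.25)
        assert abs(accepted - 0.5 * n) <= 3 * sigma

    def test_huge_uphill_rejected(self):
        rng = np.random.default_rng(1)
        assert metropolis_decide(1e6, 0.0, 1.0, rng) == "rejected"

    def test_temperature_limits(self):
        rng = np.random.default_rng(2)
        # T -> infinity: all uphill accepted; T -> 0+: none
        up = [metropolis_decide(10.0, 0.0, 1e12, rng) for _ in range(200)]
        assert all(o == "accepted" for o in up)
        down = [metropolis_decide(10.0, 0.0, 1e-9, rng) for _ in range(200)]
        assert all(o == "rejected" for o in down)

    def test_non_finite_energy_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(MinimizerError):
            metropolis_decide(np.nan, 0.0, 1.0, rng)


class TestBookkeeping:
    def test_improved_promotes_to_best(self):
        w, b = step_bookkeeping("improved", "new", "old_w", "old_b")
        assert (w, b) == ("new", "new")

    def test_accepted_advances_working_only(self):
        w, b = step_bookkeeping("accepted", "new", "old_w", "old_b")
        assert (w, b) == ("new", "old_b")

    def test_rejected_resets_to_best(self):
        w, b = step_bookkeeping("rejected", "new", "old_w", "old_b")
        assert (w, b) == ("old_b", "old_b")

    def test_skipped_resets_to_best(self):
        w, b = step_bookkeeping("skipped", None, "old_w", "old_b")
        assert (w, b) == ("old_b", "old_b")


class TestTemperature:
    def test_target_falls_linearly(self):
        s = TemperatureSettings()
        for f in (0.0, 0.25, 0.5, 1.0):
            assert s.target(f) == pytest.approx(0.5 - 0.3 * f)

    def test_tie_cools(self):
        ctrl = TemperatureController()
        t0 = ctrl.temperature
        # ratio exactly at target (0.5 at progress 0) -> cool branch
        update_temperature(ctrl, ["improved", "rejected"], 0.0)
        assert ctrl.temperature == pytest.approx(t0 * 0.95)

    def test_all_rejected_heats_until_clamp(self):
        ctrl = TemperatureController()
        for _ in range(500):
            update_temperature(ctrl, ["rejected"] * 10, 0.0)
        assert ctrl.temperature == ctrl.settings.t_max

    def test_skipped_excluded_from_denominator(self):
        ctrl_a = TemperatureController()
        ctrl_b = TemperatureController()
        update_temperature(ctrl_a, ["improved", "rejected"], 0.0)
        update_temperature(
            ctrl_b, ["improved", "rejected"] + ["skipped"] * 50, 0.0
        )
        assert ctrl_a.temperature == ctrl_b.temperature

    def test_controller_tracks_target_on_logistic_landscape(self):
        """With acceptance a smooth decreasing function of 1/T, the
        cumulative ratio converges to the moving target."""
        rng = np.random.default_rng(0)
        ctrl = TemperatureController()
        accepted = 0
        non_skipped = 0
        n_steps = 2000
        for step in range(1, n_steps + 1):
            p_accept = 1.0 / (1.0 + (40.0 / ctrl.temperature))  # logistic oracle
            accepted += rng.random() < p_accept
            non_skipped += 1
            if step % 10 == 0:
                _update_temperature_counts(
                    ctrl, accepted, non_skipped, step / n_steps
                )
        ratio = accepted / non_skipped
        assert abs(ratio - ctrl.settings.target(1.0)) < 0.05


def _toy_stage_inputs(toy):
    pool = toy.pool
    cfg = RunConfig()
    move_set = build_move_set(pool, "assembly", cfg.move)
    model0 = initial_model(toy.sequence, pool, np.random.default_rng(0))
    return pool, cfg, move_set, model0


class TestRunStage:
    def test_pathological_scorer_stops_at_nonimproving_cap(self, toy):
        """A scorer that always worsens terminates after exactly 1000
        consecutive non-improving steps."""
        pool, cfg, move_set, model0 = _toy_stage_inputs(toy)
        counter = {"n": 0}

        def worsening_scorer(model):
            counter["n"] += 1
            return float(counter["n"])  # every new model is worse

        best, traj = run_stage(
            model0, move_set, worsening_scorer,
            StageSchedule("assembly", 5000, 1000),
            TemperatureController(TemperatureSettings(t0=1e-3, t_max=1e-3)),
            np.random.default_rng(1), pool, cfg.move,
        )
        outcomes = [rec.outcome for rec in traj]
        assert "improved" not in outcomes
        assert len(traj) == 1000
        assert best is model0

    def test_same_seed_identical_trajectory(self, toy):
        pool, cfg, move_set, model0 = _toy_stage_inputs(toy)
        from ssefold.energy import score_model

        def scorer(m):
            return score_model(m, toy.prediction, cfg.weights, cfg.energy).total

        def digest():
            _, traj = run_stage(
                model0, move_set, scorer, StageSchedule("assembly", 300, 1000),
                TemperatureController(), np.random.default_rng(5), pool, cfg.move,
            )
            blob = "|".join(
                f"{r.move},{r.outcome},{r.e_new:.9g},{r.e_best:.9g}" for r in traj
            )
            return hashlib.sha256(blob.encode()).hexdigest()

        assert digest() == digest()

    def test_best_energy_non_increasing_and_outcomes_partition(self, toy):
        pool, cfg, move_set, model0 = _toy_stage_inputs(toy)
        from ssefold.energy import score_model

        def scorer(m):
            return score_model(m, toy.prediction, cfg.weights, cfg.energy).total

        _, traj = run_stage(
            model0, move_set, scorer, StageSchedule("assembly", 400, 1000),
            TemperatureController(), np.random.default_rng(8), pool, cfg.move,
        )
        e_best = [r.e_best for r in traj]
        assert all(b <= a + 1e-9 for a, b in zip(e_best, e_best[1:]))
        counts = traj.outcome_counts()
        assert sum(counts.values()) == len(traj)
        assert set(counts) == {"improved", "accepted", "rejected", "skipped"}

    def test_refinement_schedule_cap(self, toy):
        pool, cfg, _, model0 = _toy_stage_inputs(toy)
        move_set = build_move_set(pool, "refinement", cfg.move)
        counter = {"n": 0}

        def worsening_scorer(model):
            counter["n"] += 1
            return float(counter["n"])

        _, traj = run_stage(
            model0, move_set, worsening_scorer,
            StageSchedule("refinement", 2000, 400),
            TemperatureController(TemperatureSettings(t0=1e-3, t_max=1e-3)),
            np.random.default_rng(2), pool, cfg.move,
        )
        assert len(traj) == 400


class TestStagnation:
    def test_all_inapplicable_moves_raise(self, toy):
        """A move set whose every move skips on a complete model raises a
        stagnation error after a full non-improving sweep of skips."""
        from ssefold.geometry import RigidTransform, build_ideal_sse
        from ssefold.minimizer import StagnationError
        from ssefold.moves import MoveSet, REGISTRY

        # model already contains every pool region: add moves always skip
        sses = [
            build_ideal_sse(
                toy.sequence[e.first - 1 : e.last], e.first, e.last, e.ss_type
            ).transformed(RigidTransform.from_translation([12.0 * k, 0, 0]))
            for k, e in enumerate(toy.pool)
        ]
        model0 = toy.native.replace_sses(sses)
        add_only = [m for m in REGISTRY if m.name == "add_sse_random"]
        move_set = MoveSet(add_only, np.array([1.0]), "assembly")
        with pytest.raises(StagnationError):
            run_stage(
                model0, move_set, lambda m: 0.0,
                StageSchedule("assembly", 500, 50),
                TemperatureController(), np.random.default_rng(0),
                toy.pool, RunConfig().move,
            )


class TestFold:
    def test_models_reproducible_and_sorted(self, toy):
        cfg = RunConfig(
            assembly=StageSchedule("assembly", 250, 120),
            refinement=StageSchedule("refinement", 100, 60),
        )
        a = fold(toy.sequence, toy.pool, toy.prediction, cfg, n_models=3, seed=9)
        b = fold(toy.sequence, toy.pool, toy.prediction, cfg, n_models=3, seed=9)
        assert [r.energy for r in a] == [r.energy for r in b]
        energies = [r.energy for r in a]
        assert energies == sorted(energies)
        for ra, rb in zip(a, b):
            for sa, sb in zip(ra.model.sses, rb.model.sses):
                assert np.array_equal(sa.coords, sb.coords)

    def test_single_entry_pool_degenerates(self, toy):
        pool = SSEPool([PoolEntry("helix", toy.pool.entries[0].first,
                                  toy.pool.entries[0].last)])
        cfg = RunConfig(
            assembly=StageSchedule("assembly", 200, 100),
            refinement=StageSchedule("refinement", 80, 50),
        )
        res = fold(toy.sequence, pool, toy.prediction, cfg, n_models=1, seed=0)[0]
        assert res.model.n_sses == 1
        sse = res.model.sses[0]
        assert (sse.first, sse.last) == (pool.entries[0].first, pool.entries[0].last)
        counts = res.trajectories[0].outcome_counts()
        # with one SSE placed, add/swap/pair/domain moves mostly skip
        assert counts["skipped"] > 0.4 * len(res.trajectories[0])
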