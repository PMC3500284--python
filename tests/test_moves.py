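"""Move registry: applicability, weights, validity of produced models."""

import numpy as np
import pytest

from ssefold.geometry import CA, ProteinModel, build_ideal_sse
from ssefold.moves import (
    SKIPPED, MoveConfig, MoveError, build_move_set, detect_sheets, propose,
)
from ssefold.pool import PoolEntry, SSEPool

CFG = MoveConfig()


def all_helix_pool():
    return SSEPool([PoolEntry("helix", 1, 10), PoolEntry("helix", 15, 24)])


def mixed_pool():
    return SSEPool([
        PoolEntry("helix", 1, 10), PoolEntry("strand", 13, 18),
        PoolEntry("strand", 21, 26), PoolEntry("helix", 30, 39),
    ])


def model_from_pool(pool, sequence_length=45, which=None, rng=None):
    seq = "A" * sequence_length
    rng = rng or np.random.default_rng(0)
    sses = []
    for k, e in enumerate(pool):
        if which is not None and k not in which:
            continue
        sse = build_ideal_sse(seq[e.first - 1 : e.last], e.first, e.last, e.ss_type)
        from ssefold.geometry import RigidTransform
        sse = sse.transformed(
            RigidTransform.from_translation([10.0 * k, 0.0, 0.0])
        )
        sses.append(sse)
    return ProteinModel(seq, sses)


class TestBuildMoveSet:
    def test_all_helix_pool_zeroes_strand_moves(self):
        ms = build_move_set(all_helix_pool(), "assembly", CFG)
        for move, p in zip(ms.moves, ms.probabilities):
            if move.needs_strands:
                assert p == 0.0

    def test_mixed_pool_assembly_has_add_remove_swap(self):
        ms = build_move_set(mixed_pool(), "assembly", CFG)
        cats = {m.category for m, p in zip(ms.moves, ms.probabilities) if p > 0}
        assert {"add", "remove", "swap", "single_sse", "sse_pair", "domain"} <= cats

    def test_probabilities_renormalize_to_one(self):
        for pool in (all_helix_pool(), mixed_pool()):
            for stage in ("assembly", "refinement"):
                ms = build_move_set(pool, stage, CFG)
                assert ms.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_resize_moves_in_both_stages(self):
        for stage in ("assembly", "refinement"):
            ms = build_move_set(mixed_pool(), stage, CFG)
            names = {m.name for m, p in zip(ms.moves, ms.probabilities) if p > 0}
            assert {"sse_resize_nterm", "sse_resize_cterm"} <= names

    def test_empty_pool_rejected(self):
        with pytest.raises(MoveError):
            build_move_set(SSEPool([]), "assembly", CFG)

    def test_selection_frequencies_match_probabilities(self):
        """Multinomial check over 1e5 draws, 3 sigma per move."""
        ms = build_move_set(mixed_pool(), "assembly", CFG)
        rng = np.random.default_rng(0)
        n = 100_000
        counts = {m.name: 0 for m in ms.moves}
        for _ in range(n):
            counts[ms.sample(rng).name] += 1
        for move, p in zip(ms.moves, ms.probabilities):
            if p == 0:
                assert counts[move.name] == 0
                continue
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[move.name] - n * p) <= 3 * sigma, move.name


def _move_by_name(ms, name):
    return next(m for m in ms.moves if m.name == name)


class TestPropose:
    def test_add_on_complete_model_skips(self):
        pool = all_helix_pool()
        model = model_from_pool(pool)
        ms = build_move_set(pool, "assembly", CFG)
        rng = np.random.default_rng(1)
        for name in ("add_sse_random", "add_sse_next_to_sse", "add_sse_short_loop"):
            assert propose(_move_by_name(ms, name), model, pool, rng, CFG) == SKIPPED

    def test_sheet_move_without_strands_skips(self):
        pool = mixed_pool()
        model = model_from_pool(pool, which={0})  # helix only
        ms = build_move_set(pool, "assembly", CFG)
        rng = np.random.default_rng(2)
        for name in ("domain_shuffle_sheet", "domain_flip_sheet", "sheet_divide"):
            assert propose(_move_by_name(ms, name), model, pool, rng, CFG) == SKIPPED

    def test_fixed_seed_reproducible(self):
        pool = mixed_pool()
        model = model_from_pool(pool, which={0, 1})
        ms = build_move_set(pool, "assembly", CFG)
        move = _move_by_name(ms, "sse_translate_large")
        out1 = propose(move, model, pool, np.random.default_rng(7), CFG)
        out2 = propose(move, model, pool, np.random.default_rng(7), CFG)
        assert np.allclose(out1.sses[0].coords, out2.sses[0].coords)

    def test_input_model_untouched(self):
        pool = mixed_pool()
        model = model_from_pool(pool)
        before = [s.coords.copy() for s in model.sses]
        ms = build_move_set(pool, "assembly", CFG)
        rng = np.random.default_rng(3)
        for _ in range(100):
            propose(ms.sample(rng), model, pool, rng, CFG)
        for sse, old in zip(model.sses, before):
            assert np.array_equal(sse.coords, old)


class TestCategoryBehaviors:
    def test_swap_exchanges_placements(self):
        pool = all_helix_pool()
        model = model_from_pool(pool)
        ms = build_move_set(pool, "assembly", CFG)
        rng = np.random.default_rng(4)
        out = propose(_move_by_name(ms, "swap_sses"), model, pool, rng, CFG)
        assert out is not SKIPPED
        old_centers = sorted(tuple(np.round(s.axis()[0], 6)) for s in model.sses)
        new_centers = sorted(tuple(np.round(s.axis()[0], 6)) for s in out.sses)
        assert old_centers == new_centers  # multiset of positions preserved
        # sequence segments unchanged (swap moves bodies, not bounds)
        assert [(s.first, s.last) for s in out.sses] == \
               [(s.first, s.last) for s in model.sses]

    def test_domain_flip_preserves_sheet_internal_geometry(self):
        seq = "A" * 30
        from ssefold.geometry import RigidTransform
        strands = []
        for k in range(3):
            first = 1 + k * 8
            s = build_ideal_sse(seq[first - 1 : first + 4], first, first + 4,
                                "strand")
            strands.append(s.transformed(
                RigidTransform.from_translation([4.75 * k, 0, 0])
            ))
        model = ProteinModel(seq, strands)
        sheets = detect_sheets(model, CFG.sheet_pairing_cutoff)
        assert sheets == [[0, 1, 2]]
        pool = SSEPool([PoolEntry("strand", s.first, s.last) for s in strands])
        ms = build_move_set(pool, "assembly", CFG)
        out = propose(_move_by_name(ms, "domain_flip_sheet"), model, pool,
                      np.random.default_rng(5), CFG)
        assert out is not SKIPPED
        ca_old = model.atom_coords(CA)
        ca_new = out.atom_coords(CA)
        d_old = np.linalg.norm(ca_old[:, None] - ca_old[None], axis=-1)
        d_new = np.linalg.norm(ca_new[:, None] - ca_new[None], axis=-1)
        assert np.allclose(d_old, d_new, atol=1e-6)
        assert not np.allclose(ca_old, ca_new, atol=1e-3)  # actually moved

    def test_add_sse_short_loop_respects_closure_rule(self):
        pool = SSEPool([PoolEntry("helix", 1, 10), PoolEntry("helix", 14, 23)])
        model = model_from_pool(pool, sequence_length=25, which={0})
        ms = build_move_set(pool, "assembly", CFG)
        move = _move_by_name(ms, "add_sse_short_loop")
        n_checked = 0
        for seed in range(100):
            out = propose(move, model, pool, np.random.default_rng(seed), CFG)
            if out is SKIPPED:
                continue
            n_checked += 1
            euclid, n_loop = out.chain_break_gap(0)
            assert euclid <= 2.56 * (n_loop + 1) + 2.0 + 1e-9
        assert n_checked >= 50

    def test_remove_unpaired_strand_targets_unpaired(self):
        seq = "A" * 30
        from ssefold.geometry import RigidTransform
        s1 = build_ideal_sse(seq[0:5], 1, 5, "strand")
        s2 = build_ideal_sse(seq[7:12], 8, 12, "strand").transformed(
            RigidTransform.from_translation([4.75, 0, 0])
        )
        lone = build_ideal_sse(seq[14:19], 15, 19, "strand").transformed(
            RigidTransform.from_translation([25.0, 0, 0])
        )
        model = ProteinModel(seq, [s1, s2, lone])
        pool = SSEPool([PoolEntry("strand", 1, 5), PoolEntry("strand", 8, 12),
                        PoolEntry("strand", 15, 19)])
        ms = build_move_set(pool, "assembly", CFG)
        out = propose(_move_by_name(ms, "remove_unpaired_strand"), model, pool,
                      np.random.default_rng(6), CFG)
        assert out is not SKIPPED
        assert [(s.first, s.last) for s in out.sses] == [(1, 5), (8, 12)]


class TestInvariants:
    def test_random_moves_always_yield_valid_models(self):
        """Fuzz: every non-skipped move passes all model invariants."""
        pool = mixed_pool()
        rng = np.random.default_rng(9)
        for stage in ("assembly", "refinement"):
            ms = build_move_set(pool, stage, CFG)
            model = model_from_pool(pool, which={0, 1})
            for _ in range(1500):
                out = propose(ms.sample(rng), model, pool, rng, CFG)
                if out is SKIPPED:
                    continue
                # reconstruct to re-run all container invariants
                rebuilt = ProteinModel(out.sequence, list(out.sses))
                assert rebuilt.n_sses >= 1
                assert np.isfinite(out.atom_coords(CA)).all()
                model = out

    def test_assembly_amplitudes_dominate_refinement(self):
        """Empirical displacement CDF: assembly translations are larger."""
        pool = all_helix_pool()
        model = model_from_pool(pool)
        rng = np.random.default_rng(10)

        def displacements(stage, name):
            ms = build_move_set(pool, stage, CFG)
            move = _move_by_name(ms, name)
            out = []
            for _ in range(300):
                res = propose(move, model, pool, rng, CFG)
                if res is SKIPPED:
                    continue
                shift = max(
                    np.linalg.norm(a.axis()[0] - b.axis()[0])
                    for a, b in zip(res.sses, model.sses)
                )
                out.append(shift)
            return np.array(out)

        large = displacements("assembly", "sse_translate_large")
        small = displacements("refinement", "sse_translate_small")
        assert np.median(large) > np.median(small)
        assert large.max() <= CFG.assembly_max_translation + 1e-9
        assert small.max() <= CFG.refine_max_translation + 1e-9
        # stochastic dominance on a quantile grid
        for q in (0.25, 0.5, 0.75, 0.9):
            assert np.quantile(large, q) >= np.quantile(small, q)
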