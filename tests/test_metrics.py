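"""Quality metrics against independent oracles and printed benchmark tables."""

import importlib.resources
import itertools

import numpy as np
import pandas as pd
import pytest

from ssefold.metrics import (
    MetricsError, benchmark_summary, contact_order, contact_recovery,
    kabsch_rmsd, move_correlation, rmsd100,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_force_contacts(indices, cb, cutoff, min_sep):
    pairs = set()
    for a, b in itertools.combinations(range(len(indices)), 2):
        i, j = int(indices[a]), int(indices[b])
        if abs(i - j) < min_sep:
            continue
        if np.linalg.norm(np.asarray(cb[a]) - np.asarray(cb[b])) < cutoff:
            pairs.add((min(i, j), max(i, j)))
    return pairs


def brute_force_co(indices, cb, L, cutoff=8.0, min_sep=1):
    pairs = brute_force_contacts(indices, cb, cutoff, min_sep)
    seps = [j - i for i, j in pairs]
    co = sum(seps) / len(seps)
    return co, co / L, co * co / L


def rotation_grid_rmsd(a, b):
    """Brute-force minimum RMSD over SO(3): nested Euler-angle grids
    refined down to 0.05-degree resolution."""
    from scipy.spatial.transform import Rotation

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def batch_rmsd(angle_sets):
        R = Rotation.from_euler("zyz", angle_sets, degrees=True).as_matrix()
        moved = np.einsum("kij,nj->kni", R, a)
        return np.sqrt(((moved - b) ** 2).sum(axis=2).mean(axis=1))

    center = np.zeros(3)
    spans = [(180.0, 10.0), (15.0, 1.0), (1.5, 0.1), (0.15, 0.05)]
    best = np.inf
    for span, step in spans:
        axes = [np.arange(c - span, c + span + step / 2, step) for c in center]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = batch_rmsd(grid)
        k = int(np.argmin(vals))
        best = min(best, float(vals[k]))
        center = grid[k]
    return best


# ---------------------------------------------------------------------------
# RMSD family
# ---------------------------------------------------------------------------


class TestKabschRMSD:
    def test_identical_sets_zero(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_transformed_copy_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3)) * 5
        for _ in range(50):
            from scipy.spatial.transform import Rotation
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3) * 10
            assert kabsch_rmsd(pts, pts @ R.T + t) == pytest.approx(0.0, abs=1e-9)

    def test_matches_rotation_grid_oracle(self):
        """4-point toy with one point displaced 1 A: agrees with a
        brute-force grid over SO(3) within 1e-3 A."""
        a = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        b = a.copy()
        b[1, 0] += 1.0
        assert kabsch_rmsd(a, b) == pytest.approx(
            rotation_grid_rmsd(a, b), abs=1e-3
        )

    def test_reflection_not_allowed(self):
        """A mirrored chiral point set does not superpose to zero."""
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3)) * 4
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert kabsch_rmsd(pts, mirrored) > 0.1

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricsError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRMSD100:
    def test_fixed_point_at_100_residues(self):
        assert rmsd100(3.0, 100) == pytest.approx(3.0)

    def test_zero_stays_zero(self):
        for n in (14, 50, 100, 300):
            assert rmsd100(0.0, n) == 0.0

    def test_known_value_at_200(self):
        assert rmsd100(4.0, 200) == pytest.approx(
            4.0 / (1.0 + np.log(np.sqrt(2.0))), abs=1e-9
        )
        assert rmsd100(4.0, 200) == pytest.approx(2.9705, abs=1e-3)

    def test_domain_error_for_tiny_proteins(self):
        with pytest.raises(MetricsError):
            rmsd100(1.0, 13)


# ---------------------------------------------------------------------------
# Contact order and contact recovery
# ---------------------------------------------------------------------------


class TestContactOrder:
    def test_matches_printed_benchmark_row(self):
        """CO 44.41 over 102 residues gives RCO 0.44 (2 dp)."""
        co, L = 44.41, 102
        assert round(co / L, 2) == 0.44

    def test_two_residue_toy(self):
        idx = np.array([1, 2])
        cb = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        co, rco, nco = contact_order(idx, cb, seq_length=50)
        assert co == 1.0
        assert rco == pytest.approx(1 / 50)
        assert nco == pytest.approx(1 / 50)

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(10, 40)
            idx = np.sort(rng.choice(np.arange(1, 120), size=n, replace=False))
            cb = rng.normal(size=(n, 3)) * 6
            co, rco, nco = contact_order(idx, cb, seq_length=120)
            bco, brco, bnco = brute_force_co(idx, cb, 120)
            assert co == pytest.approx(bco, abs=1e-12)
            assert rco == pytest.approx(brco, abs=1e-12)
            assert nco == pytest.approx(bnco, abs=1e-12)

    def test_identities_hold_exactly(self):
        rng = np.random.default_rng(5)
        idx = np.arange(1, 31)
        cb = rng.normal(size=(30, 3)) * 5
        co, rco, nco = contact_order(idx, cb, seq_length=30)
        assert rco * 30 == pytest.approx(co, abs=1e-12)
        assert nco * 30 == pytest.approx(co * co, abs=1e-12)

    def test_no_contacts_is_an_error(self):
        idx = np.array([1, 50])
        cb = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        with pytest.raises(MetricsError):
            contact_order(idx, cb, seq_length=50)


class TestContactRecovery:
    def _native(self, rng, n=40):
        idx = np.arange(1, n + 1)
        # compact cloud so long-range contacts exist
        cb = rng.normal(size=(n, 3)) * 4.0
        return idx, cb

    def test_self_recovery_is_100(self):
        rng = np.random.default_rng(6)
        idx, cb = self._native(rng)
        assert contact_recovery(idx, cb, idx, cb) == 100.0

    def test_all_far_model_recovers_zero(self):
        rng = np.random.default_rng(7)
        idx, cb = self._native(rng)
        spread = cb * 50.0
        assert contact_recovery(idx, spread, idx, cb) == 0.0

    def test_partial_recovery_matches_hand_count(self):
        """Model preserving a hand-countable subset of native contacts."""
        rng = np.random.default_rng(8)
        idx, cb = self._native(rng)
        native_pairs = brute_force_contacts(idx, cb, 8.0, 12)
        assert len(native_pairs) >= 5
        model_cb = cb.copy()
        # push the highest-index residue far away, breaking its contacts
        broken = {p for p in native_pairs if 40 in p}
        model_cb[39] += 200.0
        expected = 100.0 * (len(native_pairs) - len(broken)) / len(native_pairs)
        got = contact_recovery(idx, model_cb, idx, cb)
        # the displaced residue may create no new qualifying native pairs
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            idx, cb = self._native(rng, n=int(rng.integers(30, 60)))
            model_cb = cb + rng.normal(size=cb.shape) * 2.0
            nat = brute_force_contacts(idx, cb, 8.0, 12)
            mod = brute_force_contacts(idx, model_cb, 8.0, 12)
            expected = 100.0 * len(nat & mod) / len(nat)
            assert contact_recovery(idx, model_cb, idx, cb) == pytest.approx(
                expected, abs=1e-12
            )

    def test_no_native_contacts_is_an_error(self):
        idx = np.array([1, 2, 3])
        cb = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        with pytest.raises(MetricsError):
            contact_recovery(idx, cb, idx, cb)  # min_sep 12 excludes all


# ---------------------------------------------------------------------------
# Benchmark summaries (transcribed reference tables)
# ---------------------------------------------------------------------------


def load_table(name):
    path = importlib.resources.files("ssefold") / "data" / name
    return pd.read_csv(path, sep="\t")


class TestBenchmarkSummary:
    def test_native_like_counts_from_reference_table(self):
        table = load_table("model_quality.tsv")
        out = benchmark_summary(table)
        assert out["rmsd100_predicted_sse_below_cut"] == 61
        assert out["rmsd100_native_sse_below_cut"] == 61
        assert out["rmsd100_native_complete_below_cut"] == 50
        assert out["rmsd100_predicted_complete_below_cut"] == 41
        assert out["rmsd100_comparator_below_cut"] == 45
        assert out["cr_native_complete_above_cut"] == 64
        assert out["cr_predicted_complete_above_cut"] == 62
        assert out["cr_comparator_above_cut"] == 60

    def test_means_match_printed_summary_row(self):
        table = load_table("model_quality.tsv")
        out = benchmark_summary(table)
        assert out["rmsd100_native_sse_mean"] == pytest.approx(5.50, abs=0.005)
        assert out["rmsd100_native_complete_mean"] == pytest.approx(6.81, abs=0.005)
        assert out["rmsd100_predicted_sse_mean"] == pytest.approx(6.04, abs=0.005)
        assert out["rmsd100_predicted_complete_mean"] == pytest.approx(7.21, abs=0.005)
        assert out["rmsd100_comparator_mean"] == pytest.approx(6.42, abs=0.005)
        assert out["cr_native_sse_mean"] == pytest.approx(44.55, abs=0.005)
        assert out["cr_predicted_sse_mean"] == pytest.approx(39.63, abs=0.005)
        assert out["rmsd100_native_sse_sd"] == pytest.approx(1.61, abs=0.005)

    def test_improvement_counts_vs_comparator(self):
        table = load_table("model_quality.tsv")
        out = benchmark_summary(table)
        assert out["rmsd100_native_complete_improved_vs_comparator"] == 24
        assert out["rmsd100_predicted_complete_improved_vs_comparator"] == 19
        assert out["cr_native_complete_improved_vs_comparator"] == 47
        assert out["cr_predicted_complete_improved_vs_comparator"] == 40

    def test_boundary_is_strict(self):
        table = pd.DataFrame({"rmsd100_native_sse": [8.0]})
        out = benchmark_summary(table, rmsd_cut=8.0)
        assert out["rmsd100_native_sse_below_cut"] == 0

    def test_zero_cut_counts_nothing(self):
        table = load_table("model_quality.tsv")
        out = benchmark_summary(table, rmsd_cut=0.0)
        assert out["rmsd100_native_sse_below_cut"] == 0

    def test_empty_table_rejected(self):
        with pytest.raises(MetricsError):
            benchmark_summary(pd.DataFrame())


class TestMoveCorrelation:
    def test_move_that_never_succeeds_floors_at_minus_three(self):
        traj = [("a", "rejected")] * 20 + [("b", "improved")] * 5
        mat = move_correlation([traj])
        assert (mat.loc["a"] == -3.0).all()

    def test_exclusive_precedence_gives_positive_correlation(self):
        """j improves only ever right after an accepted i: f1 = 1 and
        C(i->j) = -log10(f3(i))."""
        steps = []
        for _ in range(10):
            steps.append(("i", "accepted"))
            steps.append(("j", "improved"))
            steps.extend([("k", "rejected")] * 3)
        steps.append(("i", "improved"))  # make f2(i) > 0
        mat = move_correlation([steps], window=50)
        f3_i = 11 / 11  # all i moves improved or accepted
        assert mat.loc["i", "j"] == pytest.approx(np.log10(1.0 / f3_i))
        # brute-force window recount
        j_improved = [k for k, s in enumerate(steps) if s == ("j", "improved")]
        preceded = sum(
            any(m == "i" and o in ("improved", "accepted")
                for m, o in steps[max(0, k - 50):k])
            for k in j_improved
        )
        assert preceded == len(j_improved)

    def test_zero_window_floors_everything(self):
        traj = [("a", "improved"), ("b", "improved")] * 10
        mat = move_correlation([traj], window=0)
        assert (mat.values == -3.0).all()

    def test_unknown_move_names_rejected(self):
        with pytest.raises(MetricsError):
            move_correlation([[("mystery", "improved")]], move_names=["a"])
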