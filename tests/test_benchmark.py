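import numpy as np
import pytest

from tfactnet.benchmark import (
    auroc,
    benchmark_activity,
    qc_perturbed_arms,
    simulate_dropout,
)
from tfactnet.datamodel import (
    ActivityMatrix,
    GeneExpressionMatrix,
    PerturbationDesign,
)
from tfactnet.synthetic import generate_truth, simulate_counts

from .oracles import pair_count_auroc


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc(np.array([3.0, 2.0, 1.0, 0.0]),
                     np.array([True, True, False, False])) == 1.0

    def test_all_ties_give_half(self):
        assert auroc(np.full(6, 2.0), np.array([True] * 3 + [False] * 3)) == 0.5

    def test_pair_counting_example(self):
        scores = np.array([0.9, 0.8, 0.4, 0.2])
        pos = np.array([True, False, True, False])
        assert auroc(scores, pos) == pytest.approx(3 / 4)

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 51))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pos = rng.random(n) < 0.5
            if pos.all() or not pos.any():
                continue
            assert auroc(scores, pos) == pytest.approx(
                pair_count_auroc(scores, pos), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = np.round(rng.random(40), 1)
            pos = rng.random(40) < 0.5
            if pos.all() or not pos.any():
                continue
            assert auroc(scores, pos) == pytest.approx(
                roc_auc_score(pos, scores), abs=1e-12)

    def test_complement_identity(self, rng):
        scores = rng.random(30)
        pos = rng.random(30) < 0.4
        pos[0], pos[1] = True, False
        assert auroc(scores, pos) + auroc(scores, ~pos) == pytest.approx(1.0)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            auroc(np.array([1.0, 2.0]), np.array([True, True]))


def _design(arm_sizes: dict, directions: dict | None = None) -> PerturbationDesign:
    directions = directions or {}
    arm_of, arms = {}, {"control": (None, "control")}
    i = 0
    for arm, size in arm_sizes.items():
        if arm != "control":
            arms[arm] = (arm.replace("ko_", "").replace("oe_", ""),
                         directions.get(arm, "knockout"))
        for _ in range(size):
            arm_of[f"c{i:04d}"] = arm
            i += 1
    return PerturbationDesign(arm_of, arms)


class TestQC:
    @staticmethod
    def _expr_with_knockdown(rng, n_ctrl=50, n_ko=50, logfc=-3.0):
        m = n_ctrl + n_ko
        counts = rng.poisson(20, size=(2, m)).astype(float)
        # TF0 knocked down in the ko cells on the log2 scale
        counts[0, n_ctrl:] = rng.poisson(20 * 2.0 ** logfc, size=n_ko)
        return GeneExpressionMatrix(counts, ["TF0", "other"],
                                    [f"c{i:04d}" for i in range(m)])

    def test_small_arm_removed(self, rng):
        expr = self._expr_with_knockdown(rng, n_ctrl=50, n_ko=9)
        design = _design({"control": 50, "ko_TF0": 9})
        kept = qc_perturbed_arms(expr, design)
        assert kept.perturbed_arms() == []

    def test_weak_knockdown_removed(self, rng):
        expr = self._expr_with_knockdown(rng, logfc=-0.5)
        design = _design({"control": 50, "ko_TF0": 50})
        assert qc_perturbed_arms(expr, design).perturbed_arms() == []

    def test_planted_twofold_knockdown_retained(self, rng):
        expr = self._expr_with_knockdown(rng, logfc=-2.0)
        design = _design({"control": 50, "ko_TF0": 50})
        assert qc_perturbed_arms(expr, design).perturbed_arms() == ["ko_TF0"]

    def test_overexpression_direction_flips(self, rng):
        m = 100
        counts = rng.poisson(20, size=(2, m)).astype(float)
        counts[0, :50] = rng.poisson(5, size=50)  # TF up 8-fold in the OE arm
        counts[0, 50:] = rng.poisson(40, size=50)
        expr = GeneExpressionMatrix(counts, ["TF0", "other"],
                                    [f"c{i:04d}" for i in range(m)])
        design = _design({"control": 50, "oe_TF0": 50},
                         {"oe_TF0": "overexpression"})
        assert qc_perturbed_arms(expr, design).perturbed_arms() == ["oe_TF0"]

    def test_absent_tf_dropped_with_warning(self, rng):
        expr = self._expr_with_knockdown(rng)
        design = _design({"control": 50, "ko_MISSING": 50})
        with pytest.warns(UserWarning, match="absent"):
            kept = qc_perturbed_arms(expr, design)
        assert kept.perturbed_arms() == []


class TestBenchmarkActivity:
    def test_label_reversal_identity(self, rng):
        cells = [f"c{i:04d}" for i in range(40)]
        scores = rng.random((1, 40))
        act = ActivityMatrix(scores, ["TF0"], cells)
        ko = _design({"control": 20, "ko_TF0": 20})
        oe = _design({"control": 20, "oe_TF0": 20}, {"oe_TF0": "overexpression"})
        a_ko = benchmark_activity(act, ko)["auroc"][0]
        a_oe = benchmark_activity(act, oe)["auroc"][0]
        assert a_ko + a_oe == pytest.approx(1.0)

    def test_clean_knockout_scores_one(self):
        cells = [f"c{i:04d}" for i in range(20)]
        scores = np.concatenate([np.full(10, 2.0), np.full(10, -2.0)])[None, :]
        act = ActivityMatrix(scores, ["TF0"], cells)
        table = benchmark_activity(act, _design({"control": 10, "ko_TF0": 10}))
        assert table["auroc"][0] == 1.0

    def test_shuffled_scores_near_half(self, rng):
        cells = [f"c{i:04d}" for i in range(400)]
        act = ActivityMatrix(rng.random((1, 400)), ["TF0"], cells)
        table = benchmark_activity(act, _design({"control": 200, "ko_TF0": 200}))
        assert abs(table["auroc"][0] - 0.5) < 0.1

    def test_missing_tf_skipped(self, rng):
        cells = [f"c{i:04d}" for i in range(20)]
        act = ActivityMatrix(rng.random((1, 20)), ["OTHER"], cells)
        with pytest.warns(UserWarning, match="missing"):
            table = benchmark_activity(act, _design({"control": 10, "ko_TF0": 10}))
        assert table.empty


class TestSimulateDropout:
    def test_ratio_zero_is_identity(self, small_expr):
        out = simulate_dropout(small_expr, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, small_expr.values)

    def test_exact_zero_count_on_dense_matrix(self, rng):
        expr = GeneExpressionMatrix(
            rng.integers(1, 10, size=(100, 100)).astype(float),
            [f"g{i}" for i in range(100)], [f"c{i}" for i in range(100)],
        )
        out = simulate_dropout(expr, 0.3, seed=2)
        assert int((out.values == 0).sum()) == 3000

    def test_deterministic_mask(self, rng):
        expr = GeneExpressionMatrix(
            rng.integers(0, 5, size=(30, 30)).astype(float),
            [f"g{i}" for i in range(30)], [f"c{i}" for i in range(30)],
        )
        a = simulate_dropout(expr, 0.2, seed=9)
        b = simulate_dropout(expr, 0.2, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_lognorm_recomputed(self, rng):
        expr = GeneExpressionMatrix(
            rng.integers(1, 20, size=(50, 20)).astype(float),
            [f"g{i}" for i in range(50)], [f"c{i}" for i in range(20)],
        )
        out = simulate_dropout(expr, 0.4, seed=3)
        assert np.all(out.lognorm[out.values == 0] == 0.0)
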