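import numpy as np
import pytest
from scipy import stats

from tfactnet.datamodel import GeneExpressionMatrix
from tfactnet.grn import (
    PUCMatrix,
    discretize,
    entropy,
    infer_grn,
    mutual_information,
    normalize_puc,
    pid_decompose,
    puc_scores,
    specific_information,
)

from .oracles import (
    naive_ecdf_weights,
    naive_mi,
    naive_pid,
    naive_puc,
    naive_specific_info,
    naive_symmetrized_puc,
)


def _expr_from_lognorm(x: np.ndarray) -> GeneExpressionMatrix:
    """Wrap a matrix as expression whose lognorm layer is exactly x."""
    g, m = x.shape
    return GeneExpressionMatrix(
        np.zeros((g, m)), [f"g{i:02d}" for i in range(g)],
        [f"c{j:02d}" for j in range(m)], lognorm=x,
    )


class TestDiscretize:
    def test_default_bin_count_is_sqrt_cells(self, rng):
        expr = _expr_from_lognorm(rng.random((2, 100)))
        assert discretize(expr).k == 10

    def test_boundary_value_goes_right(self):
        expr = _expr_from_lognorm(np.array([[0.0, 0.5, 1.0, 0.2]]))
        bins = discretize(expr, k=2).bins[0]
        assert bins.tolist() == [0, 1, 1, 0]

    def test_binary_mode_on_counts(self):
        expr = GeneExpressionMatrix(np.array([[0.0, 3.0, 7.0, 0.0]]), ["g"],
                                    list("abcd"))
        disc = discretize(expr, mode="binary")
        assert disc.k == 2
        assert disc.bins[0].tolist() == [0, 1, 1, 0]

    def test_constant_gene_single_bin(self):
        expr = _expr_from_lognorm(np.array([[2.0, 2.0, 2.0, 2.0]]))
        assert np.all(discretize(expr, k=3).bins == 0)


class TestEntropyAndMI:
    def test_entropy_values(self):
        assert entropy(np.array([0, 0, 1, 1])) == pytest.approx(1.0)
        assert entropy(np.array([3, 3, 3])) == 0.0
        assert entropy(np.array([0, 0, 0, 1])) == pytest.approx(0.8112781, abs=1e-6)

    def test_mi_self_is_entropy(self):
        x = np.array([0, 1, 0, 1])
        assert mutual_information(x, x) == pytest.approx(entropy(x))

    def test_mi_independent_is_zero(self):
        assert mutual_information(np.array([0, 0, 1, 1]),
                                  np.array([0, 1, 0, 1])) == pytest.approx(0.0)

    def test_mi_joint_table_plug_in(self):
        assert mutual_information(np.array([0, 0, 1, 1]),
                                  np.array([0, 0, 0, 1])) == pytest.approx(
            0.3112781, abs=1e-6)

    def test_mi_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            mutual_information(np.array([0, 1]), np.array([0, 1, 0]))


class TestSpecificInformation:
    def test_independent_source_gives_zero(self):
        # T and R independent by construction
        joint = np.array([[2.0, 2.0], [1.0, 1.0]])
        assert specific_information(joint, 0) == pytest.approx(0.0)
        assert specific_information(joint, 1) == pytest.approx(0.0)

    def test_copy_source_balanced_binary(self):
        joint = np.array([[2.0, 0.0], [0.0, 2.0]])
        assert specific_information(joint, 0) == pytest.approx(1.0)

    def test_weighted_average_recovers_mi(self, rng):
        # identity sum_t p(t) I_spec(t;R) = I(T;R) on random joint samples
        for _ in range(50):
            n = int(rng.integers(6, 30))
            t = rng.integers(0, 3, size=n)
            r = rng.integers(0, 3, size=n)
            joint = np.zeros((3, 3))
            for a, b in zip(t, r):
                joint[a, b] += 1
            total = 0.0
            for tv in range(3):
                if joint[tv].sum() == 0:
                    continue
                total += joint[tv].sum() / n * specific_information(joint, tv)
            assert total == pytest.approx(naive_mi(t, r), abs=1e-9)


class TestPIDDecompose:
    def test_xor_is_pure_synergy(self):
        r = np.array([0, 0, 1, 1])
        p = np.array([0, 1, 0, 1])
        t = r ^ p
        res = pid_decompose(t, r, p)
        assert res.redundancy == pytest.approx(0.0)
        assert res.unique_r == pytest.approx(0.0)
        assert res.unique_p == pytest.approx(0.0)
        assert res.synergy == pytest.approx(1.0)

    def test_duplicate_source_is_pure_redundancy(self, rng):
        t = rng.integers(0, 2, size=40)
        r = (t + (rng.random(40) < 0.2)) % 2  # noisy copy
        res = pid_decompose(t, r, r)
        assert res.redundancy == pytest.approx(res.mi, abs=1e-9)
        assert res.unique_r == pytest.approx(0.0, abs=1e-9)

    def test_matches_naive_oracle_on_random_triples(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 16))
            t = rng.integers(0, 3, size=n)
            r = rng.integers(0, 3, size=n)
            p = rng.integers(0, 2, size=n)
            res = pid_decompose(t, r, p)
            ref = naive_pid(list(t), list(r), list(p))
            assert res.mi == pytest.approx(ref["mi"], abs=1e-9)
            assert res.redundancy == pytest.approx(ref["rdn"], abs=1e-9)
            assert res.unique_r == pytest.approx(max(ref["unq_r"], 0), abs=1e-9)
            assert res.synergy == pytest.approx(ref["syn"], abs=1e-9)

    def test_bounds_hold(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 20))
            t = rng.integers(0, 3, size=n)
            r = rng.integers(0, 3, size=n)
            p = rng.integers(0, 3, size=n)
            res = pid_decompose(t, r, p)
            mi_tp = mutual_information(t, p)
            assert -1e-9 <= res.redundancy <= min(res.mi, mi_tp) + 1e-9
            assert res.unique_r >= 0.0
            assert res.unique_r <= res.mi + 1e-9

    def test_unique_ratio_base_invariant(self, rng):
        t = rng.integers(0, 3, size=30)
        r = rng.integers(0, 3, size=30)
        p = rng.integers(0, 2, size=30)
        b2 = pid_decompose(t, r, p, base=2.0)
        be = pid_decompose(t, r, p, base=np.e)
        if b2.mi > 0:
            assert b2.unique_r / b2.mi == pytest.approx(be.unique_r / be.mi, abs=1e-9)


class TestPUCScores:
    def test_copy_with_independent_partners_scores_n_minus_2(self, rng):
        # T = R exactly; partners are iid noise -> Unq_P = I for every P
        m = 64
        r = rng.integers(0, 2, size=m)
        bins = np.vstack([r, r.copy(),
                          rng.integers(0, 2, size=m),
                          rng.integers(0, 2, size=m),
                          rng.integers(0, 2, size=m)])
        from tfactnet.grn import DiscretizedMatrix
        disc = DiscretizedMatrix(bins, 2, [np.array([0, 0.5, 1])] * 5,
                                 ["R", "T", "p1", "p2", "p3"])
        res = puc_scores(disc, ["R"], ["T"])
        n = 5
        # partners are only approximately independent in a finite sample
        assert res.puc[0, 0] == pytest.approx(n - 2, rel=0.05)
        assert res.puc[0, 0] <= n - 2 + 1e-9

    def test_zero_mi_pair_scores_zero(self, rng):
        from tfactnet.grn import DiscretizedMatrix
        # R constant -> I(R;T) = 0 for every T
        bins = np.vstack([np.zeros(16, dtype=int),
                          rng.integers(0, 2, size=16),
                          rng.integers(0, 2, size=16)])
        disc = DiscretizedMatrix(bins, 2, [np.array([0, 0.5, 1])] * 3,
                                 ["R", "T", "P"])
        assert puc_scores(disc, ["R"], ["T"]).puc[0, 0] == 0.0

    def test_symmetrization_averages_both_directions(self, rng):
        from tfactnet.grn import DiscretizedMatrix
        m = 24
        bins = rng.integers(0, 3, size=(4, m))
        ids = ["a", "b", "c", "d"]
        disc = DiscretizedMatrix(bins, 3, [np.linspace(0, 1, 4)] * 4, ids)
        by_gene = {g: list(bins[i]) for i, g in enumerate(ids)}
        res = puc_scores(disc, ["a", "b"], ids)
        expected = naive_symmetrized_puc(by_gene, ["a", "b"], ids)
        for i, r in enumerate(["a", "b"]):
            for j, t in enumerate(ids):
                if r == t:
                    assert np.isnan(res.puc[i, j])
                else:
                    assert res.puc[i, j] == pytest.approx(expected[(r, t)], abs=1e-9)

    def test_matches_naive_on_exhaustive_small_instances(self, rng):
        """Optimized pair kernels equal dictionary-counting on small panels."""
        from tfactnet.grn import DiscretizedMatrix
        for n_genes in (3, 4, 5):
            for m in (4, 6, 8):
                for k in (2, 3):
                    bins = rng.integers(0, k, size=(n_genes, m))
                    ids = [f"g{i}" for i in range(n_genes)]
                    disc = DiscretizedMatrix(bins, k, [np.linspace(0, 1, k + 1)] * n_genes, ids)
                    by_gene = {g: list(bins[i]) for i, g in enumerate(ids)}
                    res = puc_scores(disc, ids, ids)
                    ref = naive_symmetrized_puc(by_gene, ids, ids)
                    for i, r in enumerate(ids):
                        for j, t in enumerate(ids):
                            if r != t:
                                assert res.puc[i, j] == pytest.approx(
                                    ref[(r, t)], abs=1e-9), (r, t, bins)

    def test_score_within_bounds(self, rng):
        from tfactnet.grn import DiscretizedMatrix
        n, m = 6, 20
        bins = rng.integers(0, 3, size=(n, m))
        ids = [f"g{i}" for i in range(n)]
        disc = DiscretizedMatrix(bins, 3, [np.linspace(0, 1, 4)] * n, ids)
        res = puc_scores(disc, ids, ids)
        vals = res.puc[~np.isnan(res.puc)]
        assert np.all(vals >= -1e-9)
        assert np.all(vals <= n - 2 + 1e-9)


class TestNormalizePUC:
    def test_max_score_maps_to_one(self):
        puc = PUCMatrix(np.array([[0.8, 0.4], [0.2, 0.1]]), ["r1", "r2"], ["t1", "t2"])
        net = normalize_puc(puc)
        wmap = net.weight_map()
        assert wmap[("r1", "t1")] == pytest.approx(1.0)
        assert all(0.0 < w <= 1.0 for w in wmap.values())

    def test_all_equal_scores_map_to_one(self):
        puc = PUCMatrix(np.full((2, 2), 0.3), ["r1", "r2"], ["t1", "t2"])
        assert all(w == 1.0 for _, _, w in normalize_puc(puc))

    def test_matches_naive_ecdf_oracle(self, rng):
        scores = rng.random((3, 3))
        puc = PUCMatrix(scores, ["r1", "r2", "r3"], ["t1", "t2", "t3"])
        net = normalize_puc(puc)
        ref = naive_ecdf_weights({
            (f"r{i+1}", f"t{j+1}"): scores[i, j] for i in range(3) for j in range(3)
        })
        for r, t, w in net:
            assert w == pytest.approx(ref[(r, t)], abs=1e-12)


class TestInferGRN:
    @staticmethod
    def _structured_expr(rng, n_noise=14, m=120):
        """One TF driving 5 targets strongly, plus independent noise genes."""
        tf = rng.normal(0, 1, size=m)
        rows = [tf]
        ids = ["TF"]
        for i in range(5):
            rows.append(2.0 * tf + rng.normal(0, 0.3, size=m))
            ids.append(f"tgt{i}")
        for i in range(n_noise):
            rows.append(rng.normal(0, 1, size=m))
            ids.append(f"noise{i}")
        x = np.vstack(rows)
        x = x - x.min()
        return GeneExpressionMatrix(np.round(np.exp(x)), ids,
                                    [f"c{j}" for j in range(m)])

    def test_true_targets_outrank_noise(self, rng):
        expr = self._structured_expr(rng)
        net = infer_grn(expr, ["TF"])
        ranked = sorted(net.edges, key=lambda e: -e[2])
        top = {t for _, t, _ in ranked[:5]}
        assert sum(t.startswith("tgt") for t in top) >= 4

    def test_no_structure_gives_spread_weights(self, rng):
        m, n = 80, 12
        counts = rng.poisson(5.0, size=(n, m)).astype(float)
        expr = GeneExpressionMatrix(counts, [f"g{i}" for i in range(n)],
                                    [f"c{j}" for j in range(m)])
        net = infer_grn(expr, [f"g{i}" for i in range(3)])
        w = np.array([e[2] for e in net.edges])
        # null weights should cover (0, 1] broadly rather than cluster
        assert stats.kstest(w, "uniform").pvalue > 1e-4

    def test_deterministic(self, rng):
        expr = self._structured_expr(rng, n_noise=4, m=40)
        assert infer_grn(expr, ["TF"]).edges == infer_grn(expr, ["TF"]).edges
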