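import numpy as np
import pandas as pd
import pytest

from metabnet.describe import (
    centralization,
    density,
    heterogeneity,
    node_degrees_strengths,
    profile_curves,
    summarize,
)
from metabnet.modules import ModulePartition
from metabnet.network import Network


def _star(p=5):
    W = np.zeros((p, p))
    W[0, 1:] = 1.0
    W[1:, 0] = 1.0
    return W


class TestDegreesStrengths:
    def test_triangle(self):
        W = np.ones((3, 3)) - np.eye(3)
        net = Network(A=(W > 0).astype(int), W=W)
        deg, s = node_degrees_strengths(net)
        assert np.array_equal(deg, [2, 2, 2])
        assert np.allclose(s, 2.0)

    def test_empty(self):
        net = Network(A=np.zeros((4, 4), int), W=np.zeros((4, 4)))
        deg, s = node_degrees_strengths(net)
        assert deg.sum() == 0 and s.sum() == 0

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(size=(7, 7))
        W = np.triu(W, 1)
        W = W + W.T
        A = (W > 0.5).astype(int)
        W = W * A
        net = Network(A=A, W=W)
        deg, s = node_degrees_strengths(net)
        for i in range(7):
            assert deg[i] == sum(A[i, j] for j in range(7))
            assert s[i] == pytest.approx(sum(W[i, j] for j in range(7)))


class TestMeasures:
    @pytest.mark.parametrize("p", [3, 5, 8])
    def test_complete_unit_graph_density_one(self, p):
        M = np.ones((p, p)) - np.eye(p)
        assert density(M) == pytest.approx(1.0)

    def test_empty_density_zero(self):
        assert density(np.zeros((4, 4))) == 0.0

    def test_four_node_path_with_half_weights(self):
        M = np.zeros((4, 4))
        for i in range(3):
            M[i, i + 1] = M[i + 1, i] = 0.5
        assert density(M) == pytest.approx(0.25)

    def test_regular_graph_centralization_and_heterogeneity_zero(self):
        M = np.ones((6, 6)) - np.eye(6)
        assert centralization(M) == pytest.approx(0.0)
        assert heterogeneity(M) == pytest.approx(0.0)

    def test_five_node_star_centralization(self):
        assert centralization(_star(5)) == pytest.approx(12 / 25)

    def test_centralization_bounded_for_intensity_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.integers(3, 10)
            W = rng.uniform(size=(p, p))
            W = np.triu(W, 1)
            W = W + W.T
            assert centralization(W) <= 1.0

    def test_heterogeneity_from_strengths(self):
        # strengths {1, 1, 0}: sd (n-1 divisor) sqrt(1/3), mean 2/3
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = 1.0
        assert heterogeneity(M) == pytest.approx(np.sqrt(3) / 2)

    def test_measures_match_brute_force(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(size=(6, 6))
        W = np.triu(W, 1)
        W = W + W.T
        p = 6
        s = [sum(W[i, j] for j in range(p)) for i in range(p)]
        assert density(W) == pytest.approx(
            sum(W[i, j] for i in range(p) for j in range(p) if i != j) / (p * (p - 1))
        )
        assert centralization(W) == pytest.approx((max(s) - np.mean(s)) / p)
        assert heterogeneity(W) == pytest.approx(np.std(s, ddof=1) / np.mean(s))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        W = rng.uniform(size=(8, 8))
        W = np.triu(W, 1)
        W = W + W.T
        perm = rng.permutation(8)
        Wp = W[np.ix_(perm, perm)]
        assert density(W) == pytest.approx(density(Wp))
        assert centralization(W) == pytest.approx(centralization(Wp))
        assert heterogeneity(W) == pytest.approx(heterogeneity(Wp))

    def test_zero_strength_heterogeneity_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            heterogeneity(np.zeros((3, 3)))


class TestSummarize:
    def _planted(self):
        W = np.zeros((12, 12))
        W[:6, :6] = 1.0
        W[6:, 6:] = 1.0
        np.fill_diagonal(W, 0)
        net = Network(A=(W > 0).astype(int), W=W)
        labels = {n: 1 if i < 6 else 2 for i, n in enumerate(net.nodes)}
        return net, ModulePartition(labels, "dynamic_hybrid")

    def test_planted_blocks_are_denser_than_whole(self):
        net, part = self._planted()
        summ = summarize(net, part, min_report_size=5)
        table = summ.table.set_index("module")
        assert table.loc["module_1", "density"] == pytest.approx(1.0)
        assert table.loc["module_2", "density"] == pytest.approx(1.0)
        assert table.loc["complete_network", "density"] < 1.0

    def test_small_modules_hidden_but_partition_intact(self):
        net, part = self._planted()
        part.labels[net.nodes[0]] = 3  # split off a singleton-ish module
        summ = summarize(net, part, min_report_size=5)
        assert "module_3" not in set(summ.table["module"])
        assert part.labels[net.nodes[0]] == 3


class TestProfileCurves:
    def _decomposed(self, y, n):
        from metabnet.decompose import DecomposedMatrix

        frame = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "timepoint": 0, "m1": y}
        )
        return DecomposedMatrix(frame=frame, part="diet_lifestyle")

    def test_linear_signal_reproduced(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 2.0 * x - 1.0
        curves = profile_curves(self._decomposed(y, 200), pd.DataFrame({"F1": x}))
        expected = 2.0 * curves["x"].to_numpy() - 1.0
        assert np.max(np.abs(curves["fitted_y"].to_numpy() - expected)) < 1e-6

    def test_constant_signal_gives_flat_curve(self):
        x = np.linspace(-1, 1, 50)
        curves = profile_curves(
            self._decomposed(np.full(50, 3.14), 50), pd.DataFrame({"F1": x})
        )
        assert np.allclose(curves["fitted_y"], 3.14)

    def test_few_distinct_scores_fall_back_to_linear(self):
        x = np.repeat([0.0, 1.0, 2.0], 10)
        y = 1.0 + x
        curves = profile_curves(self._decomposed(y, 30), pd.DataFrame({"F1": x}))
        assert curves["linear_fallback"].all()
        assert np.max(np.abs(curves["fitted_y"] - (1.0 + curves["x"]))) < 1e-8

    def test_within_module_curves_more_similar_than_between(self, small_study,
                                                            small_fits):
        from metabnet.decompose import extract_diet_lifestyle_part

        bundle = small_study.bundle
        y_l = extract_diet_lifestyle_part(small_fits, bundle)
        scores = bundle.F.reset_index(drop=True)
        truth = small_study.truth.module_labels_true
        part = ModulePartition(dict(truth), "dynamic_hybrid")
        curves = profile_curves(y_l, scores, partition=part)
        same, diff = [], []
        for diet in scores.columns:
            piv = curves[curves["diet"] == diet].pivot(
                index="x", columns="metabolite", values="fitted_y"
            )
            C = piv.corr().to_numpy()
            mets = list(piv.columns)
            for i in range(len(mets)):
                for j in range(i + 1, len(mets)):
                    (same if truth[mets[i]] == truth[mets[j]] else diff).append(
                        C[i, j]
                    )
        # shared module-level diet responses align curve directions in-module;
        # across modules directions are unrelated (mean correlation ~ 0)
        assert np.mean(same) > np.mean(diff)
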