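"""Differential layer: fold change, t tests, volcano, ANOVA+Sidak, PCA, heat map."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import silhouette_score

import mrmquant as mq
from mrmquant.simulate import StudyMatrix


def make_study(values: np.ndarray, groups: list[str]) -> StudyMatrix:
    values = np.asarray(values, float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    return StudyMatrix(
        values=pd.DataFrame(values, index=[f"a{i}" for i in range(values.shape[0])],
                            columns=samples),
        sample_groups=pd.Series(groups, index=samples),
        planted=pd.DataFrame(columns=["analyte", "group", "fold_change"]),
    )


class TestFoldChange:
    def test_ratio_of_means(self):
        study = make_study([[10, 10, 20, 20]], ["A", "A", "B", "B"])
        assert mq.fold_change(study, "A", "B")["a0"] == pytest.approx(2.0)
        assert mq.fold_change(study, "B", "A")["a0"] == pytest.approx(0.5)

    def test_identical_groups_give_one(self):
        study = make_study([[5, 7, 5, 7]], ["A", "A", "B", "B"])
        assert mq.fold_change(study, "A", "B")["a0"] == pytest.approx(1.0)

    def test_unknown_group_rejected(self):
        study = make_study([[1, 2, 3, 4]], ["A", "A", "B", "B"])
        with pytest.raises(KeyError):
            mq.fold_change(study, "A", "Z")


class TestTTest:
    def test_identical_groups_p_one(self):
        study = make_study([[1, 2, 3, 1, 2, 3]], ["A"] * 3 + ["B"] * 3)
        assert mq.t_test(study, "A", "B", flavor="student")["a0"] == pytest.approx(1.0)

    def test_hand_computed_student_t(self):
        # pooled-variance t = 10 with df = 8
        study = make_study(
            [[10, 11, 12, 13, 14, 20, 21, 22, 23, 24]], ["A"] * 5 + ["B"] * 5
        )
        p = mq.t_test(study, "A", "B", flavor="student")["a0"]
        assert p == pytest.approx(2 * sps.t.sf(10.0, 8), rel=1e-9)
        assert p == pytest.approx(8.5e-6, rel=0.02)

    def test_degenerate_zero_variance_equal_means(self):
        study = make_study([[5, 5, 5, 5]], ["A", "A", "B", "B"])
        assert mq.t_test(study, "A", "B")["a0"] == 1.0

    def test_null_rejection_rate_calibrated(self):
        study = mq.simulate_study(1000, n_per_group=5, cv=0.10, seed=11)
        p = mq.t_test(study, "WT", "TgTg")
        rate = float((p < 0.05).mean())
        assert 0.035 <= rate <= 0.065


class TestVolcano:
    @pytest.mark.parametrize(
        "fc, p, selected, direction",
        [(1.6, 0.04, True, "up"), (1.4, 0.001, False, ""), (0.6, 0.01, True, "down"),
         (1.5, 0.04, False, ""), (1.6, 0.05, False, "")],  # strict gates
    )
    def test_threshold_rule(self, fc, p, selected, direction, monkeypatch):
        study = make_study([[1, 1, 1, 1]], ["A", "A", "B", "B"])
        monkeypatch.setattr(mq.stats, "fold_change",
                            lambda *a, **k: pd.Series([fc], index=["a0"]))
        monkeypatch.setattr(mq.stats, "t_test",
                            lambda *a, **k: pd.Series([p], index=["a0"]))
        rec = mq.volcano_select(study, "A", "B").loc["a0"]
        assert bool(rec["selected"]) is selected
        assert rec["direction"] == direction

    def test_planted_effects_recovered(self):
        planted = [(f"analyte{i + 1:04d}", "TgTg", 2.0) for i in range(30)]
        study = mq.simulate_study(247, n_per_group=5, planted=planted, cv=0.10, seed=1)
        table = mq.volcano_select(study, "WT", "TgTg")
        hits = set(table.index[table["selected"]])
        truth = {a for a, _, _ in planted}
        sensitivity = len(hits & truth) / len(truth)
        false_rate = len(hits - truth) / max(len(hits), 1)
        assert sensitivity >= 0.9 and false_rate <= 0.1
        assert (table.loc[sorted(hits & truth), "direction"] == "up").all()


class TestSidak:
    def test_closed_form(self):
        assert mq.sidak_adjust(0.01, 3) == pytest.approx(0.029701)

    def test_bounds(self):
        assert mq.sidak_adjust(0.0, 5) == 0.0
        assert mq.sidak_adjust(1.0, 5) == 1.0

    def test_monotone_in_p(self):
        p = np.linspace(0, 1, 50)
        adj = mq.sidak_adjust(p, 4)
        assert np.all(np.diff(adj) >= 0) and np.all((adj >= 0) & (adj <= 1))
        assert np.all(adj >= p)


class TestAnova:
    def test_hand_decomposition(self):
        # SSB = 6 (df 2), SSW = 6 (df 6) -> F = 3.0
        study = make_study(
            [[1, 2, 3, 2, 3, 4, 3, 4, 5]], ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        )
        res = mq.anova_sidak(study, reference_group="C")
        assert res.loc["a0", "F"] == pytest.approx(3.0)
        assert res.loc["a0", "p_anova"] == pytest.approx(sps.f.sf(3.0, 2, 6), rel=1e-9)
        assert res.loc["a0", "p_anova"] == pytest.approx(0.125, abs=0.005)

    def test_pairwise_sidak_columns(self):
        study = mq.simulate_study(5, n_per_group=4, seed=2)
        res = mq.anova_sidak(study, reference_group="TgTg")
        for g in ("WT", "Tg"):
            raw, adj = res[f"p_{g}_vs_TgTg"], res[f"p_adj_{g}_vs_TgTg"]
            assert np.allclose(adj, 1 - (1 - raw) ** 2)

    def test_single_group_rejected(self):
        study = make_study([[1, 2, 3]], ["A", "A", "A"])
        with pytest.raises(ValueError, match="2 groups"):
            mq.anova_sidak(study, "A")


class TestPca:
    def test_one_dimensional_variation(self):
        study = make_study([[1, -1], [0, 0]], ["A", "B"])
        res = mq.pca(study)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_scores_reconstruct_centered_matrix(self):
        study = mq.simulate_study(8, n_per_group=3, seed=4)
        res = mq.pca(study)
        X = study.values.T
        C = (X - X.mean(axis=0)).to_numpy()
        assert np.allclose(res.scores.to_numpy() @ res.loadings.to_numpy().T, C, atol=1e-10)

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(0)
        study = make_study(rng.normal(size=(3, 5)), ["A", "A", "B", "B", "B"])
        res = mq.pca(study)
        sk = SkPCA().fit(study.values.T.to_numpy())
        assert np.allclose(
            res.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-10
        )
        assert np.allclose(np.abs(res.scores.to_numpy()),
                           np.abs(sk.transform(study.values.T.to_numpy())), atol=1e-8)

    def test_loadings_orthonormal_and_variance_ordering(self):
        study = mq.simulate_study(12, n_per_group=4, seed=9)
        res = mq.pca(study)
        V = res.loadings.to_numpy()
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_strong_group_effects_separate_on_pc12(self):
        planted = [(f"analyte{i + 1:04d}", grp, fc)
                   for i in range(40)
                   for grp, fc in (("TgTg", 3.0), ("Tg", 1.7))]
        study = mq.simulate_study(100, n_per_group=5, planted=planted, cv=0.10, seed=6)
        res = mq.pca(study)
        score = silhouette_score(
            res.scores.iloc[:, :2], study.sample_groups.loc[res.scores.index]
        )
        assert score > 0


class TestHeatmap:
    def test_rows_are_z_scored(self):
        study = mq.simulate_study(10, n_per_group=4, seed=3)
        z, _ = mq.heatmap_matrix(study)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_identical_analytes_cluster_together(self):
        base = np.array([[1, 2, 3, 4], [10, 9, 2, 1], [1, 2, 3, 4.0]])
        study = make_study(base, ["A", "A", "B", "B"])
        _, order = mq.heatmap_matrix(study)
        assert abs(order.index("a0") - order.index("a2")) == 1

    def test_planted_two_cluster_structure(self):
        up = [1.0, 1.1, 5.0, 5.2]
        down = [5.0, 5.1, 1.0, 1.2]
        study = make_study([up, down, up, down], ["A", "A", "B", "B"])
        _, order = mq.heatmap_matrix(study)
        assert abs(order.index("a0") - order.index("a2")) == 1
        assert abs(order.index("a1") - order.index("a3")) == 1

    def test_zero_variance_rows_warn_and_zero(self):
        study = make_study([[1, 1, 1, 1], [1, 2, 3, 4]], ["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="zero-variance"):
            z, _ = mq.heatmap_matrix(study)
        assert np.allclose(z.loc["a0"], 0.0)

    def test_empty_subset_rejected(self):
        study = make_study([[1, 2, 3, 4]], ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="empty"):
            mq.heatmap_matrix(study, [])
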