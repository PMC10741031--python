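"""Peak alignment, similarity, HCA, PCA and OPLS-DA/VIP."""

import numpy as np
import pandas as pd
import pytest

from chebutools.fingerprint_chemometrics import (
    PeakTable,
    align_common_peaks,
    autoscale,
    fingerprint_similarity,
    hca,
    oplsda,
    pca,
    vip_select,
)
from chebutools.synthetic_data import SyntheticDesign, generate_peak_tables


@pytest.fixture()
def three_group_table():
    table, truth = generate_peak_tables(SyntheticDesign(), seed=7)
    return table, truth


class TestAlignCommonPeaks:
    def test_shared_peaks_become_common(self):
        rng = np.random.default_rng(0)
        seeded_rts = np.linspace(2.0, 30.0, 23)
        batches = {}
        for b in range(18):
            peaks = [(rt + rng.normal(0, 0.02), rng.uniform(50, 500))
                     for rt in seeded_rts]
            # batch-unique extras well away from the seeded grid
            peaks += [(35.0 + b * 0.7, rng.uniform(5, 50))]
            batches[f"S{b+1}"] = peaks
        table, common = align_common_peaks(batches, rt_tol=0.1)
        assert len(common) == 23
        assert len(table.peak_ids) == 23 + 18

    def test_single_batch_every_peak_common(self):
        table, common = align_common_peaks({"S1": [(1.0, 10.0), (2.0, 20.0)]})
        assert len(common) == 2

    def test_disjoint_batches_share_nothing(self):
        table, common = align_common_peaks({
            "S1": [(1.0, 10.0), (2.0, 20.0)],
            "S2": [(5.0, 10.0), (6.0, 20.0)],
        })
        assert common == []


class TestFingerprintSimilarity:
    def test_identical_batch_scores_one(self):
        areas = pd.DataFrame([[1.0, 2.0, 3.0]] * 3, index=list("abc"),
                             columns=["P1", "P2", "P3"])
        report = fingerprint_similarity(PeakTable(areas=areas))
        assert all(s == pytest.approx(1.0) for s in report.scores.values())

    def test_orthogonal_batch_scores_zero(self):
        areas = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"],
                             columns=["P1", "P2"])
        report = fingerprint_similarity(PeakTable(areas=areas), reference="a")
        assert report.scores["b"] == pytest.approx(0.0)

    def test_matches_dot_product_oracle(self):
        areas = pd.DataFrame([[1.0, 2.0, 2.0], [2.0, 1.0, 2.0], [3.0, 3.0, 0.0]],
                             index=list("abc"), columns=["P1", "P2", "P3"])
        report = fingerprint_similarity(PeakTable(areas=areas), reference="mean")
        ref = areas.values.mean(axis=0)
        for batch in areas.index:
            v = areas.loc[batch].values
            oracle = v @ ref / (np.linalg.norm(v) * np.linalg.norm(ref))
            assert report.scores[batch] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_batch_scaling(self, three_group_table):
        table, _ = three_group_table
        scaled = PeakTable(areas=table.areas.copy())
        scaled.areas.iloc[0] *= 7.5
        a = fingerprint_similarity(table, reference="mean")
        b = fingerprint_similarity(scaled, reference="mean")
        # reference changes slightly, so compare the scaled batch against a
        # fixed reference batch instead
        a = fingerprint_similarity(table, reference="S9")
        b = fingerprint_similarity(scaled, reference="S9")
        assert b.scores["S1"] == pytest.approx(a.scores["S1"], abs=1e-9)

    def test_all_zero_vector_is_an_error(self):
        areas = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["a", "b"],
                             columns=["P1", "P2"])
        with pytest.raises(ValueError):
            fingerprint_similarity(PeakTable(areas=areas), reference="a")


class TestAutoscale:
    def test_zero_mean_unit_variance(self, three_group_table):
        table, _ = three_group_table
        scaled = autoscale(table)
        assert np.allclose(scaled.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(scaled.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        areas = pd.DataFrame({"P1": [1.0, 2.0, 3.0], "P2": [5.0, 5.0, 5.0]},
                             index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            scaled = autoscale(PeakTable(areas=areas))
        assert list(scaled.columns) == ["P1"]

    def test_round_trip(self):
        areas = pd.DataFrame(np.random.default_rng(1).uniform(1, 9, (5, 4)),
                             index=list("abcde"), columns=list("WXYZ"))
        scaled = autoscale(areas)
        back = scaled * areas.std(axis=0, ddof=1) + areas.mean(axis=0)
        assert np.allclose(back.values, areas.values, atol=1e-9)


class TestHca:
    def test_three_groups_recovered(self, three_group_table):
        table, truth = three_group_table
        _, order, assignment = hca(table, k=3)
        mapping = {}
        for batch, cluster in assignment.items():
            group = truth.group_labels[batch]
            assert mapping.setdefault(cluster, group) == group
        assert len(mapping) == 3
        assert sorted(order) == sorted(table.batch_ids)

    def test_duplicate_batches_merge_first(self):
        rng = np.random.default_rng(3)
        areas = pd.DataFrame(rng.uniform(1, 9, (4, 6)), index=list("abcd"))
        areas.loc["d"] = areas.loc["a"]  # exact duplicate
        link, _, _ = hca(PeakTable(areas=areas), scale=False)
        assert link[0, 2] == pytest.approx(0.0)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 3}

    def test_k_equals_n(self, three_group_table):
        table, _ = three_group_table
        _, _, assignment = hca(table, k=len(table.batch_ids))
        assert len(set(assignment.values())) == len(table.batch_ids)

    def test_k_above_n_rejected(self, three_group_table):
        table, _ = three_group_table
        with pytest.raises(ValueError):
            hca(table, k=99)


class TestPca:
    def test_rank_one_matrix(self):
        base = np.outer(np.arange(1.0, 5.0), np.array([1.0, 2.0, 3.0]))
        frame = pd.DataFrame(base, index=list("abcd"), columns=["P1", "P2", "P3"])
        result = pca(frame, n_components=1)
        assert result.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_match_sklearn(self, three_group_table):
        from sklearn.decomposition import PCA as SkPCA
        table, _ = three_group_table
        scaled = autoscale(table)
        ours = pca(scaled, n_components=5)
        theirs = SkPCA(n_components=5).fit(scaled.values)
        np.testing.assert_allclose(
            ours.explained_variance_fraction, theirs.explained_variance_ratio_,
            atol=1e-10)

    def test_full_rank_fractions_sum_to_one(self, three_group_table):
        table, _ = three_group_table
        scaled = autoscale(table)
        result = pca(scaled)
        assert result.explained_variance_fraction.sum() == pytest.approx(1.0)
        diffs = np.diff(result.explained_variance_fraction)
        assert (diffs <= 1e-12).all()

    def test_three_groups_separate_in_score_space(self, three_group_table):
        from sklearn.metrics import silhouette_score
        table, truth = three_group_table
        result = pca(autoscale(table), n_components=2)
        labels = [truth.group_labels[b] for b in table.batch_ids]
        assert silhouette_score(result.scores.values, labels) > 0

    def test_sign_convention_deterministic(self, three_group_table):
        table, _ = three_group_table
        scaled = autoscale(table)
        a = pca(scaled, 3)
        b = pca(scaled.iloc[::-1], 3)  # reversed batch order
        for comp in a.loadings.columns:
            assert a.loadings[comp].abs().idxmax() == b.loadings[comp].abs().idxmax()
            assert a.loadings[comp][a.loadings[comp].abs().idxmax()] > 0


class TestOplsda:
    @staticmethod
    def _two_group(seed=0, n=14, p=12, separation=6.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = ["A"] * (n // 2) + ["B"] * (n - n // 2)
        X[: n // 2, :4] += separation
        frame = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                             columns=[f"P{j}" for j in range(p)])
        scaled = (frame - frame.mean()) / frame.std(ddof=1)
        return scaled, y

    def test_separable_data_has_high_q2(self):
        scaled, y = self._two_group()
        result = oplsda(scaled, y)
        assert result.q2 > 0.9
        assert result.r2y >= result.q2

    def test_permuted_labels_collapse_q2(self):
        scaled, y = self._two_group()
        observed = oplsda(scaled, y).q2
        rng = np.random.default_rng(10)
        permuted_q2 = []
        for _ in range(30):
            perm = list(rng.permutation(y))
            if len(set(perm)) < 2:
                continue
            try:
                permuted_q2.append(oplsda(scaled, perm).q2)
            except ValueError:  # a fold lost a class
                continue
        assert len(permuted_q2) >= 20
        assert np.median(permuted_q2) < 0.2
        assert max(permuted_q2) < observed

    def test_vip_normalization_identity(self):
        scaled, y = self._two_group(seed=3)
        result = oplsda(scaled, y)
        assert float((result.vip ** 2).sum()) == pytest.approx(
            scaled.shape[1], abs=1e-9)

    def test_zero_orthogonal_reduces_to_pls(self):
        from sklearn.cross_decomposition import PLSRegression
        scaled, y = self._two_group(seed=5)
        result = oplsda(scaled, y, n_orthogonal=0)
        y_enc = np.array([1.0 if v == "B" else -1.0 for v in y])
        sk = PLSRegression(n_components=1, scale=False).fit(scaled.values, y_enc)
        fitted_ours = result.predictive_scores * _q_of(result, y_enc)
        fitted_sk = sk.predict(scaled.values).ravel() - y_enc.mean()
        np.testing.assert_allclose(fitted_ours, fitted_sk, atol=1e-8)

    def test_single_class_rejected(self):
        scaled, _ = self._two_group()
        with pytest.raises(ValueError):
            oplsda(scaled, ["A"] * len(scaled))

    def test_too_many_folds_rejected(self):
        scaled, y = self._two_group(n=6)
        with pytest.raises(ValueError):
            oplsda(scaled, y, cv_folds=10)


def _q_of(result, y_enc):
    t = result.predictive_scores
    y_c = y_enc - y_enc.mean()
    return float(y_c @ t / (t @ t))


class TestVipSelect:
    def test_planted_markers_top_ranked_in_orthogonal_design(self):
        from chebutools.synthetic_data import _GROUP_PROFILES, _PLANTED_MARKERS
        overrides = tuple((r, _GROUP_PROFILES[r]) for r in _PLANTED_MARKERS)
        design = SyntheticDesign(profile_overrides=overrides, flat_baseline=True)
        table, truth = generate_peak_tables(design, seed=2)
        sub = [b for b in table.batch_ids
               if truth.group_labels[b] in ("II", "III")]
        y = [truth.group_labels[b] for b in sub]
        result = oplsda(autoscale(table.areas.loc[sub]), y)
        ranked = result.vip.sort_values(ascending=False)
        assert set(ranked.index[:8]) == set(truth.planted_markers)
        assert set(truth.planted_markers) <= set(vip_select(result).index)

    def test_all_noise_table_selects_only_by_chance(self):
        rng = np.random.default_rng(123)
        counts = []
        for seed in range(20):
            X = pd.DataFrame(rng.normal(size=(14, 20)),
                             columns=[f"P{j}" for j in range(20)])
            scaled = (X - X.mean()) / X.std(ddof=1)
            y = ["A"] * 7 + ["B"] * 7
            counts.append(len(vip_select(oplsda(scaled, y))))
        # under the null the VIP>1 count stays near its combinatorial share
        assert np.mean(counts) < 12

    def test_threshold_above_max_gives_empty(self):
        scaled, y = TestOplsda._two_group(seed=8)
        result = oplsda(scaled, y)
        assert len(vip_select(result, threshold=result.vip.max() + 1)) == 0
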