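"""Normalization, contamination scoring/residualization, outlier QC, PCA."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import proteorank as pr
from proteorank.datamodel import DataError
from proteorank.preprocess import (
    huber_regress_matrix,
    log2_reference_normalize,
    score_group_confounded,
)

from conftest import make_dataset


def _matrix(vals, proteins=None, samples=None):
    vals = np.asarray(vals, dtype=float)
    proteins = proteins or [f"P{i + 1}" for i in range(vals.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(vals.shape[1])]
    return pd.DataFrame(vals, index=proteins, columns=samples)


class TestNormalization:
    def test_column_median_centering(self):
        mat = _matrix([[2.0], [8.0]])
        out = pr.log2_median_normalize(mat)
        np.testing.assert_allclose(out.to_numpy().ravel(), [-1.0, 1.0])

    def test_idempotent_on_log_scale(self):
        ds = make_dataset(n_proteins=9)
        once = pr.log2_median_normalize(ds)
        twice = pr.log2_median_normalize(np.exp2(once))
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_all_missing_column_rejected(self):
        mat = _matrix([[4.0, np.nan], [16.0, np.nan]])
        with pytest.raises(DataError, match="empty sample"):
            pr.log2_median_normalize(mat)

    def test_missing_cells_stay_missing(self):
        ds = make_dataset(missing=[(0, 1)])
        out = pr.log2_median_normalize(ds)
        assert np.isnan(out.iloc[0, 1])
        assert np.isfinite(out.iloc[1, 1])

    def test_reference_normalization_removes_loading_offsets(self):
        """Per-sample loading multipliers collapse to one global constant."""
        ds = make_dataset(n_proteins=30, seed=2)
        shifted = ds.intensities * np.array([1.0, 4.0, 0.5, 2.0])
        a = log2_reference_normalize(ds.intensities)
        b = log2_reference_normalize(shifted)
        diff = (b - a).to_numpy()
        np.testing.assert_allclose(diff, diff.mean(), atol=1e-9)


class TestContaminationScore:
    def test_mean_of_panel(self):
        mat = _matrix([[10.0], [12.0], [99.0]])
        s = pr.contamination_score(mat, ["P1", "P2"])
        assert s.iloc[0] == 11.0

    def test_single_protein_panel(self):
        mat = _matrix([[7.0, 3.0]])
        s = pr.contamination_score(mat, ["P1"])
        np.testing.assert_allclose(s.to_numpy(), [7.0, 3.0])

    def test_panel_order_irrelevant(self):
        mat = _matrix(np.arange(12.0).reshape(3, 4))
        a = pr.contamination_score(mat, ["P1", "P2", "P3"])
        b = pr.contamination_score(mat, ["P3", "P1", "P2"])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_unobserved_panel_sample_rejected(self):
        mat = _matrix([[5.0, np.nan], [1.0, 2.0]])
        with pytest.raises(DataError, match="s2"):
            pr.contamination_score(mat, ["P1"])


class TestRobustRegression:
    def test_exact_linear_fit_recovers_slope_and_flattens(self):
        """y = 2*score + 5 exactly: slope 2, residual column constant 5."""
        s = pd.Series([-2.0, -1.0, 0.0, 1.0, 2.0], index=[f"s{i}" for i in range(5)])
        y = 2.0 * s.to_numpy() + 5.0
        mat = _matrix(y[None, :], samples=list(s.index))
        model = pr.regress_out_contamination(mat, s)
        assert abs(model.coefficients.iloc[0] - 2.0) < 1e-8
        np.testing.assert_allclose(model.residual_matrix.to_numpy().ravel(), 5.0, atol=1e-8)

    def test_independent_protein_passes_through(self):
        rng = np.random.default_rng(0)
        corr = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            s = pd.Series(rng.normal(0, 1, 30), index=[f"s{i}" for i in range(30)])
            y = rng.normal(10, 1, 30)
            mat = _matrix(y[None, :], samples=list(s.index))
            model = pr.regress_out_contamination(mat, s)
            assert abs(model.coefficients.iloc[0]) < 0.5
            corr.append(np.corrcoef(model.residual_matrix.to_numpy().ravel(), y)[0, 1])
        # a spurious fitted slope removes O(1/n) of the variance at most
        assert min(corr) > 0.9
        assert np.mean(corr) > 0.95

    def test_huber_resists_gross_outlier_better_than_ols(self):
        """Closed-form OLS is pulled by one gross outlier; Huber is not."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = 20
            s = rng.normal(0, 1, m)
            y = s + rng.normal(0, 0.1, m)
            y[int(rng.integers(m))] += 8.0
            X = np.column_stack([np.ones(m), s])
            ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
            _, b1, _ = huber_regress_matrix(y[None, :], s)
            if abs(b1[0] - 1.0) < abs(ols - 1.0):
                wins += 1
        assert wins >= 9

    def test_weighted_residual_orthogonal_to_score(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(0, 1, 24), index=[f"s{i}" for i in range(24)])
        vals = rng.normal(12, 1, (40, 24)) + np.outer(rng.normal(0, 0.5, 40), s)
        vals[3, 5] = np.nan
        mat = _matrix(vals, samples=list(s.index))
        model = pr.regress_out_contamination(mat, s)
        sc = s.to_numpy() - s.to_numpy().mean()
        for i in range(40):
            w = model.robust_weights.iloc[i].to_numpy()
            obs = np.isfinite(w)
            r = (model.residual_matrix.iloc[i] - model.intercepts.iloc[i]).to_numpy()[obs]
            wc = w[obs]
            num = np.sum(wc * r * sc[obs])
            denom = np.sqrt(np.sum(wc * r**2) * np.sum(wc * sc[obs] ** 2))
            if denom > 0:
                assert abs(num / denom) < 1e-8

    def test_equals_ols_when_no_point_downweighted(self):
        rng = np.random.default_rng(2)
        m = 50
        s = rng.normal(0, 1, m)
        y = 3.0 + 0.5 * s + rng.normal(0, 0.01, m) * 0.0 + rng.uniform(-0.01, 0.01, m)
        b0, b1, w = huber_regress_matrix(y[None, :], s)
        assert np.nanmin(w) == 1.0
        X = np.column_stack([np.ones(m), s])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert abs(b0[0] - beta[0]) < 1e-10
        assert abs(b1[0] - beta[1]) < 1e-10

    def test_matches_statsmodels_rlm(self):
        """Vectorized IRLS equals statsmodels RLM (HuberT, c=1.345)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = 25
            s = rng.normal(0, 1, m)
            y = 1.0 + 2.0 * s + rng.normal(0, 0.5, m)
            y[int(rng.integers(m))] += rng.choice([-6.0, 6.0])
            b0, b1, _ = huber_regress_matrix(y[None, :], s)
            ref = sm.RLM(
                y, sm.add_constant(s), M=sm.robust.norms.HuberT(t=1.345)
            ).fit(maxiter=200, tol=1e-10, conv="coefs")
            assert abs(b0[0] - ref.params[0]) < 1e-5
            assert abs(b1[0] - ref.params[1]) < 1e-5

    def test_constant_scores_rejected(self):
        mat = _matrix(np.random.default_rng(0).uniform(1, 2, (3, 5)))
        s = pd.Series(np.ones(5), index=mat.columns)
        with pytest.raises(DataError, match="degenerate covariate"):
            pr.regress_out_contamination(mat, s)

    def test_sparse_protein_flagged_and_passed_through(self):
        vals = np.random.default_rng(0).normal(10, 1, (2, 6))
        vals[0, :4] = np.nan  # only 2 observations
        mat = _matrix(vals)
        s = pd.Series(np.arange(6.0), index=mat.columns)
        model = pr.regress_out_contamination(mat, s)
        assert model.unfitted == ["P1"]
        np.testing.assert_allclose(
            model.residual_matrix.iloc[0].to_numpy(), vals[0], equal_nan=True
        )


class TestOutlierDetection:
    def test_sd_fallback_hand_computation(self):
        """(0,0,0,8): MAD=0 so SD path; threshold 12 at k=3, 4 at k=1."""
        s = pd.Series([0.0, 0.0, 0.0, 8.0], index=list("abcd"))
        assert pr.detect_outlier_samples(s, k=3.0) == []
        assert pr.detect_outlier_samples(s, k=1.0) == ["d"]

    def test_all_equal_scores_no_outliers(self):
        s = pd.Series([5.0] * 6, index=[f"s{i}" for i in range(6)])
        assert pr.detect_outlier_samples(s) == []

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        s = pd.Series(rng.normal(0, 1, 20), index=[f"s{i}" for i in range(20)])
        s.iloc[3] += 6
        base = pr.detect_outlier_samples(s, k=3.0)
        scaled = pr.detect_outlier_samples(s * 37.0, k=3.0)
        assert base == scaled == ["s3"]

    def test_planted_outlier_recovery(self):
        """Simulated +5 SD contaminated samples are flagged at k=3.

        Clean samples are never flagged; the large majority of planted
        outliers are caught (a +5 SD shift can land just under a 3-robust-SD
        threshold, so seed-perfect recovery is not a property of the rule).
        """
        exact, recovered, planted_total = 0, 0, 0
        for seed in range(10):
            cfg = pr.default_study_config(n_proteins=500, seed=seed)
            datasets, truth = pr.generate_study(cfg)
            csf = [d for d in datasets if d.dataset_id == "csf_disc"][0]
            logm = log2_reference_normalize(csf)
            scores = pr.contamination_score(logm, truth.contamination_marker_ids)
            flagged = pr.detect_outlier_samples(scores, k=3.0)
            assert set(flagged) <= set(truth.outlier_sample_ids)  # no false flags
            recovered += len(set(flagged) & set(truth.outlier_sample_ids))
            planted_total += len(truth.outlier_sample_ids)
            exact += sorted(flagged) == sorted(truth.outlier_sample_ids)
        assert recovered >= 0.8 * planted_total
        assert exact >= 6


class TestConfoundedBranch:
    def test_group_associated_score_detected_and_correction_skipped(self):
        rng = np.random.default_rng(0)
        groups = ("AD",) * 8 + ("Ctl",) * 8
        ds = make_dataset(n_proteins=30, groups=groups, seed=5)
        # plant a marker protein strongly separating the groups
        mat = ds.intensities.copy()
        mat.loc["P001"] = np.concatenate([
            2000.0 + rng.normal(0, 10, 8),
            100.0 + rng.normal(0, 5, 8),
        ])
        ds = pr.ProteomeDataset(
            "toy", "csf", "human", "discovery", mat, ds.sample_groups
        )
        res = pr.preprocess_dataset(
            ds, ["P001"], skip_correction_if_confounded=True
        )
        assert res.confounded
        assert res.model is None  # only outlier handling, no residualization

    def test_confound_statistic_null_case(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(0, 1, 20), index=[f"s{i}" for i in range(20)])
        groups = pd.Series(["AD"] * 10 + ["Ctl"] * 10, index=scores.index)
        flagged, p = score_group_confounded(scores, groups)
        assert p > 0.05 and not flagged


class TestPCA:
    def test_planted_groups_separate_on_pc1(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, m = 200, 16
            X = rng.normal(0, 1, (n, m))
            X[: n // 10, 8:] += 3.0  # 10% of proteins shifted in half the samples
            mat = _matrix(X)
            scores, var = pr.pca_qc(mat)
            pc1 = scores["PC1"].to_numpy()
            if max((pc1[:8].max() < pc1[8:].min()), (pc1[:8].min() > pc1[8:].max())):
                hits += 1
        assert hits >= 9

    def test_duplicate_samples_identical_coordinates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (50, 4))
        X[:, 3] = X[:, 0]
        scores, _ = pr.pca_qc(_matrix(X))
        np.testing.assert_allclose(
            scores.iloc[0].to_numpy(), scores.iloc[3].to_numpy(), atol=1e-9
        )

    def test_variance_fractions_bounded(self):
        rng = np.random.default_rng(1)
        scores, var = pr.pca_qc(_matrix(rng.normal(0, 1, (30, 6))))
        assert 0 <= var.sum() <= 1 + 1e-12

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 8))
        a, _ = pr.pca_qc(_matrix(X))
        b, _ = pr.pca_qc(_matrix(X.copy()))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            pr.pca_qc(_matrix([[1.0]]))
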