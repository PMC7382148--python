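"""Moderated t, Z transform, BH FDR, DE calling, abundance/depth analysis."""

import os
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import proteorank as pr
from proteorank.datamodel import DataError
from proteorank.diffexp import estimate_variance_prior, trigamma_inverse


def _de_input(a, c):
    """Build (matrix, groups) from per-group value lists for one protein."""
    a, c = np.atleast_2d(a), np.atleast_2d(c)
    mat = pd.DataFrame(
        np.hstack([a, c]),
        index=[f"P{i}" for i in range(a.shape[0])],
        columns=[f"a{j}" for j in range(a.shape[1])] + [f"c{j}" for j in range(c.shape[1])],
    )
    groups = pd.Series(
        ["AD"] * a.shape[1] + ["Ctl"] * c.shape[1], index=mat.columns
    )
    return mat, groups


class TestModeratedT:
    def test_d0_zero_is_textbook_pooled_t(self):
        """x=(1,2,3) vs y=(4,5,6): pooled t = -3.674, p ~ 0.0214 on 4 df."""
        mat, groups = _de_input([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]])
        de = pr.fit_moderated_t(mat, groups, d0=0)
        t = de.table["t"].iloc[0]
        p = de.table["p_raw"].iloc[0]
        assert abs(t - (-3.6742346)) < 1e-6
        assert abs(p - 0.0213116) < 1e-6

    def test_d0_zero_equals_scipy_pooled_t_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            na, nc = rng.integers(3, 9, size=2)
            a = rng.normal(0, 1, (20, na))
            c = rng.normal(0.3, 1.2, (20, nc))
            mat, groups = _de_input(a, c)
            de = pr.fit_moderated_t(mat, groups, d0=0)
            t_ref, p_ref = stats.ttest_ind(a, c, axis=1, equal_var=True)
            np.testing.assert_allclose(de.table["t"], t_ref, atol=1e-12)
            np.testing.assert_allclose(de.table["p_raw"], p_ref, atol=1e-12)

    def test_d0_infinite_limit_uses_prior_variance_only(self):
        rng = np.random.default_rng(1)
        mat, groups = _de_input(rng.normal(0, 1, (30, 5)), rng.normal(0, 1, (30, 5)))
        de = pr.fit_moderated_t(mat, groups, d0=np.inf)
        lfc = de.table["log2fc"].to_numpy()
        expected = lfc / np.sqrt(de.s0sq * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(de.table["t"].to_numpy(), expected, atol=1e-12)

    def test_matches_limma_ebayes(self):
        """Independent oracle: R limma lmFit/eBayes on the same matrix."""
        rng = np.random.default_rng(3)
        n, na, nc = 60, 5, 6
        mat, groups = _de_input(
            rng.normal(10, 1, (n, na)) * rng.uniform(0.5, 2, (n, 1)),
            rng.normal(10, 1, (n, nc)) * rng.uniform(0.5, 2, (n, 1)),
        )
        de = pr.fit_moderated_t(mat, groups)
        with tempfile.TemporaryDirectory() as d:
            mat.to_csv(os.path.join(d, "m.tsv"), sep="\t")
            script = f"""
suppressMessages(library(limma))
m <- as.matrix(read.delim("{d}/m.tsv", row.names=1))
design <- model.matrix(~0 + factor(c(rep("AD",{na}), rep("Ctl",{nc})), levels=c("AD","Ctl")))
colnames(design) <- c("AD","Ctl")
fit <- eBayes(contrasts.fit(lmFit(m, design), makeContrasts(AD-Ctl, levels=design)))
out <- data.frame(t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior, s0sq=fit$s2.prior)
write.table(out, "{d}/limma.tsv", sep="\\t", quote=FALSE)
"""
            open(os.path.join(d, "cmp.R"), "w").write(script)
            subprocess.run(["Rscript", os.path.join(d, "cmp.R")], check=True,
                           capture_output=True)
            ref = pd.read_csv(os.path.join(d, "limma.tsv"), sep="\t", index_col=0)
        assert abs(de.d0 - ref["d0"].iloc[0]) < 1e-4
        assert abs(de.s0sq - ref["s0sq"].iloc[0]) < 1e-6
        np.testing.assert_allclose(de.table["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(de.table["p_raw"], ref["p"], atol=1e-8)

    def test_null_p_uniform_and_shrinkage_tames_small_variances(self):
        """Under the global null p is uniform; shrinkage beats the plain t
        at fixed |t| cutoffs because tiny sample variances stop exploding."""
        ks_ps, excess_plain, excess_mod = [], [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mat, groups = _de_input(
                rng.normal(0, 1, (2000, 10)), rng.normal(0, 1, (2000, 10))
            )
            de = pr.fit_moderated_t(mat, groups)
            plain = pr.fit_moderated_t(mat, groups, d0=0)
            p = de.table["p_raw"].to_numpy()
            ks_ps.append(stats.kstest(p, "uniform").pvalue)
            cut = 4.0
            excess_plain.append((np.abs(plain.table["t"]) > cut).mean())
            excess_mod.append((np.abs(de.table["t"]) > cut).mean())
        assert min(ks_ps) > 0.01
        assert np.mean(excess_mod) <= np.mean(excess_plain)

    def test_missing_group_rejected(self):
        mat, groups = _de_input([[1.0, 2.0]], [[3.0, 4.0]])
        with pytest.raises(DataError):
            pr.fit_moderated_t(mat, groups.replace("Ctl", "MCI"))

    def test_sparse_protein_gets_missing_statistics(self):
        rng = np.random.default_rng(0)
        a, c = rng.normal(0, 1, (5, 4)), rng.normal(0, 1, (5, 4))
        a[0, :3] = np.nan  # one usable AD sample only
        mat, groups = _de_input(a, c)
        de = pr.fit_moderated_t(mat, groups)
        assert np.isnan(de.table["p_raw"].iloc[0])
        assert np.isnan(de.table["z"].iloc[0])
        assert de.table["p_raw"].iloc[1:].notna().all()

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in (0.01, 0.5, 2.0, 40.0, 500.0):
            y = float(polygamma(1, x))
            assert abs(trigamma_inverse(y) - x) < 1e-6 * max(1.0, x)


class TestZTransform:
    def test_basic_example(self):
        np.testing.assert_allclose(
            pr.z_transform_logfc([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0]
        )

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=40).filter(
            lambda v: np.std(v) > 1e-6
        )
    )
    def test_output_standardized(self, vals):
        z = pr.z_transform_logfc(vals)
        assert abs(np.mean(z)) < 1e-9
        assert abs(np.std(z, ddof=1) - 1.0) < 1e-9

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        np.testing.assert_allclose(
            pr.z_transform_logfc(x), pr.z_transform_logfc(3.0 * x + 7.0), atol=1e-9
        )

    def test_zero_sd_rejected(self):
        with pytest.raises(DataError, match="degenerate"):
            pr.z_transform_logfc([2.0, 2.0, 2.0])


def _bh_bruteforce(p):
    """Sort, scale by n/rank, cumulative-min from the bottom, unsort."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBH:
    def test_hand_examples(self):
        np.testing.assert_allclose(
            pr.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(pr.bh_adjust([0.01, 0.5]), [0.02, 0.5])
        np.testing.assert_allclose(pr.bh_adjust([0.3]), [0.3])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(pr.bh_adjust(p), _bh_bruteforce(p), atol=1e-12)

    def test_nan_passthrough_and_range_check(self):
        out = pr.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])
        with pytest.raises(DataError):
            pr.bh_adjust([0.5, 1.5])

    def test_monotone_and_above_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        fdr = pr.bh_adjust(p)
        assert np.all(fdr >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-12)


class TestCallDE:
    def _result(self, z, fdr, p=None):
        n = len(z)
        tbl = pd.DataFrame(
            {
                "log2fc": z,
                "z": z,
                "t": z,
                "p_raw": p if p is not None else fdr,
                "fdr": fdr,
                "mean_abund": np.zeros(n),
                "n_ad": 5,
                "n_ctl": 5,
                "s2": 1.0,
            },
            index=[f"P{i}" for i in range(n)],
        )
        return pr.DEResult("toy", "csf", tbl, d0=1.0, s0sq=1.0)

    def test_joint_threshold(self):
        de = self._result([5.1, 1.0], [0.001, 0.5])
        assert pr.call_de(de, pr.DECallSpec(z_min=2, fdr_max=0.05)) == {"P0"}

    def test_stringent_nested_in_default(self):
        rng = np.random.default_rng(0)
        de = self._result(rng.normal(0, 3, 200), rng.random(200))
        loose = pr.call_de(de, pr.DECallSpec(z_min=2, fdr_max=0.05))
        strict = pr.call_de(de, pr.DECallSpec(z_min=5, fdr_max=0.01))
        assert strict <= loose

    def test_direction_filter(self):
        de = self._result([-3.0, 3.0], [0.01, 0.01])
        assert pr.call_de(de, pr.DECallSpec(z_min=2, fdr_max=0.05, direction="down")) == {"P0"}
        assert pr.call_de(de, pr.DECallSpec(z_min=2, fdr_max=0.05, direction="up")) == {"P1"}


class TestAbundanceDepth:
    def test_rank_by_mean_and_ties_by_id(self):
        mat = pd.DataFrame(
            {"s1": [100.0, 10.0, 1.0, 10.0]},
            index=["B", "C", "D", "A"],
        )
        r = pr.abundance_rank(mat)
        assert r["B"] == 1 and r["A"] == 2 and r["C"] == 3 and r["D"] == 4

    def test_depth_curve_counts_and_median(self):
        ranks = pd.Series(
            np.arange(1, 5001), index=[f"P{i:04d}" for i in range(1, 5001)]
        )
        curve = pr.depth_detection_curve({"P0010", "P3000"}, ranks, [500, 4000])
        assert curve.detected_counts == [1, 2]
        assert curve.median_rank == 1505.0

    def test_saturation_at_max_rank(self):
        ranks = pd.Series([1, 2, 3], index=["A", "B", "C"])
        curve = pr.depth_detection_curve({"A", "B", "C"}, ranks, [3])
        assert curve.detected_counts == [3]

    def test_unknown_query_protein_rejected(self):
        ranks = pd.Series([1], index=["A"])
        with pytest.raises(DataError, match="ZZ"):
            pr.depth_detection_curve({"ZZ"}, ranks, [1])

    def test_curve_monotone_for_random_sets(self):
        rng = np.random.default_rng(0)
        ranks = pd.Series(
            np.arange(1, 1001), index=[f"P{i}" for i in range(1000)]
        )
        for _ in range(10):
            q = set(rng.choice(ranks.index, 40, replace=False))
            grid = np.sort(rng.integers(1, 1001, size=8))
            curve = pr.depth_detection_curve(q, ranks, grid)
            assert np.all(np.diff(curve.detected_counts) >= 0)

    def test_simulator_ranks_match_planted_order(self, small_study):
        cfg, datasets, truth = small_study
        ds = datasets[0]
        r = pr.abundance_rank(np.log2(ds.intensities))
        order = truth.abundance_order()
        expected = {p: i + 1 for i, p in enumerate(order) if p in set(ds.proteins)}
        # noise can swap close neighbours; planted order holds to a few ranks
        diffs = [abs(r[p] - expected[p]) for p in ds.proteins]
        assert np.median(diffs) <= 5


class TestValidationCorrelation:
    def test_limits(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pr.validation_correlation(x, x) == pytest.approx(1.0)
        assert pr.validation_correlation(x, -x) == pytest.approx(-1.0)

    def test_noisy_replicate_high_r(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 20)
            y = x + rng.normal(0, 0.1 * np.std(x), 20)
            if pr.validation_correlation(x, y) > 0.95:
                hits += 1
        assert hits >= 9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            pr.validation_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DataError):
            pr.validation_correlation([1.0, 2.0], [1.0, 2.0])
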