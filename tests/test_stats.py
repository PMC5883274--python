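"""Tests for background correction, normalization, filters and the
moderated t framework."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from songmark import stats as st


class TestBackgroundCorrection:
    @pytest.mark.parametrize(
        "fg,bg,expected",
        [(1000.0, 100.0, 900.0), (80.0, 100.0, 0.5), (100.0, 100.0, 0.5)],
    )
    def test_half_rule(self, fg, bg, expected):
        assert st.background_correct_half(fg, bg) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.background_correct_half(-1.0, 0.0)


class TestLoessNormalization:
    def test_constant_m_normalizes_to_zero(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(5, 12, 400)
        M = np.full(400, 0.7)
        out = st.normalize_within_array(M, A, tip_groups=np.zeros(400, int))
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_planted_intensity_bias_removed(self):
        """A smooth 0.5*sin(A) dye bias is reduced at least five-fold."""
        rng = np.random.default_rng(1)
        n = 4000
        A = rng.uniform(6, 14, n)
        bias = 0.5 * np.sin(A)
        M = bias + rng.normal(0, 0.1, n)
        tips = rng.integers(0, 8, n)
        out = st.normalize_within_array(M, A, tip_groups=tips)
        before = sps.binned_statistic(A, M, bins=20)[0]
        after = sps.binned_statistic(A, out, bins=20)[0]
        assert np.mean(np.abs(before)) > 5 * np.mean(np.abs(after))

    def test_single_group_equals_global_fit(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(5, 12, 300)
        M = 0.3 * A + rng.normal(0, 0.1, 300)
        one = st.normalize_within_array(M, A, tip_groups=np.zeros(300, int))
        glob = st.normalize_within_array(M, A)
        np.testing.assert_allclose(one, glob)

    def test_degenerate_identical_a_subtracts_median(self):
        M = np.array([1.0, 2.0, 3.0])
        out = st.normalize_within_array(M, np.full(3, 8.0))
        np.testing.assert_allclose(out, M - 2.0)


class TestOrientation:
    def test_sample_in_cy5_unchanged(self):
        np.testing.assert_allclose(
            st.to_sample_over_reference(np.array([1.2]), "Cy5"), [1.2]
        )

    def test_sample_in_cy3_flips_sign(self):
        np.testing.assert_allclose(
            st.to_sample_over_reference(np.array([1.2]), "Cy3"), [-1.2]
        )

    def test_unknown_dye_rejected(self):
        with pytest.raises(ValueError):
            st.to_sample_over_reference(np.array([1.0]), "Cy9")


class TestLowSignalFilter:
    def test_threshold_formula_matches_window_recomputation(self):
        """threshold == window mean + 2.5 * window SD, recomputed from the
        sorted curve and the reported window bounds."""
        rng = np.random.default_rng(3)
        n = 4000
        expressed = rng.random(n) < 0.3
        vals = np.where(expressed, rng.normal(10, 1, n), rng.normal(4, 0.5, n))
        rm = pd.DataFrame({"nucleus": vals, "surround": vals + 0.05})
        thr, removed, info = st.low_signal_cutoff(rm)
        assert info["method"] == "knee"
        stat = rm.max(axis=1).sort_values(ascending=False).to_numpy()
        wlo, whi = info["window"]
        window = stat[wlo:whi]
        assert thr == pytest.approx(window.mean() + 2.5 * window.std(ddof=1))

    def test_unimodal_curve_triggers_fallback(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(10, 1, 5000)
        rm = pd.DataFrame({"nucleus": vals, "surround": vals})
        with pytest.warns(UserWarning):
            thr, removed, info = st.low_signal_cutoff(rm)
        assert info["method"] == "fallback"
        assert len(removed) == 0

    def test_mean_statistic_option(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(9, 1, 2000)
        rm = pd.DataFrame({"a": vals, "b": vals - 4.0})
        stat_max, _, _ = st.low_signal_cutoff(rm, statistic="max")
        with pytest.raises(ValueError):
            st.low_signal_cutoff(rm, statistic="median")


class TestCvFilter:
    def test_equal_cvs_remove_nothing(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(100, 1000, 50)
        values = pd.DataFrame(
            {f"s{i}": base * (1 + 0.1 * np.sin(i)) for i in range(4)}
        )
        removed, cv, thr, nonpos = st.high_variance_filter(values)
        assert len(removed) == 0 and len(nonpos) == 0

    def test_extreme_cv_probe_removed_boundary_retained(self):
        rng = np.random.default_rng(7)
        n = 200
        values = pd.DataFrame(rng.normal(100, 5, (n, 6)))
        values.iloc[0] = [40, 160, 40, 160, 40, 160]  # CV far above the rest
        removed, cv, thr, _ = st.high_variance_filter(values)
        assert 0 in set(removed)
        # strict inequality: a probe exactly at 2x the mean CV is retained
        cv2 = cv.drop(index=0)
        boundary = cv2.index[(cv2 <= thr)]
        assert not (set(boundary) & set(removed))

    def test_nonpositive_mean_flagged(self):
        values = pd.DataFrame({"a": [1.0, -5.0], "b": [2.0, -6.0]})
        removed, cv, thr, nonpos = st.high_variance_filter(values)
        assert list(nonpos) == [1]


def _null_matrix(seed, m=10000, n1=3, n2=3, sd_spread=0.3):
    rng = np.random.default_rng(seed)
    sd = 0.4 * np.exp(rng.normal(0, sd_spread, m))
    vals = rng.normal(0, 1, (m, n1 + n2)) * sd[:, None]
    return pd.DataFrame(vals, index=[f"P{i}" for i in range(m)])


class TestModeratedT:
    def test_no_shrinkage_limit_equals_ordinary_t(self):
        """d0 = 0 reproduces the textbook pooled two-sample t exactly."""
        mat = _null_matrix(8, m=300)
        groups = ["nucleus"] * 3 + ["surround"] * 3
        tab, _ = st.fit_moderated_t(mat, groups, d0=0)
        ref = sps.ttest_ind(mat.iloc[:, :3], mat.iloc[:, 3:], axis=1)
        np.testing.assert_allclose(tab["t_mod"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(tab["p"], ref.pvalue, atol=1e-10)

    def test_complete_shrinkage_limit_is_fixed_variance_z(self):
        """d0 -> infinity collapses every probe onto the prior variance."""
        mat = _null_matrix(9, m=300)
        groups = ["nucleus"] * 3 + ["surround"] * 3
        tab, model = st.fit_moderated_t(mat, groups, d0=np.inf, s0sq=0.25)
        se = np.sqrt(0.25 * (2.0 / 3.0))
        np.testing.assert_allclose(tab["t_mod"], tab["M"] / se, atol=1e-10)
        np.testing.assert_allclose(
            tab["p"], 2 * sps.norm.sf(np.abs(tab["t_mod"])), atol=1e-12
        )

    def test_posterior_variance_lies_between_prior_and_sample(self):
        mat = _null_matrix(10, m=500)
        groups = ["nucleus"] * 3 + ["surround"] * 3
        tab, model = st.fit_moderated_t(mat, groups)
        s2_post = (model.d0 * model.s0sq + model.dg * tab["s2"]) / (
            model.d0 + model.dg
        )
        lo = np.minimum(tab["s2"], model.s0sq)
        hi = np.maximum(tab["s2"], model.s0sq)
        assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()

    def test_group_swap_antisymmetry(self):
        mat = _null_matrix(11, m=200)
        groups = np.array(["nucleus"] * 3 + ["surround"] * 3)
        a, _ = st.fit_moderated_t(mat, groups)
        b, _ = st.fit_moderated_t(mat, groups, group_order=("surround", "nucleus"))
        np.testing.assert_allclose(a["M"], -b["M"], atol=1e-12)
        np.testing.assert_allclose(a["t_mod"], -b["t_mod"], atol=1e-10)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_column_permutation_invariance(self):
        mat = _null_matrix(12, m=200)
        groups = np.array(["nucleus"] * 3 + ["surround"] * 3)
        perm = [3, 0, 4, 1, 5, 2]
        a, _ = st.fit_moderated_t(mat, groups)
        b, _ = st.fit_moderated_t(mat.iloc[:, perm], groups[perm])
        np.testing.assert_allclose(a["t_mod"], b["t_mod"], atol=1e-10)

    def test_single_sample_group_rejected(self):
        mat = _null_matrix(13, m=50).iloc[:, :3]
        with pytest.raises(ValueError):
            st.fit_moderated_t(mat, ["nucleus", "nucleus", "surround"])

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's lmFit/eBayes on the same matrix
        reproduces our hyperparameters and moderated statistics."""
        mat = _null_matrix(42, m=200)
        mat.iloc[:20, :3] += 1.0
        groups = ["nucleus"] * 3 + ["surround"] * 3
        tab, model = st.fit_moderated_t(mat, groups)
        csv = tmp_path / "mat.csv"
        mat.to_csv(csv)
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            mat <- as.matrix(read.csv('{csv}', row.names=1))
            design <- cbind(Intercept=1, nucleus=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(mat, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])
            write.csv(out, '{tmp_path / "out.csv"}', row.names=FALSE)
            cat(fit$df.prior, fit$s2.prior, sep='\\n')
        """))
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        d0_r, s0sq_r = map(float, proc.stdout.split())
        ref = pd.read_csv(tmp_path / "out.csv")
        assert model.d0 == pytest.approx(d0_r, rel=1e-4)
        assert model.s0sq == pytest.approx(s0sq_r, rel=1e-4)
        np.testing.assert_allclose(tab["t_mod"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(tab["p"], ref["p"], rtol=1e-6)


class TestMultipleTesting:
    def test_bh_matches_hand_computed_step_up(self):
        np.testing.assert_allclose(
            st.adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(
            st.adjust_pvalues([0.01, 0.04, 0.9]), [0.03, 0.06, 0.9]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(st.adjust_pvalues([1.0, 1.0, 1.0]), 1.0)

    def test_storey_with_pi0_one_equals_bh(self):
        # p-values concentrated near 1 push the pi0 estimate to its cap
        p = np.linspace(0.5, 1.0, 40)
        np.testing.assert_allclose(
            st.adjust_pvalues(p, "storey"), st.adjust_pvalues(p, "BH")
        )

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(14)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(0, 1, 200)])
        assert (st.adjust_pvalues(p, "storey") <= st.adjust_pvalues(p, "BH") + 1e-12).all()

    def test_q_monotone_in_p_and_above_p(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(0, 1, 500)
        q = st.adjust_pvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            st.adjust_pvalues([0.5, 1.2])
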