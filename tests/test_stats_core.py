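import math

import numpy as np
import pytest
from scipy import stats

from diffmark.stats_core import (
    CountMatrix,
    ModerationParams,
    NormalizedMatrix,
    bh_fdr,
    chisq_independence,
    estimate_moderation,
    hypergeom_enrichment,
    log_transform,
    moderated_t_test,
    ranksum_compare,
    scale_normalize,
)


def make_cm(counts, libs=None, condition=None):
    counts = np.asarray(counts)
    nf, ns = counts.shape
    if libs is None:
        libs = counts.sum(axis=0)
    if condition is None:
        condition = ["control"] * (ns // 2) + ["treated"] * (ns - ns // 2)
    return CountMatrix(
        [f"f{i}" for i in range(nf)], [f"s{j}" for j in range(ns)], counts, libs, condition
    )


def make_nm(values, condition=None):
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    if condition is None:
        condition = ["control"] * (ns // 2) + ["treated"] * (ns - ns // 2)
    return NormalizedMatrix(
        [f"f{i}" for i in range(nf)], [f"s{j}" for j in range(ns)], values, condition, 1.0, 1e6
    )


class TestScaleNormalize:
    def test_per_million_arithmetic(self):
        cm = make_cm([[10, 10], [0, 0]], libs=[2_000_000, 1_000_000])
        scaled, _ = scale_normalize(cm, target=1_000_000)
        assert scaled[0, 0] == pytest.approx(5.0)
        assert scaled[0, 1] == pytest.approx(10.0)

    def test_equal_libraries_identity(self):
        cm = make_cm([[3, 4], [5, 6]], libs=[1000, 1000])
        scaled, _ = scale_normalize(cm, target=1000)
        assert np.array_equal(scaled, cm.counts)

    def test_column_sums_reconstruct_raw(self, rng):
        counts = rng.integers(0, 100, size=(30, 4))
        libs = rng.integers(10_000, 50_000, size=4)
        cm = make_cm(counts, libs=libs)
        scaled, target = scale_normalize(cm)
        # scaled column sum * (library/target) recovers the raw column sum
        back = scaled.sum(axis=0) * (libs / target)
        assert np.allclose(back, counts.sum(axis=0))
        # equalized effective totals relative to depth
        eff = scaled.sum(axis=0) / counts.sum(axis=0) * libs
        assert np.allclose(eff, eff[0], rtol=1e-9)


class TestLogTransform:
    def test_values(self):
        cm = make_cm([[0, 3], [1, 1]])
        nm = log_transform(np.array([[0.0, 3.0], [1.0, 1.0]]), cm, pseudocount=1.0)
        assert nm.values[0, 0] == 0.0
        assert nm.values[0, 1] == pytest.approx(2.0)  # log2(4)

    def test_bad_pseudocount(self):
        cm = make_cm([[1, 1]])
        with pytest.raises(ValueError):
            log_transform(np.ones((1, 2)), cm, pseudocount=0.0)

    def test_column_order_preserved(self, rng):
        cm = make_cm(rng.integers(0, 50, size=(40, 2)))
        scaled = cm.counts.astype(float)
        nm = log_transform(scaled, cm, pseudocount=0.5)
        for j in range(2):
            assert np.array_equal(np.argsort(nm.values[:, j]), np.argsort(scaled[:, j]))


class TestModeration:
    def test_recovers_known_prior(self):
        # variances drawn from the scaled-F hierarchy with known d0, s0^2
        rng = np.random.default_rng(42)
        d0, s0_sq, d_g = 8.0, 0.5, 4
        sigma2 = d0 * s0_sq / rng.chisquare(d0, size=5000)
        s2 = sigma2 * rng.chisquare(d_g, size=5000) / d_g
        mod = estimate_moderation(s2, d_g)
        assert mod.d0 == pytest.approx(d0, rel=0.30)
        assert mod.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_constant_variances_give_complete_shrinkage(self):
        mod = estimate_moderation([0.3] * 100, residual_df=2)
        assert math.isinf(mod.d0)
        assert mod.s0_sq == pytest.approx(0.3, rel=1e-6)

    def test_zero_residual_df_rejected(self):
        with pytest.raises(ValueError):
            estimate_moderation([0.1, 0.2], residual_df=0)

    def test_all_zero_variances_instruct_user(self):
        with pytest.raises(ValueError, match="pseudocount|jitter"):
            estimate_moderation([0.0, 0.0, 0.0], residual_df=2)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_pooled_t(self, rng):
        values = rng.normal(size=(50, 6))
        nm = make_nm(values)
        results = moderated_t_test(nm, ModerationParams(0.0, 1.0))
        ref = stats.ttest_ind(values[:, 3:], values[:, :3], axis=1, equal_var=True)
        assert np.allclose([r.t_stat for r in results], ref.statistic)
        assert np.allclose([r.p_value for r in results], ref.pvalue)

    def test_d0_infinite_shares_prior_variance(self):
        nm = make_nm([[0.0, 0.0, 1.0, 1.0], [0.0, 2.0, 3.0, 5.0]])
        s0_sq = 0.25
        results = moderated_t_test(nm, ModerationParams(math.inf, s0_sq))
        for r, lfc in zip(results, [1.0, 3.0]):
            assert r.t_stat == pytest.approx(lfc / (math.sqrt(s0_sq) * math.sqrt(1.0)))

    def test_hand_computed_plugin(self):
        # lfc = 2.0; pooled s2 = 0.02; stilde2 = (2*0.02 + 2*0.02)/4 = 0.02
        # t = 2 / sqrt(0.02 * (1/2 + 1/2)) = 14.142135...; df = 4
        nm = make_nm([[1.0, 1.2, 3.0, 3.2]])
        (r,) = moderated_t_test(nm, ModerationParams(2.0, 0.02))
        assert r.log_fc == pytest.approx(2.0)
        assert r.t_stat == pytest.approx(14.142135623730951)
        assert r.p_value == pytest.approx(0.00014512817061319757, rel=1e-9)

    def test_shrinkage_boundedness(self, rng):
        # stilde^2 lies strictly between s_g^2 and s0^2 for finite positive d0
        values = rng.normal(size=(200, 4))
        nm = make_nm(values)
        mod = ModerationParams(4.0, 0.5)
        results = moderated_t_test(nm, mod)
        ctrl, trt = values[:, :2], values[:, 2:]
        s2 = (ctrl.var(axis=1, ddof=1) + trt.var(axis=1, ddof=1)) / 2
        stilde2 = np.array(
            [(r.log_fc / r.t_stat) ** 2 for r in results]
        )  # se^2 = stilde2 * (1/2+1/2)
        lo = np.minimum(s2, mod.s0_sq)
        hi = np.maximum(s2, mod.s0_sq)
        ok = (stilde2 > lo - 1e-12) & (stilde2 < hi + 1e-12)
        assert ok.all()

    def test_single_replicate_condition_rejected(self):
        nm = make_nm(np.zeros((3, 3)), condition=["control", "treated", "treated"])
        with pytest.raises(ValueError):
            moderated_t_test(nm, ModerationParams(1.0, 1.0))


class TestBH:
    def test_hand_stepup(self):
        q = bh_fdr([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_degenerate_vectors(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert np.allclose(bh_fdr([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels_and_is_idempotent(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        q = bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref)
        # q is monotone along sorted p
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        # thresholding q at alpha reproduces the classic step-up rejection set
        m = p.size
        for alpha in (0.2, 0.5, 0.9):
            ranked = np.sort(p)
            below = np.nonzero(ranked <= alpha * np.arange(1, m + 1) / m)[0]
            k = below[-1] + 1 if below.size else 0
            reject_stepup = p <= (ranked[k - 1] if k else -1.0)
            assert np.array_equal(q <= alpha, reject_stepup)


class TestChisq:
    def test_closed_form_2x2(self):
        stat, df, p = chisq_independence([[10, 20], [20, 10]])
        assert stat == pytest.approx(20.0 / 3.0)
        assert df == 1
        assert p == pytest.approx(0.009823274507519235, rel=1e-9)

    def test_expected_table_gives_zero(self):
        stat, df, p = chisq_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_df_of_2x3(self):
        _, df, _ = chisq_independence([[5, 6, 7], [8, 9, 10]])
        assert df == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chisq_independence([[0, 0], [5, 5]])

    def test_random_2x2_matches_closed_form(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 50, size=4)
            n = a + b + c + d
            want = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            stat, df, _ = chisq_independence([[a, b], [c, d]])
            assert stat == pytest.approx(want, rel=1e-10)


class TestHypergeom:
    def test_exact_combinatorial_corner(self):
        universe = {f"x{i}" for i in range(20)}
        term = {f"x{i}" for i in range(10)}
        rows = hypergeom_enrichment(term, universe, {"T": term})
        assert rows[0]["p"] == pytest.approx(1.0 / math.comb(20, 10), rel=1e-9)

    def test_matches_exact_summation(self, rng):
        universe = {f"x{i}" for i in range(30)}
        for _ in range(20):
            hits = set(rng.choice(sorted(universe), size=8, replace=False))
            term = set(rng.choice(sorted(universe), size=12, replace=False))
            rows = hypergeom_enrichment(hits, universe, {"T": term})
            k = len(term & hits)
            # exact upper-tail summation
            N, K, n = 30, 12, 8
            want = sum(
                math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
                for i in range(k, min(K, n) + 1)
            )
            assert rows[0]["p"] == pytest.approx(want, rel=1e-9)

    def test_empty_term_skipped(self):
        rows = hypergeom_enrichment({"a"}, {"a", "b"}, {"T": set()})
        assert rows == []

    def test_hit_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"z"}, {"a", "b"}, {})


class TestRanksum:
    def test_identical_samples(self):
        ma, mb, p = ranksum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ma == mb == 2.0
        assert p > 0.9

    def test_clear_shift(self):
        a = list(range(1, 21))
        b = list(range(101, 121))
        ma, mb, p = ranksum_compare(a, b)
        assert mb - ma == 100
        assert p < 1e-4

    def test_singletons(self):
        ma, mb, p = ranksum_compare([3.0], [5.0])
        assert (ma, mb) == (3.0, 5.0)
        assert 0.0 <= p <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ranksum_compare([], [1.0])


class TestLimmaCrossCheck:
    def test_moderated_pipeline_matches_limma(self, tmp_path):
        """Our moments fit + moderated t reproduces limma's lmFit/eBayes."""
        import shutil
        import subprocess

        rscript = shutil.which("Rscript")
        assert rscript, "Rscript not on PATH"
        rng = np.random.default_rng(20)
        values = rng.normal(7.0, 1.0, size=(120, 4))
        values[:8, 2:] += 1.5
        nm = make_nm(values)
        cond = np.asarray(nm.condition)
        ctrl = values[:, cond == "control"]
        trt = values[:, cond == "treated"]
        s2 = (ctrl.var(axis=1, ddof=1) + trt.var(axis=1, ddof=1)) / 2
        mod = estimate_moderation(s2, 2)
        ours = moderated_t_test(nm, mod)

        np.savetxt(tmp_path / "vals.tsv", values, delimiter="\t")
        script = f"""
        x <- as.matrix(read.table("{tmp_path}/vals.tsv"))
        suppressMessages(library(limma))
        design <- cbind(Intercept = 1, treated = c(0, 0, 1, 1))
        fit <- eBayes(lmFit(x, design))
        tt <- topTable(fit, coef = "treated", number = Inf, sort.by = "none")
        write.table(data.frame(t = tt$t, p = tt$P.Value), "{tmp_path}/out.tsv",
                    sep = "\\t", row.names = FALSE, quote = FALSE)
        """
        subprocess.run([rscript, "-e", script], check=True, capture_output=True)
        ref = np.loadtxt(tmp_path / "out.tsv", skiprows=1)
        assert np.allclose([r.t_stat for r in ours], ref[:, 0], rtol=5e-3, atol=1e-4)
        # limma caps the total df at sum(df.residual) where we take the
        # d0 = inf limit exactly (normal reference); referring our t to
        # limma's capped df must reproduce its p-values tightly
        df_cap = 2 * values.shape[0]
        p_on_capped_df = 2.0 * stats.t.sf(np.abs([r.t_stat for r in ours]), df_cap)
        assert np.allclose(p_on_capped_df, ref[:, 1], rtol=5e-3, atol=1e-8)
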