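import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special
from scipy import stats as sps

from phoscall import stats

# ---------------------------------------------------------------------------
# independent oracles: straight transcriptions of the closed-form equations,
# kept deliberately naive and separate from the implementation under test


def oracle_moderated(values, d0, s02):
    values = [v for v in values if not math.isnan(v)]
    n = len(values)
    mean = sum(values) / n
    s2 = sum((v - mean) ** 2 for v in values) / (n - 1)
    d = n - 1
    if math.isinf(d0):
        s2_post, df = s02, math.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df = d0 + d
    t = mean / math.sqrt(s2_post / n)
    if math.isinf(df):
        p = 2 * sps.norm.sf(abs(t))
    else:
        p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def oracle_bh(pvalues):
    """O(n^2) literal step-up: adj_i = min_{p_j >= p_i} p_j * m / rank_j."""
    m = len(pvalues)
    ranked = sorted(range(m), key=lambda i: pvalues[i])
    adj = [None] * m
    best = 1.0
    for pos in range(m - 1, -1, -1):
        i = ranked[pos]
        best = min(best, pvalues[i] * m / (pos + 1))
        adj[i] = best
    return adj


def oracle_prior(variances, d):
    """Independent transcription of the log-variance moment equations."""
    v = np.asarray(variances, float)
    e = np.log(v) - special.digamma(d / 2) + np.log(d / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2)
    if evar <= 0:
        return math.inf, float(np.mean(v))
    # invert trigamma by bisection (slow, simple, independent)
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if special.polygamma(1, mid) > evar:
            lo = mid
        else:
            hi = mid
    d0 = 2 * lo
    s02 = math.exp(np.mean(e) + special.digamma(d0 / 2) - math.log(d0 / 2))
    return d0, s02


# ---------------------------------------------------------------------------


class TestPriorEstimation:
    def test_recovers_point_prior_from_homogeneous_variances(self):
        rng = np.random.default_rng(101)
        d = 2
        variances = 1.0 * rng.chisquare(d, size=10000) / d
        prior = stats.estimate_prior(variances, d)
        # no inter-site heterogeneity: d0 very large (or infinite), s0^2 ~ 1
        assert prior.d0 > 50 or math.isinf(prior.d0)
        assert prior.s0_squared == pytest.approx(1.0, abs=0.05)

    def test_recovers_finite_prior_df(self):
        rng = np.random.default_rng(202)
        d0_true, s02_true, d = 4.0, 1.0, 2
        sig2 = d0_true * s02_true / rng.chisquare(d0_true, size=5000)
        variances = sig2 * rng.chisquare(d, size=5000) / d
        prior = stats.estimate_prior(variances, d)
        assert prior.d0 == pytest.approx(d0_true, rel=0.25)
        assert prior.s0_squared == pytest.approx(s02_true, rel=0.25)

    def test_two_identical_variances_give_point_prior_at_value(self):
        prior = stats.estimate_prior([0.3, 0.3], 2)
        assert math.isinf(prior.d0)
        assert prior.s0_squared == pytest.approx(0.3)

    def test_all_zero_variances_degenerate(self):
        with pytest.raises(stats.DegenerateInputError):
            stats.estimate_prior([0.0, 0.0, 0.0], 2)

    def test_agrees_with_independent_transcription(self):
        rng = np.random.default_rng(303)
        for _ in range(10):
            v = rng.chisquare(3, size=200) / 3 * rng.lognormal(0, 0.5, 200)
            prior = stats.estimate_prior(v, 3)
            d0_o, s02_o = oracle_prior(v, 3)
            if math.isinf(d0_o):
                assert math.isinf(prior.d0)
            else:
                assert prior.d0 == pytest.approx(d0_o, rel=1e-6)
            assert prior.s0_squared == pytest.approx(s02_o, rel=1e-6)

    def test_trigamma_inverse_roundtrip(self):
        for y in [1e-5, 0.01, 0.5, 1.645, 10.0, 1e6]:
            x = stats.trigamma_inverse(y)
            assert float(special.polygamma(1, x)) == pytest.approx(y, rel=1e-8)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_t(self):
        values = [-1.2, -0.8, -1.0]
        res = stats.moderated_t(values, d0=0.0, s0_squared=1.0)
        # mean -1, sd 0.2: t = -1 / (0.2 / sqrt(3)) = -5 * sqrt(3)
        assert res.t_mod == pytest.approx(-5 * math.sqrt(3), abs=1e-12)
        scipy_t = sps.ttest_1samp(values, 0.0)
        assert res.t_mod == pytest.approx(scipy_t.statistic, abs=1e-10)
        assert res.p == pytest.approx(scipy_t.pvalue, abs=1e-10)

    def test_d0_zero_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(404)
        for _ in range(50):
            values = rng.normal(0, 1, size=int(rng.integers(2, 8)))
            res = stats.moderated_t(values, d0=0.0, s0_squared=5.0)
            ref = sps.ttest_1samp(values, 0.0)
            assert res.t_mod == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetric_values_give_t_zero_p_one(self):
        res = stats.moderated_t([-0.4, 0.0, 0.4], d0=2.0, s0_squared=0.1)
        assert res.t_mod == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_sample_variance_uses_shrunken_variance(self):
        d0, s02, n = 3.0, 0.09, 3
        res = stats.moderated_t([-1.0, -1.0, -1.0], d0=d0, s0_squared=s02)
        expected_s2_post = d0 * s02 / (d0 + (n - 1))
        assert res.s2 == 0.0
        assert res.s2_post == pytest.approx(expected_s2_post)
        assert res.t_mod == pytest.approx(-1.0 / math.sqrt(expected_s2_post / n))

    def test_infinite_prior_is_z_test(self):
        values = [-0.5, -0.7, -0.6]
        res = stats.moderated_t(values, d0=math.inf, s0_squared=0.04)
        assert res.s2_post == pytest.approx(0.04)
        assert math.isinf(res.df_total)
        z = np.mean(values) / math.sqrt(0.04 / 3)
        assert res.t_mod == pytest.approx(z)
        assert res.p == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-12)

    def test_insufficient_replicates_gives_na(self):
        res = stats.moderated_t([-1.0, math.nan, math.nan], d0=1.0, s0_squared=1.0)
        assert math.isnan(res.t_mod) and math.isnan(res.p)

    def test_posterior_variance_between_sample_and_prior(self):
        rng = np.random.default_rng(505)
        for _ in range(50):
            values = rng.normal(0, 1, size=4)
            d0 = float(rng.uniform(0.5, 10))
            s02 = float(rng.uniform(0.1, 3))
            res = stats.moderated_t(values, d0=d0, s0_squared=s02)
            lo, hi = min(res.s2, s02), max(res.s2, s02)
            assert lo - 1e-12 <= res.s2_post <= hi + 1e-12

    def test_agrees_with_oracle_on_random_instances(self):
        rng = np.random.default_rng(606)
        for _ in range(50):
            values = rng.normal(-0.5, 0.5, size=int(rng.integers(2, 6)))
            d0 = float(rng.choice([0.0, 1.5, 4.0, math.inf]))
            s02 = float(rng.uniform(0.05, 2.0))
            res = stats.moderated_t(values, d0=d0, s0_squared=s02)
            t_o, df_o, p_o = oracle_moderated(values, d0, s02)
            assert res.t_mod == pytest.approx(t_o, rel=1e-10)
            assert res.p == pytest.approx(p_o, rel=1e-10)
            assert res.df_total == df_o or res.df_total == pytest.approx(df_o)


class TestBhFdr:
    def test_hand_worked_example(self):
        assert stats.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert stats.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(707)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
            assert stats.bh_fdr(p) == pytest.approx(oracle_bh(list(p)), abs=0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(808)
        p = rng.uniform(1e-6, 1.0, size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert stats.bh_fdr(p) == pytest.approx(ref, rel=1e-12)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_at_most_one(self, p):
        adj = stats.bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        # monotone in rank
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            stats.bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            stats.bh_fdr([0.5, 1.5])


class TestBaitEnrichment:
    def test_hand_computed_z(self):
        z = stats.bait_enrichment_z([10, 10, 10], [1, 1.1, 0.9])
        assert z == pytest.approx(90.0)

    def test_equal_means_give_zero(self):
        assert stats.bait_enrichment_z([1.0, 1.0], [0.9, 1.1]) == pytest.approx(0.0)

    def test_all_missing_controls_error(self):
        with pytest.raises(ValueError):
            stats.bait_enrichment_z([10, 10], [math.nan, math.nan])

    def test_missing_controls_imputed_with_floor(self):
        z = stats.bait_enrichment_z([10, 10], [2.0, math.nan, math.nan],
                                    floor=1.0)
        control = [2.0, 1.0, 1.0]
        expected = (10 - np.mean(control)) / np.std(control, ddof=1)
        assert z == pytest.approx(expected)

    def test_zero_control_spread_is_infinite_with_warning(self):
        with pytest.warns(RuntimeWarning):
            z = stats.bait_enrichment_z([5, 5], [1.0, 1.0, 1.0])
        assert math.isinf(z) and z > 0


class TestTypeIError:
    def test_null_simulation_calibration(self):
        """On pure-null data the moderated test keeps its nominal size."""
        import pandas as pd

        rng = np.random.default_rng(909)
        n_sites, n_rep = 7000, 3
        frames = []
        for i, cond in enumerate(["A", "B", "C"]):
            x = rng.normal(0.0, 0.25, size=(n_sites, n_rep))
            frames.append(pd.DataFrame({
                "site_id": [f"s{j}" for j in range(n_sites)],
                "condition": cond,
                "log2fc_rep1": x[:, 0],
                "log2fc_rep2": x[:, 1],
                "log2fc_rep3": x[:, 2],
                "summary_log2FC": np.median(x, axis=1),
                "protein_quantified": True,
            }))
        norm = pd.concat(frames, ignore_index=True)
        results = stats.test_all_conditions(norm)
        p = results["p"].to_numpy()
        assert len(p) >= 20000
        frac = float(np.mean(p < 0.05))
        assert frac == pytest.approx(0.05, abs=0.01)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestLimmaCrossCheck:
    def test_matches_limma_ebayes(self, tmp_path):
        """Full agreement with the reference empirical-Bayes implementation."""
        rng = np.random.default_rng(1010)
        d0_true, s02_true = 4.0, 0.04
        sig2 = d0_true * s02_true / rng.chisquare(d0_true, 120)
        x = rng.normal(0, np.sqrt(sig2)[:, None], size=(120, 3))
        x[:15] -= 1.0
        mat = tmp_path / "mat.tsv"
        np.savetxt(mat, x, delimiter="\t")
        out = tmp_path / "limma.tsv"
        script = tmp_path / "check.R"
        script.write_text(f"""
suppressMessages(library(limma))
x <- as.matrix(read.table('{mat}'))
fit <- eBayes(lmFit(x, design=matrix(1, ncol(x), 1)))
write.table(data.frame(d0=fit$df.prior, s02=fit$s2.prior,
                       t=fit$t[,1], p=fit$p.value[,1]),
            '{out}', sep='\\t', row.names=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        import pandas as pd

        ref = pd.read_csv(out, sep="\t")
        prior = stats.estimate_prior(x.var(axis=1, ddof=1), 2)
        assert prior.d0 == pytest.approx(float(ref["d0"][0]), rel=1e-6)
        assert prior.s0_squared == pytest.approx(float(ref["s02"][0]), rel=1e-6)
        for i in range(len(x)):
            res = stats.moderated_t(x[i], prior.d0, prior.s0_squared)
            assert res.t_mod == pytest.approx(float(ref["t"][i]), rel=1e-8)
            assert res.p == pytest.approx(float(ref["p"][i]), rel=1e-8)
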