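import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from isopull.errors import DomainError, HyperparameterError
from isopull.protein_stats import (
    D0_CAP,
    aggregate_protein,
    bh_adjust,
    fit_hyperparameters,
    moderated_test,
    run_differential,
)


class TestAggregateProtein:
    def test_median_and_log2(self):
        q = aggregate_protein([2.0, 4.0, 8.0], ["A", "B", "C"])
        assert q.protein_ratio == 4.0
        assert q.log2_ratio == 2.0
        assert q.n_peptides == 3

    def test_median_robust_to_one_outlier(self):
        q = aggregate_protein([1.0, 1.0, 1.0, 9.0], list("ABCD"))
        assert q.protein_ratio == 1.0

    def test_duplicate_sequences_count_once_but_both_ratios_enter(self):
        # oracle (hand evaluation): median{1, 1, 3, 5} = 2; distinct peps = 3
        q = aggregate_protein([1.0, 1.0, 3.0, 5.0], ["A", "A", "B", "C"])
        assert q.protein_ratio == 2.0
        assert q.n_peptides == 3

    def test_empty_raises(self):
        with pytest.raises(DomainError):
            aggregate_protein([], [])


class TestModeratedTest:
    def test_frozen_worked_example(self):
        # independent direct-formula oracle, evaluated before the build:
        # y = {1.0, 1.2, 0.8, 1.0}: mean 1.0, s2 = 0.08/3 = 0.0266667
        # s2_post = (4*0.04 + 3*0.0266667)/7 = 0.03428571
        # t = 1.0 / sqrt(0.03428571/4) = 10.8012, df = 7
        r = moderated_test([1.0, 1.2, 0.8, 1.0], d0=4.0, s0_2=0.04)
        assert r.mean_log2 == pytest.approx(1.0)
        assert r.s2_g == pytest.approx(0.0266667, abs=1e-6)
        assert r.s2_post == pytest.approx(0.0342857, abs=1e-6)
        assert r.t_mod == pytest.approx(10.8012, abs=1e-3)
        assert r.df == 7.0

    def test_no_moderation_limit_equals_classical_t(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2), size=rng.integers(3, 9))
            r = moderated_test(y, d0=0.0, s0_2=0.5)
            t_ref, p_ref = stats.ttest_1samp(y, 0.0)
            assert r.t_mod == pytest.approx(t_ref, abs=1e-10, rel=1e-10)
            assert r.p == pytest.approx(p_ref, abs=1e-10, rel=1e-10)

    def test_infinite_shrinkage_pins_posterior_at_prior(self):
        r = moderated_test([0.1, 0.4, -0.2, 0.3], d0=D0_CAP, s0_2=0.04)
        assert r.s2_post == pytest.approx(0.04, abs=1e-6)

    def test_all_zero_replicates_yield_null(self):
        r = moderated_test([0.0, 0.0, 0.0], d0=4.0, s0_2=0.0)
        assert r.t_mod == 0.0 and r.p == 1.0

    def test_single_replicate_rejected(self):
        with pytest.raises(DomainError):
            moderated_test([1.0], 1.0, 0.1)

    @given(
        s0=st.floats(0.01, 1.0), d0=st.floats(0.5, 50.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_posterior_variance_between_sample_and_prior(self, s0, d0, seed):
        y = np.random.default_rng(seed).normal(0, 0.5, size=4)
        r = moderated_test(y, d0=d0, s0_2=s0)
        lo, hi = min(r.s2_g, s0), max(r.s2_g, s0)
        assert lo - 1e-12 <= r.s2_post <= hi + 1e-12

    def test_abs_t_monotone_in_prior_variance(self):
        y = [0.5, 0.7, 0.6, 0.55]  # s2_g small
        ts = [abs(moderated_test(y, 4.0, s0).t_mod) for s0 in (0.01, 0.05, 0.2, 1.0)]
        assert all(a >= b for a, b in zip(ts, ts[1:]))


class TestHyperparameters:
    def test_identical_variances_give_complete_shrinkage(self):
        d0, s0 = fit_hyperparameters([0.04] * 20, 3)
        assert d0 == D0_CAP
        r = moderated_test([0.1, 0.2, 0.15, 0.12], d0, s0)
        assert r.s2_post == pytest.approx(s0, rel=1e-4)

    def test_recovery_from_scaled_inverse_chi_square(self):
        rng = np.random.default_rng(2024)
        d0_true, s0_true, dg = 4.0, 0.04, 3
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(dg, size=5000) / dg
        d0, s0 = fit_hyperparameters(s2, dg)
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0 == pytest.approx(s0_true, rel=0.10)

    def test_single_variance_rejected(self):
        with pytest.raises(HyperparameterError):
            fit_hyperparameters([0.1], 3)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_squeezevar(self, tmp_path):
        """Independent oracle: Bioconductor limma's squeezeVar on the same
        variances must yield the same prior df and prior variance."""
        rng = np.random.default_rng(42)
        sigma2 = 5.0 * 0.05 / rng.chisquare(5.0, size=300)
        s2 = sigma2 * rng.chisquare(3, size=300) / 3
        vf = tmp_path / "vars.txt"
        np.savetxt(vf, s2)
        out = subprocess.run(
            ["Rscript", "-e",
             f"suppressMessages(library(limma)); x<-scan('{vf}',quiet=TRUE);"
             "o<-squeezeVar(x,df=3); cat(sprintf('%.12g\\n', c(o$df.prior,o$var.prior)))"],
            capture_output=True, text=True, check=True,
        )
        d0_l, s0_l = map(float, out.stdout.split())
        d0, s0 = fit_hyperparameters(s2, 3)
        assert d0 == pytest.approx(d0_l, rel=1e-6)
        assert s0 == pytest.approx(s0_l, rel=1e-6)


def bh_oracle(p):
    """Brute-force step-up definition: adj_(i) = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        # oracle: {0.01,0.02,0.03,0.04} -> all 0.04
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equals_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_array_equal(bh_adjust(p), bh_oracle(p))

    def test_agrees_with_statsmodels_cross_check(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(15)
        for _ in range(50):
            p = rng.uniform(size=40)
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
            )

    def test_monotone_in_sorted_order_and_bounded(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj <= 1.0).all()

    def test_domain_error(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])


def _quants(rows):
    return pd.DataFrame(
        rows,
        columns=["protein_id", "sample_type", "condition", "fa_level",
                 "replicate", "log2_ratio", "n_peptides"],
    )


class TestRunDifferential:
    def test_noiseless_null_group_is_flat_and_insignificant(self):
        rows = [(f"P{i}", "WT_WT", "control", "fa_0.2", r, 0.0, 5)
                for i in range(5) for r in range(1, 5)]
        res = run_differential(_quants(rows))
        assert (res["enrichment_fold"] == 1.0).all()
        assert not res["significant"].any()

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(60):
            mu = 3.0 if i < 5 else 0.0
            for r in range(1, 5):
                rows.append(("Q%03d" % i, "BAIT_WT", "control", "fa_0.2", r,
                             mu + rng.normal(0, 0.15), 10))
        res = run_differential(_quants(rows))
        hits = set(res.loc[res["significant"], "protein_id"])
        assert hits == {"Q%03d" % i for i in range(5)}

    def test_bh_universe_is_per_sample_type(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(30):
            for r in range(1, 5):
                rows.append((f"P{i}", "BAIT_WT", "control", "fa_0.2", r,
                             rng.normal(0, 0.2), 5))
                rows.append((f"P{i}", "WT_WT", "control", "fa_0.2", r,
                             rng.normal(0, 0.2), 5))
        res = run_differential(_quants(rows))
        for _, sub in res.groupby("sample_type"):
            np.testing.assert_allclose(
                sub["adj_p"].to_numpy(), bh_adjust(sub["p"].to_numpy())
            )

    def test_groups_with_single_replicate_skipped(self):
        rows = [("P1", "BAIT_WT", "control", "fa_0.2", 1, 0.5, 3)] + [
            ("P2", "BAIT_WT", "control", "fa_0.2", r, 0.1, 3) for r in range(1, 5)
        ] + [("P3", "BAIT_WT", "control", "fa_0.2", r, 0.2, 3) for r in range(1, 5)]
        res = run_differential(_quants(rows))
        assert set(res["protein_id"]) == {"P2", "P3"}
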