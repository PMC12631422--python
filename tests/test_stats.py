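import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from cmcoh import (
    CMCCorrelation,
    bh_fdr,
    correlate,
    generate_cohort_frame,
    normality_gate,
    posthoc_power,
    run_analysis,
    stratify,
)
from cmcoh.core_io import ValidationError
from cmcoh.stats import _spearman_exact_p


class TestStratify:
    def _cohort(self, injury, fa=None):
        n = len(injury)
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "cst_injury_pct": injury,
                "fa_cst": fa if fa is not None else [0.5] * n,
            }
        )

    def test_midpoint_median_split(self):
        groups = stratify(self._cohort([10, 20, 80, 90]), "injury")
        assert sorted(groups["mild_moderate"]["cst_injury_pct"]) == [10, 20]
        assert sorted(groups["severe"]["cst_injury_pct"]) == [80, 90]

    def test_injury_boundary_subject_goes_mild_moderate(self):
        """A subject exactly at the median (≤ threshold) is mild-moderate."""
        groups = stratify(self._cohort([10, 30, 50, 80, 90]), "injury")
        assert 50 in set(groups["mild_moderate"]["cst_injury_pct"])

    def test_fa_boundary_subject_goes_high_integrity(self):
        """A subject exactly at the median FA (≥ threshold) is high."""
        cohort = self._cohort([0] * 5, fa=[0.40, 0.55, 0.62, 0.70, 0.75])
        groups = stratify(cohort, "integrity")
        assert 0.62 in set(groups["high"]["fa_cst"])
        assert len(groups["high"]) == 3 and len(groups["low"]) == 2

    def test_missing_fa_excluded_from_split(self):
        cohort = self._cohort([0] * 5, fa=[0.4, np.nan, 0.6, 0.7, np.nan])
        groups = stratify(cohort, "integrity")
        assert len(groups["high"]) + len(groups["low"]) == 3

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            stratify(self._cohort([50, 50, 50, 50]), "injury")


class TestNormalityGate:
    def test_gate_level_on_normal_data(self):
        """The raw-branch pass rate on i.i.d. normal samples sits near the
        nominal 95% of the Shapiro-Wilk test."""
        rng = np.random.default_rng(0)
        passes = sum(
            normality_gate(rng.standard_normal(20))[0] == "normal"
            for _ in range(300)
        )
        assert 0.90 <= passes / 300 <= 0.99

    def test_lognormal_data_takes_log_branch(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(60):
            x = np.exp(rng.standard_normal(50) * 1.2)
            dist, transformed = normality_gate(x)
            if dist == "lognormal":
                hits += 1
                np.testing.assert_allclose(transformed, np.log(x))
        assert hits > 30

    def test_nonpositive_sample_skips_log_branch(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([[0.0], np.exp(rng.standard_normal(49) * 1.5)])
        assert normality_gate(x)[0] == "nonnormal"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            normality_gate(np.ones(10))


class TestCorrelate:
    def test_perfect_linear_gives_pearson_one(self):
        # seed chosen so both samples pass the Shapiro gate (a ~5% per-sample
        # false-reject rate is inherent to the gate)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        res = correlate(x, 2 * x + 1)
        assert res.method == "pearson"
        assert res.estimate == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_skewed_but_log_normalizable_takes_pearson_on_logs(self):
        """Both samples lognormal and log-linearly related: the gate takes
        the log branch and Pearson on the transformed values is exact."""
        rng = np.random.default_rng(4)
        x = np.exp(rng.standard_normal(15) * 2.0)
        res = correlate(x, x**3)
        assert res.method == "pearson"
        assert res.estimate == pytest.approx(1.0)

    def test_monotone_nonlinear_gives_spearman_one(self):
        """Cubing a symmetric sample breaks normality and (with negatives)
        the log branch, forcing the rank path; monotonicity gives ρ = 1."""
        rng = np.random.default_rng(14)
        x = rng.standard_normal(15)
        res = correlate(x, x**3)
        assert res.method == "spearman"
        assert res.estimate == pytest.approx(1.0)

    def test_printed_strength_pair_p_of_order_1e4(self):
        """A Pearson r of exactly 0.94 at n = 9 gives a two-tailed p on the
        order of 1e-4 (t-based)."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(9)
        e = rng.standard_normal(9)
        # orthogonalize and standardize so the sample r is exactly 0.94
        x = (x - x.mean()) / x.std()
        e = e - e.mean() - x * (e @ x) / (x @ x) * 1.0
        e = e / np.linalg.norm(e) * np.sqrt(len(x))
        y = 0.94 * x + np.sqrt(1 - 0.94**2) * e
        r, p = sps.pearsonr(x, y)
        assert r == pytest.approx(0.94, abs=1e-12)
        assert 1e-5 < p < 5e-4

    def test_pairwise_complete_and_minimum_n(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(8)
        y = 0.5 * x + rng.standard_normal(8)
        x[2], y[5] = np.nan, np.nan
        assert correlate(x, y).n == 6
        with pytest.raises(ValidationError, match="n=2"):
            correlate([1.0, np.nan, 3, 4], [np.nan, 2, 3, 4])


class TestSpearmanExact:
    def test_perfect_monotone_small_n(self):
        """For untied monotone data the exact two-tailed p is 2/n!."""
        x = np.arange(1.0, 6)
        rho, p = _spearman_exact_p(x, x**2)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_exact_matches_montecarlo_permutation(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(8)
        y = 0.7 * x + rng.standard_normal(8)
        rho, p_exact = _spearman_exact_p(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        draws = np.array([
            np.corrcoef(rx, rng.permutation(ry))[0, 1] for _ in range(20_000)
        ])
        p_mc = np.mean(np.abs(draws) >= abs(rho) - 1e-12)
        assert p_exact == pytest.approx(p_mc, abs=0.015)

    def test_ties_handled_with_midranks(self):
        x = np.array([1.0, 2, 2, 3, 4, 5])
        y = np.array([1.0, 1, 2, 3, 5, 5])
        rho, p = _spearman_exact_p(x, y)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic)
        assert 0 < p <= 1


class TestBhFdr:
    @staticmethod
    def _brute_force(p, q):
        """Literal step-up definition: largest k with p_(k) ≤ kq/m, and
        adjusted p_(i) = min_{j≥i} m p_(j)/j."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        for pos, i in enumerate(order):
            adj[i] = min(
                min(m * p[order[j]] / (j + 1) for j in range(pos, m)), 1.0
            )
        return adj, adj <= q

    def test_worked_example(self):
        adj, reject = bh_fdr([0.001, 0.02, 0.03, 0.04], q=0.05)
        np.testing.assert_allclose(adj, [0.004, 0.04, 0.04, 0.04])
        assert reject.all()

    def test_flat_and_singleton(self):
        adj, reject = bh_fdr([0.5] * 6)
        np.testing.assert_allclose(adj, 0.5)
        assert not reject.any()
        adj1, _ = bh_fdr([0.013])
        assert adj1[0] == pytest.approx(0.013)

    @pytest.mark.parametrize("m", [1, 2, 5, 10])
    def test_equals_bruteforce_and_statsmodels(self, m):
        rng = np.random.default_rng(m)
        for _ in range(200):
            p = rng.random(m)
            adj, reject = bh_fdr(p, q=0.05)
            adj_bf, reject_bf = self._brute_force(p, 0.05)
            np.testing.assert_allclose(adj, adj_bf, atol=1e-12)
            np.testing.assert_array_equal(reject, reject_bf)
            sm_reject, sm_adj, _, _ = multipletests(p, 0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, sm_adj, atol=1e-12)
            np.testing.assert_array_equal(reject, sm_reject)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(11)
        p = rng.random(10)
        adj, _ = bh_fdr(p)
        assert (adj >= p - 1e-15).all()


class TestPosthocPower:
    def test_null_effect_power_equals_alpha(self):
        assert posthoc_power(0.0, 20, alpha=0.05) == pytest.approx(0.05, abs=1e-4)
        assert posthoc_power(0.0, 20, method="fisher_z") == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_effect_and_n(self):
        grid_r = [0.1, 0.3, 0.5, 0.7, 0.9]
        powers = [posthoc_power(r, 15) for r in grid_r]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        grid_n = [6, 10, 20, 50]
        powers_n = [posthoc_power(0.4, n) for n in grid_n]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))

    def test_methods_converge_for_large_n(self):
        for r in (0.2, 0.5):
            assert posthoc_power(r, 400) == pytest.approx(
                posthoc_power(r, 400, method="fisher_z"), abs=0.01
            )

    def test_fisher_z_matches_montecarlo(self):
        """10,000 bivariate-normal samples (ρ=0.6, n=20): the simulated
        rejection rate agrees with the Fisher-z power within 0.02."""
        rng = np.random.default_rng(7)
        n, rho, reps = 20, 0.6, 10_000
        x = rng.standard_normal((reps, n))
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal((reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        crit = sps.t.ppf(0.975, n - 2)
        mc = np.mean(np.abs(t) > crit)
        # the z-approximation runs systematically low at this n (~0.02)
        assert posthoc_power(rho, n, method="fisher_z") == pytest.approx(mc, abs=0.025)
        assert posthoc_power(rho, n, method="exact") == pytest.approx(mc, abs=0.01)

    def test_guards(self):
        with pytest.raises(ValidationError):
            posthoc_power(0.5, 3)
        with pytest.raises(ValidationError):
            posthoc_power(1.0, 10)


class TestRunAnalysis:
    def test_family_enumeration(self):
        frame, _ = generate_cohort_frame(n_subjects=21, seed=8)
        res = run_analysis(frame)
        fams = set(res.table[~res.table["exploratory"]]["subgroup"])
        assert fams == {
            "cohort_injury",
            "cohort_integrity",
            "mild_moderate_injury",
            "severe_injury",
            "high_integrity",
            "low_integrity",
        }
        for fam in fams:
            sub = res.table[res.table["subgroup"] == fam]
            assert len(sub) == 48

    def test_planted_cell_found_and_annotated(self):
        cell = "SMA:extensor_digitorum:high_beta"
        frame, _ = generate_cohort_frame(
            n_subjects=21, planted={cell: 0.9}, seed=9
        )
        res = run_analysis(
            frame, families=(("cohort_injury", None, "cst_injury_pct"),)
        )
        t = res.table[~res.table["exploratory"]]
        best = t.loc[t["p_adj"].idxmin()]
        assert best["cell"] == cell
        if best["significant"]:
            assert 0 < best["power_exact"] <= 1
            assert not np.isnan(best["power_fisher_z"])
        # exploratory behavioral correlations are labelled as such
        expl = res.table[res.table["exploratory"]]
        assert set(expl["covariate"]) <= {"uefm", "arat"}
        assert np.isnan(expl["p_adj"]).all()

    def test_small_family_skipped(self):
        frame, _ = generate_cohort_frame(n_subjects=6, seed=10)
        res = run_analysis(frame, min_n=5)
        # the 3-subject half of each median split cannot support correlation
        assert len(res.skipped_families) >= 2

    def test_summary_mentions_counts(self):
        frame, _ = generate_cohort_frame(n_subjects=12, seed=12)
        res = run_analysis(frame)
        text = res.summary()
        assert "FDR level" in text and "significant" in text

    def test_frame_without_cells_rejected(self):
        with pytest.raises(ValidationError):
            CMCCorrelation(pd.DataFrame({"cst_injury_pct": [1.0, 2, 3, 4]}))
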