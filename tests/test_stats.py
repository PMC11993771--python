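"""noninferiority_stats: t-interval, Mann-Whitney, Shapiro-Wilk, power."""

from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from radioplan.errors import PairingError, StatsError
from radioplan.stats import (
    GroupSummary,
    mann_whitney_u,
    noninferiority_from_interval,
    paired_noninferiority,
    posthoc_power_mw,
    shapiro_wilk,
    study_table,
)


class TestPairedNoninferiority:
    def test_all_zero_differences(self):
        r = paired_noninferiority([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], margin=5.0)
        assert r.mean_diff == 0.0
        assert r.ci_lower == r.ci_upper == 0.0
        assert r.degenerate
        assert r.noninferior

    def test_closed_form_t_interval(self):
        # d = [1,2,3,4]: mean 2.5, sd 1.29099, t_3 = 3.18245
        r = paired_noninferiority([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0], margin=5.0)
        assert r.mean_diff == pytest.approx(2.5)
        assert r.ci_lower == pytest.approx(0.4457, abs=1e-3)
        assert r.ci_upper == pytest.approx(4.5542, abs=1e-3)
        # independent closed-form oracle to 1e-10
        d = np.array([1.0, 2.0, 3.0, 4.0])
        hw = sps.t.ppf(0.975, 3) * d.std(ddof=1) / sqrt(4)
        assert r.ci_lower == pytest.approx(d.mean() - hw, abs=1e-10)
        assert r.ci_upper == pytest.approx(d.mean() + hw, abs=1e-10)

    def test_uses_absolute_values(self):
        r1 = paired_noninferiority([-1.0, 2.0, -3.0], [1.0, -2.0, 3.0], margin=1.0)
        assert r1.mean_diff == 0.0

    def test_decision_rule(self):
        r = paired_noninferiority([3.0, 4.0, 5.0, 6.0], [1.0, 1.0, 1.0, 1.0], margin=5.0)
        assert r.noninferior == (r.ci_lower > -5.0)

    def test_monotone_in_margin(self):
        rng = np.random.default_rng(0)
        ec, suh = rng.normal(2, 1, 16), rng.normal(0.5, 1, 16)
        for m1, m2 in [(1.0, 2.0), (2.0, 5.0), (0.5, 10.0)]:
            r1 = paired_noninferiority(ec, suh, margin=m1)
            r2 = paired_noninferiority(ec, suh, margin=m2)
            if r1.noninferior:
                assert r2.noninferior

    def test_printed_summary_decisions(self):
        # decision logic applied to already-published interval summaries
        assert noninferiority_from_interval(2.3, 0.6, 4.0, margin=5.0)
        assert noninferiority_from_interval(0.38, 0.11, 0.66, margin=2.0)
        assert not noninferiority_from_interval(-6.0, -8.0, -4.0, margin=5.0)

    def test_type_one_error_at_boundary(self):
        # H0 boundary (mean difference = -margin): one-sided 0.025 test
        rng = np.random.default_rng(11)
        margin, n, reps = 5.0, 16, 10_000
        d = rng.normal(-margin, 3.0, size=(reps, n))
        mean = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        lo = mean - sps.t.ppf(0.975, n - 1) * sd / sqrt(n)
        rate = (lo > -margin).mean()
        assert 0.015 <= rate <= 0.035


class TestMannWhitney:
    def test_spec_example(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples(self):
        u, p = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0], mode="exact")
        assert p == 1.0

    def test_exact_matches_brute_force(self):
        # independent enumeration oracle for all n_a + n_b <= 10 cases drawn
        rng = np.random.default_rng(5)
        for n_a, n_b in [(2, 3), (3, 3), (4, 4), (5, 5), (3, 7)]:
            a = np.round(rng.normal(size=n_a), 1)
            b = np.round(rng.normal(size=n_b), 1)
            u, p = mann_whitney_u(a, b, mode="exact")
            ranks = sps.rankdata(np.concatenate([a, b]))
            n = n_a + n_b
            u_obs = min(
                ranks[:n_a].sum() - n_a * (n_a + 1) / 2,
                ranks[n_a:].sum() - n_b * (n_b + 1) / 2,
            )
            count = sum(
                1
                for idx in combinations(range(n), n_a)
                if ranks[list(idx)].sum() - n_a * (n_a + 1) / 2 <= u_obs + 1e-12
            )
            assert u == pytest.approx(u_obs)
            assert p == pytest.approx(min(1.0, 2 * count / comb(n, n_a)), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=6), rng.normal(size=6)
        _, p = mann_whitney_u(a, b, mode="exact")
        p_sp = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(p_sp, abs=1e-10)

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            a, b = rng.normal(size=7), rng.normal(0.5, 1, size=7)
            _, p_exact = mann_whitney_u(a, b, mode="exact")
            _, p_norm = mann_whitney_u(a, b, mode="normal_approx")
            assert abs(p_exact - p_norm) < 0.03

    def test_exact_size_limit(self):
        with pytest.raises(ValueError):
            mann_whitney_u(np.arange(8.0), np.arange(8.0), mode="exact")


class TestShapiroWilk:
    def test_linear_order_statistics_n3(self):
        w, _ = shapiro_wilk([-1.0, 0.0, 1.0])
        assert w == pytest.approx(1.0, abs=1e-6)

    def test_constant_input_raises(self):
        with pytest.raises(StatsError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])

    def test_bimodal_rejected(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-5, 0.3, 10), rng.normal(5, 0.3, 10)])
        _, p = shapiro_wilk(x)
        assert p < 0.01

    def test_type_one_error_calibration(self):
        # rejection rate at alpha = 0.05 for true normal samples of n = 20
        rng = np.random.default_rng(29)
        rejections = 0
        reps = 2000  # calibration at suite scale; 10k reps run in acceptance
        for _ in range(reps):
            _, p = shapiro_wilk(rng.normal(size=20))
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065


class TestPosthocPower:
    def test_null_effect_is_alpha_floor(self):
        a = GroupSummary(13, 1.0, 0.5)
        b = GroupSummary(18, 1.0, 0.5)
        assert posthoc_power_mw(a, b) == pytest.approx(0.05, abs=0.01)

    def test_monotone_in_effect(self):
        powers = [
            posthoc_power_mw(GroupSummary(13, 1.0 + d, 0.5), GroupSummary(18, 1.0, 0.5))
            for d in [0.0, 0.1, 0.2, 0.4, 0.8]
        ]
        assert all(p2 >= p1 for p1, p2 in zip(powers, powers[1:]))

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(StatsError):
            posthoc_power_mw(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0))

    def test_against_monte_carlo_simulation(self):
        # simulation oracle at the guide-QC group sizes; the approximation
        # must land within +-0.10 of simulated Mann-Whitney power
        a = GroupSummary(13, 0.085, 0.007)
        b = GroupSummary(18, 0.091, 0.013)
        approx = posthoc_power_mw(a, b, alpha=0.05)
        rng = np.random.default_rng(17)
        reps, hits = 10_000, 0
        for _ in range(reps):
            x = rng.normal(a.mean, a.sd, a.n)
            y = rng.normal(b.mean, b.sd, b.n)
            p = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
            hits += p < 0.05
        assert approx == pytest.approx(hits / reps, abs=0.10)


class TestStudyTable:
    def make_df(self, n=8, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = rng.normal(0, 2, 6)
            for arm in ("in_house", "external"):
                vals = base if identical else rng.normal(0, 2, 6)
                rows.append(
                    dict(
                        case_id=f"c{i}",
                        guide_arm=arm,
                        rot_x=vals[0],
                        rot_y=vals[1],
                        rot_z=vals[2],
                        trans_x=vals[3],
                        trans_y=vals[4],
                        trans_z=vals[5],
                    )
                )
        return pd.DataFrame(rows)

    def test_identical_arms_mean_diff_zero(self):
        summary, decisions = study_table(self.make_df(identical=True))
        assert decisions["rot_x"].mean_diff == 0.0
        assert decisions["rot_x"].noninferior
        assert decisions["trans_z"].noninferior

    def test_summary_shape_and_absolute_values(self):
        summary, _ = study_table(self.make_df())
        assert len(summary) == 12  # 6 parameters x 2 arms
        assert (summary["mean_abs"] >= 0).all()

    def test_folded_normal_summary_means(self):
        # arm errors ~ N(0, sigma): the absolute-value summary mean must sit
        # within 3 SE of the folded-normal mean sigma*sqrt(2/pi)
        rng = np.random.default_rng(2)
        n, sigma = 400, 2.0
        rows = []
        for i in range(n):
            for arm in ("in_house", "external"):
                v = rng.normal(0, sigma, 6)
                rows.append(
                    dict(case_id=f"c{i}", guide_arm=arm, rot_x=v[0], rot_y=v[1],
                         rot_z=v[2], trans_x=v[3], trans_y=v[4], trans_z=v[5])
                )
        summary, _ = study_table(pd.DataFrame(rows))
        expected = sigma * np.sqrt(2 / np.pi)
        se = sigma * np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        for m in summary["mean_abs"]:
            assert abs(m - expected) < 3 * se + 1e-9

    def test_missing_arm_raises_with_case_name(self):
        df = self.make_df(n=4)
        df = df[~((df.case_id == "c2") & (df.guide_arm == "external"))]
        with pytest.raises(PairingError, match="c2"):
            study_table(df)

    def test_missing_column_rejected(self):
        df = self.make_df().drop(columns=["rot_y"])
        with pytest.raises(ValueError, match="rot_y"):
            study_table(df)
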