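"""Cohort statistics: Spearman, WT normalization, Tobit, LMM/ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from aortaflow.stats import (
    last_measurement_per_mouse,
    lmm_anova,
    normalize_to_wt,
    spearman_by_group,
    tobit_fit,
)
from aortaflow.synthetic import CohortSpec, generate_cohort


def one_group(x, y):
    return pd.DataFrame({"sex": "M", "genotype": "MU", "x": x, "y": y})


class TestSpearman:
    def test_perfectly_increasing_pairs(self):
        out = spearman_by_group(one_group([1, 2, 3, 4, 5], [10, 20, 30, 40, 50]), "x", "y")
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_perfectly_decreasing_pairs(self):
        out = spearman_by_group(one_group([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]), "x", "y")
        assert out.r.iloc[0] == pytest.approx(-1.0)

    def test_tied_table_matches_rank_covariance_oracle(self):
        x = [1, 2, 3, 4, 5, 6, 7, 7.0]
        y = [2, 1, 4, 3, 6, 5, 8, 7.0]
        out = spearman_by_group(one_group(x, y), "x", "y")
        xr, yr = sps.rankdata(x), sps.rankdata(y)
        xc, yc = xr - xr.mean(), yr - yr.mean()
        oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert out.r.iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_matches_enumeration(self):
        x = [1.0, 2, 3, 4, 5, 6]
        y = [2.0, 1, 5, 3, 6, 4]
        out = spearman_by_group(one_group(x, y), "x", "y")
        xr, yr = sps.rankdata(x), sps.rankdata(y)
        xc, yc = xr - xr.mean(), yr - yr.mean()
        rho_obs = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        count = 0
        total = 0
        for perm in itertools.permutations(yc):
            rho = (np.array(perm) @ xc) / np.sqrt((xc @ xc) * (yc @ yc))
            count += abs(rho) >= abs(rho_obs) - 1e-12
            total += 1
        assert out.p.iloc[0] == pytest.approx(count / total, abs=1e-12)

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman_by_group(one_group(x, y), "x", "y")
        warped = spearman_by_group(one_group(np.exp(x), y**3), "x", "y")
        assert warped.r.iloc[0] == pytest.approx(base.r.iloc[0], abs=1e-12)
        assert warped.p.iloc[0] == pytest.approx(base.p.iloc[0], abs=1e-12)

    def test_zero_variance_flagged(self):
        out = spearman_by_group(one_group([1, 1, 1, 1], [1, 2, 3, 4]), "x", "y")
        assert out.flag.iloc[0] == "zero_variance"
        assert np.isnan(out.r.iloc[0])

    def test_small_groups_flagged_not_reported(self):
        out = spearman_by_group(one_group([1, 2], [2, 1]), "x", "y")
        assert out.flag.iloc[0] == "too_few"


class TestNormalizeToWT:
    @staticmethod
    def table():
        return pd.DataFrame(
            {
                "mouse_id": ["w1", "w2", "m1", "m2"],
                "sex": ["M"] * 4,
                "genotype": ["WT", "WT", "MU", "MU"],
                "age_mo": [2] * 4,
                "max_diameter_mm": [1.0, 1.2, 1.65, 1.1],
                "lifespan_days": [120.0] * 4,
                "censored": [1, 1, 0, 0],
            }
        )

    def test_mu_ratio_hand_computed(self):
        out = normalize_to_wt(self.table(), metrics=["max_diameter_mm"])
        # WT cell mean = 1.1; MU values 1.65 and 1.1 -> 1.5 and 1.0
        assert out.max_diameter_mm_wtnorm.tolist() == pytest.approx(
            [1.0 / 1.1, 1.2 / 1.1, 1.5, 1.0]
        )

    def test_wt_cell_means_are_exactly_one(self):
        out = normalize_to_wt(self.table(), metrics=["max_diameter_mm"])
        wt = out[out.genotype == "WT"]
        assert wt.max_diameter_mm_wtnorm.mean() == pytest.approx(1.0, abs=1e-12)

    def test_mu_value_equal_to_wt_mean_normalizes_to_one(self):
        t = self.table()
        t.loc[t.mouse_id == "m1", "max_diameter_mm"] = 1.1
        out = normalize_to_wt(t, metrics=["max_diameter_mm"])
        assert out.loc[out.mouse_id == "m1", "max_diameter_mm_wtnorm"].iloc[0] == (
            pytest.approx(1.0)
        )

    def test_missing_wt_cell_error_names_the_cell(self):
        t = self.table()
        t = t[t.genotype == "MU"]
        with pytest.raises(ValueError, match="age_mo=2"):
            normalize_to_wt(t, metrics=["max_diameter_mm"])

    def test_idempotent_when_wt_is_unity(self):
        t = self.table()
        t["max_diameter_mm"] = [1.0, 1.0, 1.5, 1.0]
        once = normalize_to_wt(t, metrics=["max_diameter_mm"])
        again = normalize_to_wt(
            once.drop(columns=["max_diameter_mm"]).rename(
                columns={"max_diameter_mm_wtnorm": "max_diameter_mm"}
            ),
            metrics=["max_diameter_mm"],
        )
        assert np.allclose(
            again.max_diameter_mm_wtnorm, once.max_diameter_mm_wtnorm
        )


def simulate_censored(rng, n=100, slope=-30.0, censor_q=0.7):
    x = rng.normal(1.5, 0.4, n)
    y = 150.0 + slope * x + rng.normal(0, 15.0, n)
    bound = np.quantile(y, censor_q)
    cens = y >= bound
    return np.where(cens, bound, y), cens, x


class TestTobit:
    def test_no_censoring_equals_ols(self, rng):
        x = rng.normal(size=60)
        y = 100.0 - 25.0 * x + rng.normal(0, 10, 60)
        res = tobit_fit(y, np.zeros(60, dtype=bool), x)
        ols = sps.linregress(x, y)
        assert res.slope == pytest.approx(ols.slope, abs=1e-6)
        assert res.intercept == pytest.approx(ols.intercept, abs=1e-6)

    def test_constant_predictor_gives_zero_slope_and_r2(self, rng):
        y = 100 + rng.normal(0, 10, 20)
        res = tobit_fit(y, np.zeros(20, dtype=bool), np.full(20, 2.0))
        assert res.slope == 0.0
        assert res.pseudo_r2 == 0.0

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            tobit_fit([120.0] * 10, [True] * 10, np.arange(10.0))

    def test_simulated_recovery_with_30_percent_censoring(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(40):
            y, cens, x = simulate_censored(rng, n=100, slope=-30.0, censor_q=0.7)
            res = tobit_fit(y, cens, x)
            hits += abs(res.slope - (-30.0)) <= 2 * res.se_slope
        assert hits >= 36  # ~95% nominal coverage of a 2 SE band

    def test_estimate_is_a_local_likelihood_maximum(self, rng):
        y, cens, x = simulate_censored(rng, n=80)
        res = tobit_fit(y, cens, x)
        from aortaflow.stats import _tobit_negll

        xm = x - x.mean()
        theta_hat = np.array(
            [res.intercept + res.slope * x.mean(), res.slope, np.log(res.scale)]
        )
        ll_hat = -_tobit_negll(theta_hat, xm, y, cens)
        for _ in range(50):
            pert = theta_hat + rng.normal(0, [1.0, 1.0, 0.05])
            assert -_tobit_negll(pert, xm, y, cens) <= ll_hat + 1e-9

    def test_slope_approaches_ols_as_censoring_vanishes(self, rng):
        x = rng.normal(1.5, 0.4, 150)
        y_full = 150.0 - 30.0 * x + rng.normal(0, 15.0, 150)
        ols = sps.linregress(x, y_full).slope
        diffs = []
        for q in (0.6, 0.7, 0.8, 0.9, None):  # None: censoring fraction 0
            bound = np.quantile(y_full, q) if q is not None else y_full.max() + 1.0
            cens = y_full >= bound
            res = tobit_fit(np.where(cens, bound, y_full), cens, x)
            diffs.append(abs(res.slope - ols))
        assert diffs[-1] < 1e-6
        assert diffs[-1] <= diffs[0] + 1e-9

    def test_pseudo_r2_in_unit_interval(self, rng):
        y, cens, x = simulate_censored(rng)
        res = tobit_fit(y, cens, x)
        assert 0.0 <= res.pseudo_r2 <= 1.0

    def test_null_metric_effect_ci_covers_zero(self):
        # cohorts generated with no metric-lifespan link: the recovered slope
        # should be indistinguishable from zero at nominal rate
        covered = 0
        n_seeds = 60
        for seed in range(n_seeds):
            t = generate_cohort(
                CohortSpec(
                    n_per_group=50, metric_effect=0.0, noise_sd=15.0,
                    baseline_lifespan_days=110.0, seed=seed,
                )
            )
            t = normalize_to_wt(t, metrics=["max_diameter_mm"])
            mu = last_measurement_per_mouse(t[t.genotype == "MU"])
            res = tobit_fit(
                mu.lifespan_days, mu.censored.astype(bool), mu.max_diameter_mm_wtnorm
            )
            lo, hi = res.slope_ci()
            covered += lo <= 0.0 <= hi
        assert covered / n_seeds >= 0.90


def balanced_table(rng, n_mice=3, genotype_shift=0.0, re_sd=0.0, center_within_mouse=False):
    rows = []
    i = 0
    for s in ["M", "F"]:
        for g in ["WT", "MU"]:
            for _ in range(n_mice):
                i += 1
                b = rng.normal(0, re_sd) if re_sd > 0 else 0.0
                resid = rng.normal(size=4)
                if center_within_mouse:
                    resid -= resid.mean()
                for j, a in enumerate([1, 2, 3, 4]):
                    rows.append(
                        dict(
                            mouse_id=f"m{i}", age_mo=a, sex=s, genotype=g,
                            y=0.1 * a + (genotype_shift if g == "MU" else 0.0)
                            + b + resid[j],
                        )
                    )
    return pd.DataFrame(rows)


class TestLMMAnova:
    def test_matches_classical_anova_when_re_variance_is_zero(self, rng):
        # within-mouse centered residuals force the REML variance component
        # to its zero boundary; Wald F must then equal classical three-way
        # ANOVA (balanced design, Type II = III under sum coding)
        df = balanced_table(rng, genotype_shift=1.0, center_within_mouse=True)
        res = lmm_anova(df, "y")
        assert res.re_variance < 1e-6
        ols = smf.ols(
            "y ~ C(age_mo, Sum)*C(sex, Sum)*C(genotype, Sum)",
            df.assign(age_mo=df.age_mo.astype(str)),
        ).fit()
        f_oracle = anova_lm(ols, typ=2)["F"].dropna()
        for term, f in zip(res.anova.term, res.anova.F):
            assert f == pytest.approx(f_oracle[term], abs=1e-6, rel=1e-6)

    def test_large_genotype_shift_detected(self):
        detections = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            df = balanced_table(rng, n_mice=10, genotype_shift=5.0, re_sd=0.5)
            res = lmm_anova(df, "y")
            geno = res.anova[res.anova.term.str.fullmatch(r"C\(genotype, Sum\)")]
            detections += (
                geno.p.iloc[0] < 0.001
                and geno.F.iloc[0] == res.anova.F.max()
            )
        assert detections >= 19

    def test_null_p_values_roughly_uniform(self):
        pvals = []
        for seed in range(120):
            rng = np.random.default_rng(7000 + seed)
            df = balanced_table(rng, n_mice=3, re_sd=0.3)
            res = lmm_anova(df, "y")
            pvals.extend(res.anova.p.tolist())
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 <= frac <= 0.09

    def test_contrast_set_and_unestimable_flagging(self, rng):
        df = balanced_table(rng, genotype_shift=2.0, re_sd=0.2)
        df = df[~((df.genotype == "MU") & (df.sex == "F") & (df.age_mo == 4))]
        res = lmm_anova(df, "y")
        c = res.contrasts
        # genotype-within-sex-x-age and sex-within-genotype-x-age families
        assert len(c[c.contrast.str.startswith("genotype")]) == 8
        assert len(c[c.contrast.str.startswith("sex")]) == 8
        dropped = c[(c.get("sex") == "F") & (c.age_mo == "4") & c.contrast.str.startswith("genotype")]
        assert (dropped.flag == "unestimable").all()
        ok = c[c.flag == "ok"]
        assert np.isfinite(ok.estimate).all() and np.isfinite(ok.p).all()

    def test_genotype_contrast_estimates_the_shift(self, rng):
        df = balanced_table(rng, n_mice=8, genotype_shift=3.0, re_sd=0.2)
        res = lmm_anova(df, "y")
        geno = res.contrasts[res.contrasts.contrast.str.startswith("genotype")]
        assert geno[geno.flag == "ok"].estimate.mean() == pytest.approx(3.0, abs=0.5)
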