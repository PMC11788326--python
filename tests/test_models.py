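"""Within/between centering, mixed-model fits, ICC, R², correlations, power."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wearpa import models, synthetic


class TestCentering:
    def test_single_person_daily_deviations(self):
        g = pd.Series(["a", "a", "a"])
        daily, overall = models.center_within_between(pd.Series([2.0, 4.0, 6.0]), g)
        assert daily.tolist() == [-2.0, 0.0, 2.0]
        assert overall.tolist() == [0.0, 0.0, 0.0]

    def test_two_person_between_centering(self):
        g = pd.Series(["a", "a", "b", "b"])
        daily, overall = models.center_within_between(pd.Series([3.0, 5.0, 5.0, 7.0]), g)
        assert overall.tolist() == [-1.0, -1.0, 1.0, 1.0]

    def test_unbalanced_panel_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        g = pd.Series(np.repeat(list("abcd"), [3, 7, 2, 8]))
        x = pd.Series(rng.normal(10, 4, len(g)))
        daily, overall = models.center_within_between(x, g)
        person_means = {k: x[g == k].mean() for k in "abcd"}
        grand = np.mean(list(person_means.values()))  # unweighted
        for i in range(len(g)):
            assert daily[i] == pytest.approx(x[i] - person_means[g[i]])
            assert overall[i] == pytest.approx(person_means[g[i]] - grand)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=4, max_size=24))
    def test_reconstruction_and_zero_sum(self, vals):
        g = pd.Series(np.repeat(["a", "b"], [len(vals) // 2, len(vals) - len(vals) // 2]))
        x = pd.Series(vals, dtype=float)
        daily, overall = models.center_within_between(x, g)
        person_mean = x.groupby(g).transform("mean")
        assert np.allclose(daily + person_mean, x)
        assert abs(daily.groupby(g).sum()).max() < 1e-6 * max(1.0, abs(x).max())


@pytest.fixture(scope="module")
def panel():
    table, truth = synthetic.simulate_panel(seed=123)
    return table, truth


class TestFit:
    def test_recovers_planted_slope_direction_and_scale(self, panel):
        table, truth = panel
        res = models.fit_random_intercept(table, "lpa_out_min")
        est = res.fixed.loc["tmean_daily"]
        assert est["ci_low"] < 2.33 < est["ci_high"]
        assert res.sigma2 > 0 and res.tau00 > 0
        assert res.n_persons == 40 and res.n_obs == 400

    def test_zero_variance_outcome_is_flagged_degenerate(self, panel):
        table, _ = panel
        t = table.copy()
        t["flat"] = 5.0
        res = models.fit_random_intercept(t, "flat")
        assert res.singular
        assert res.sigma2 == 0.0
        assert (res.fixed.drop(index="Intercept")["estimate"] == 0).all()

    def test_result_table_has_published_layout_rows(self, panel):
        table, _ = panel
        res = models.fit_random_intercept(table, "walk_out_min")
        frame = res.to_frame()
        for v in models.WEATHER_PAIRS:
            assert f"{v}_daily" in frame.index and f"{v}_overall" in frame.index
        for term in ("freeze_thaw", "tropical_night", "study_day", "age_c",
                     "sex_female", "health_c", "weekend"):
            assert term in frame.index
        for meta in ("sigma2", "tau00_id", "n_id", "observations",
                     "r2_marginal", "r2_conditional"):
            assert meta in frame.index

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript + lme4")
    def test_fixed_effects_match_lme4_reference(self, panel, tmp_path):
        table, _ = panel
        design, _ = models.build_design(table, "lpa_out_min")
        csv = tmp_path / "design.csv"
        design.to_csv(csv, index=False)
        rhs = " + ".join(models.DEFAULT_PREDICTORS)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(lpa_out_min ~ {rhs} + (1 | participant_id), data = d, REML = TRUE)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            out <- data.frame(term = names(fe), estimate = as.numeric(fe))
            write.csv(out, "{tmp_path}/fe.csv", row.names = FALSE)
            write.csv(data.frame(tau00 = vc$vcov[1], sigma2 = vc$vcov[2]),
                      "{tmp_path}/vc.csv", row.names = FALSE)
        """))
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True, capture_output=True)
        fe = pd.read_csv(tmp_path / "fe.csv").set_index("term")["estimate"]
        vc = pd.read_csv(tmp_path / "vc.csv")
        res = models.fit_random_intercept(table, "lpa_out_min")
        ours = res.fixed["estimate"]
        ref = pd.concat([pd.Series({"Intercept": fe["(Intercept)"]}), fe.drop("(Intercept)")])
        scale = float(np.std(design["lpa_out_min"]))
        assert np.allclose(ours.to_numpy(), ref.reindex(ours.index).to_numpy(),
                           rtol=1e-4, atol=1e-4 * scale)
        assert res.sigma2 == pytest.approx(float(vc["sigma2"].iloc[0]), rel=1e-3)
        assert res.tau00 == pytest.approx(float(vc["tau00"].iloc[0]), rel=1e-3)


class TestIcc:
    def test_equal_variances_give_half(self):
        rng = np.random.default_rng(2)
        n_p, n_d = 200, 50
        u = rng.normal(0, 1, n_p)
        y = u[np.repeat(np.arange(n_p), n_d)] + rng.normal(0, 1, n_p * n_d)
        t = pd.DataFrame({"participant_id": np.repeat(np.arange(n_p), n_d), "y": y})
        assert models.compute_icc(t, "y") == pytest.approx(0.5, abs=0.03)

    def test_no_between_variance_gives_zero(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(
            {"participant_id": np.repeat(np.arange(30), 10), "y": rng.normal(0, 1, 300)}
        )
        assert models.compute_icc(t, "y") == pytest.approx(0.0, abs=0.02)

    def test_planted_icc_recovered_at_study_size(self):
        rng = np.random.default_rng(4)
        n_p, n_d, icc = 40, 10, 0.40
        u = rng.normal(0, np.sqrt(icc), n_p)
        y = u[np.repeat(np.arange(n_p), n_d)] + rng.normal(0, np.sqrt(1 - icc), n_p * n_d)
        t = pd.DataFrame({"participant_id": np.repeat(np.arange(n_p), n_d), "y": y})
        est = models.compute_icc(t, "y")
        assert abs(est - icc) < 0.08
        assert 0.0 <= est <= 1.0


class TestR2:
    def test_zero_fixed_variance(self):
        m, c = models.compute_r2(sigma2=3.0, tau00=1.0, fixed_effect_variance=0.0)
        assert m == 0.0 and c == pytest.approx(0.25)  # conditional equals the ICC

    def test_zero_between_variance_collapses(self):
        m, c = models.compute_r2(sigma2=2.0, tau00=0.0, fixed_effect_variance=1.0)
        assert m == c

    def test_matches_independent_formula_on_fit(self, panel):
        table, _ = panel
        design, _ = models.build_design(table, "lpa_out_min")
        res = models.fit_random_intercept(table, "lpa_out_min")
        # independent evaluation of the variance-partition formula
        X = np.column_stack(
            [np.ones(len(design))] + [design[p].to_numpy() for p in models.DEFAULT_PREDICTORS]
        )
        beta = res.fixed["estimate"].to_numpy()
        vf = np.var(X @ beta, ddof=1)
        denom = vf + res.tau00 + res.sigma2
        assert res.r2_marginal == pytest.approx(vf / denom, abs=1e-10)
        assert res.r2_conditional == pytest.approx((vf + res.tau00) / denom, abs=1e-10)
        assert res.r2_marginal <= res.r2_conditional


class TestPersonCorrelation:
    def test_perfectly_linear_is_one(self):
        t = pd.DataFrame(
            {"participant_id": np.repeat(np.arange(20), 3),
             "x": np.repeat(np.arange(20.0), 3),
             "y": np.repeat(2.0 * np.arange(20.0) + 1.0, 3)}
        )
        r, p = models.person_level_correlation(t, "x", "y")
        assert r == pytest.approx(1.0)

    def test_null_simulation_keeps_r_small(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(200):
            t = pd.DataFrame(
                {"participant_id": np.arange(40),
                 "x": rng.normal(size=40), "y": rng.normal(size=40)}
            )
            r, _ = models.person_level_correlation(t, "x", "y")
            hits += abs(r) < 0.32
        assert hits >= 190  # >= 95 % of null replicates

    def test_point_biserial_sign_matches_planted_shift(self):
        rng = np.random.default_rng(6)
        grp = np.repeat([0, 1], 20)
        y = rng.normal(0, 1, 40) + 0.5 * grp  # d = 0.5 upward shift
        signs = []
        for _ in range(30):
            y = rng.normal(0, 1, 40) + 0.5 * grp
            t = pd.DataFrame({"participant_id": np.arange(40), "g": grp, "y": y})
            r, _ = models.person_level_correlation(t, "g", "y", kind="point_biserial")
            signs.append(r > 0)
        assert np.mean(signs) > 0.8


class TestPower:
    def test_huge_effect_is_always_detected(self):
        pw = models.power_simulation(5.0, "within", 40, 10, icc=0.4, reps=40, seed=0)
        assert pw >= 0.99

    def test_power_monotone_in_effect_size(self):
        grid = [0.0, 0.1, 0.25, 0.6]
        pws = [
            models.power_simulation(e, "within", 30, 8, icc=0.4, reps=120, seed=1) for e in grid
        ]
        assert all(b >= a - 0.05 for a, b in zip(pws, pws[1:]))
        assert pws[-1] > 0.9

    def test_between_level_needs_larger_effects(self):
        within = models.power_simulation(0.3, "within", 30, 8, icc=0.4, reps=100, seed=2)
        between = models.power_simulation(0.3, "between", 30, 8, icc=0.4, reps=100, seed=2)
        assert within > between
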