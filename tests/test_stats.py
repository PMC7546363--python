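import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from gazehmm import LmmSpec, center_covariate, fit_lmm, run_all_models
from gazehmm.stats import all_model_specs, group_effect_pretest
from gazehmm.types import ValidationError


def synth_table(seed=0, group_effect=0.0, cov_slope=0.0, tau=1.0,
                sigma=1.0, sizes=(25, 15, 12), variable="transition_count",
                category="face_face", mean=8.0):
    """Variable-table rows (plus covariate rows) with known structure.

    ``group_effect`` shifts the ASD_ADHD group; the covariate rows carry a
    planted linear effect of ``cov_slope`` on the response.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for g, size in zip(("TD", "ASD_ADHD", "ASD"), sizes):
        for _ in range(size):
            pid += 1
            b = rng.normal(0.0, tau)
            for stim, act in (("A1", "four_actor"), ("A2", "four_actor"),
                              ("B1", "one_actor"), ("B2", "one_actor")):
                cov = rng.normal(300.0, 30.0)
                v = mean + b + rng.normal(0.0, sigma) \
                    + cov_slope * (cov - 300.0) \
                    + (group_effect if g == "ASD_ADHD" else 0.0)
                base = {"participant": f"P{pid:03d}", "group": g,
                        "stimulus": stim, "actors": act}
                rows.append({**base, "variable": variable,
                             "category": category, "value": v})
                rows.append({**base, "variable": "total_transitions",
                             "category": "all", "value": cov})
                rows.append({**base, "variable": "total_fixation_duration",
                             "category": "all", "value": cov / 3.0})
    return pd.DataFrame(rows)


class TestCenterCovariate:
    def test_constant_column_centres_to_zero(self):
        df = pd.DataFrame({"covariate": [300.0, 300.0, 300.0]})
        out = center_covariate(df, "covariate")
        np.testing.assert_allclose(out["covariate"], 0.0, atol=1e-10)

    def test_two_values(self):
        df = pd.DataFrame({"covariate": [290.0, 310.0]})
        out = center_covariate(df, "covariate")
        assert out["covariate"].tolist() == [-10.0, 10.0]

    def test_idempotent(self):
        df = pd.DataFrame({"covariate": [1.0, 2.0, 6.0]})
        once = center_covariate(df, "covariate")
        twice = center_covariate(once, "covariate")
        pd.testing.assert_frame_equal(once, twice)
        assert abs(once["covariate"].mean()) < 1e-10

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"covariate": [1.0, np.nan]})
        with pytest.raises(ValidationError):
            center_covariate(df, "covariate")


class TestFitLmm:
    def test_planted_group_effect_detected(self):
        table = synth_table(seed=1, group_effect=-2.0, tau=0.8, sigma=0.8)
        r = fit_lmm(table, LmmSpec("transition_count", "face_face",
                                   "total_transitions"))
        assert r.contrasts[("TD", "ASD_ADHD")][2] < 0.01
        assert r.contrasts[("TD", "ASD_ADHD")][0] == pytest.approx(-2.0,
                                                                   abs=0.8)
        assert r.contrasts[("TD", "ASD")][2] > 0.05

    def test_contrasts_equal_group_mean_differences_when_balanced(self):
        # no covariate, huge residual-free design: estimated marginal
        # means reduce to raw group means
        rng = np.random.default_rng(5)
        rows = []
        for gi, g in enumerate(("TD", "ASD_ADHD")):
            for p in range(8):
                for stim, act in (("A1", "four_actor"), ("B1", "one_actor")):
                    rows.append({"participant": f"{g}{p}", "group": g,
                                 "stimulus": stim, "actors": act,
                                 "variable": "transition_probability",
                                 "category": "face_face",
                                 "value": 10.0 * gi + rng.normal(0, 0.5)})
        table = pd.DataFrame(rows)
        r = fit_lmm(table, LmmSpec("transition_probability", "face_face",
                                   None))
        raw_diff = (table[table.group == "ASD_ADHD"].value.mean()
                    - table[table.group == "TD"].value.mean())
        assert r.contrasts[("TD", "ASD_ADHD")][0] == pytest.approx(
            raw_diff, abs=1e-6)
        em = r.emmeans
        assert em["ASD_ADHD"][0] - em["TD"][0] == pytest.approx(
            r.contrasts[("TD", "ASD_ADHD")][0], abs=1e-10)

    def test_covariate_slope_recovered(self):
        table = synth_table(seed=3, cov_slope=1.0, tau=0.5, sigma=0.5)
        wide = None
        from gazehmm.stats import pivot_for_model
        spec = LmmSpec("transition_count", "face_face", "total_transitions")
        r = fit_lmm(table, spec)
        # recover the slope directly from the fitted fixed effects
        import statsmodels.formula.api as smf
        wide = pivot_for_model(table, spec)
        wide = center_covariate(wide, "covariate")
        res = smf.mixedlm("value ~ C(group, Treatment('TD')) * C(actors)"
                          " + covariate", wide,
                          groups=wide["participant"]).fit()
        assert res.fe_params["covariate"] == pytest.approx(1.0, abs=0.1)
        assert r.converged

    def test_result_invariant_to_row_order(self):
        table = synth_table(seed=7, group_effect=-1.0)
        spec = LmmSpec("transition_count", "face_face", "total_transitions")
        r1 = fit_lmm(table, spec)
        shuffled = table.sample(frac=1.0, random_state=0)
        r2 = fit_lmm(shuffled, spec)
        assert r1.f_group == pytest.approx(r2.f_group, rel=1e-8)
        assert r1.contrasts[("TD", "ASD_ADHD")][0] == pytest.approx(
            r2.contrasts[("TD", "ASD_ADHD")][0], rel=1e-8)

    def test_centering_does_not_change_group_f(self):
        table = synth_table(seed=9, group_effect=-1.5)
        spec = LmmSpec("transition_count", "face_face", "total_transitions")
        r1 = fit_lmm(table, spec)
        shifted = table.copy()
        mask = shifted["variable"] == "total_transitions"
        shifted.loc[mask, "value"] += 1000.0   # centering removes any shift
        r2 = fit_lmm(shifted, spec)
        assert r1.f_group == pytest.approx(r2.f_group, rel=1e-6)

    def test_single_group_rejected(self):
        table = synth_table(sizes=(10, 0, 0))
        with pytest.raises(ValidationError):
            fit_lmm(table, LmmSpec("transition_count", "face_face",
                                   "total_transitions"))

    def test_probability_spec_forbids_covariate(self):
        with pytest.raises(ValueError):
            LmmSpec("transition_probability", "face_face",
                    "total_transitions")
        with pytest.raises(ValueError):
            LmmSpec("transition_count", "face_face", None)


class TestRunAllModels:
    def test_sixteen_models_reported(self):
        specs = all_model_specs()
        assert len(specs) == 16
        assert sum(s.covariate is None for s in specs) == 5

    def test_full_report_shape_on_synthetic_table(self):
        # all 16 variables present, single response value pattern
        frames = []
        for spec in all_model_specs():
            frames.append(synth_table(seed=11, variable=spec.variable,
                                      category=spec.category)
                          [lambda d: d["variable"] == spec.variable])
        base = synth_table(seed=11)
        cov_rows = base[base["variable"].isin(
            ["total_transitions", "total_fixation_duration"])]
        table = pd.concat(frames + [cov_rows], ignore_index=True)
        report = run_all_models(table)
        assert len(report) == 16
        assert report["converged"].all()
        assert report["p_TD_vs_ASD_ADHD"].between(0, 1).all()

    def test_pretest_runs_on_covariates(self):
        table = synth_table(seed=13)
        F, p = group_effect_pretest(table, "total_transitions")
        assert np.isfinite(F) and 0 <= p <= 1


def test_fixed_effects_match_lme4_reference():
    """Cross-check the mixed-model fixed effects against R lme4 (REML)."""
    from shutil import which
    if which("Rscript") is None:
        pytest.skip("Rscript not available")
    table = synth_table(seed=21, group_effect=-1.0, tau=1.0, sigma=0.7,
                        sizes=(12, 10, 8))
    from gazehmm.stats import pivot_for_model
    spec = LmmSpec("transition_count", "face_face", "total_transitions")
    wide = center_covariate(pivot_for_model(table, spec), "covariate")
    import tempfile, os, json
    with tempfile.TemporaryDirectory() as td:
        csv = os.path.join(td, "d.csv")
        wide.to_csv(csv, index=False)
        rcode = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$group <- relevel(factor(d$group), ref = "TD")
            d$actors <- factor(d$actors)
            m <- lmer(value ~ group * actors + covariate + (1|participant),
                      data = d, REML = TRUE)
            cat(jsonlite::toJSON(as.list(fixef(m)), digits = 12))
        """)
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=300)
        if out.returncode != 0:
            pytest.skip(f"Rscript failed: {out.stderr[-200:]}")
        ref = {k: v[0] for k, v in json.loads(out.stdout).items()}
    import statsmodels.formula.api as smf
    res = smf.mixedlm("value ~ C(group, Treatment('TD')) * C(actors)"
                      " + covariate", wide, groups=wide["participant"]
                      ).fit(reml=True)
    ours = res.fe_params
    assert ours["Intercept"] == pytest.approx(ref["(Intercept)"], abs=1e-4)
    assert ours["covariate"] == pytest.approx(ref["covariate"], abs=1e-6)
    got_g = [v for k, v in ours.items()
             if "group" in k and "actors" not in k]
    ref_g = [v for k, v in ref.items()
             if k.startswith("group") and ":" not in k]
    np.testing.assert_allclose(sorted(got_g), sorted(ref_g), atol=1e-4)
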