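import shutil
import subprocess
import textwrap

import numpy as np
import pytest

import etawithin as ew
from etawithin import CodingScheme, RandomSpec
from etawithin.classical import t_independent
from etawithin.mixed import (
    effect_report, eta2w_lmm, fit_lmm, marginal_r2, satterthwaite_df,
    semipartial_r2,
)
from etawithin.simulate import SimSpec, simulate_crossed
from .conftest import participant_means


@pytest.fixture(scope="module")
def wm_dummy_fit(wm_between):
    return fit_lmm(wm_between, ["group"], [RandomSpec("participant")],
                   CodingScheme("dummy"))


class TestRandomInterceptOnly:
    """Between-groups data, two measurements per participant: the LME
    reduces to the classical two-group analysis."""

    @pytest.fixture()
    def fit(self, wm_dummy_fit):
        return wm_dummy_fit

    def test_dummy_estimates_are_reference_mean_and_difference(self, fit):
        est = fit.fixed.set_index("term")["estimate"]
        assert est["(Intercept)"] == pytest.approx(39.5, abs=1e-6)
        assert est["group"] == pytest.approx(-5.0, abs=1e-6)

    def test_deviation_intercept_is_grand_mean(self, wm_between):
        fit = fit_lmm(wm_between, ["group"], [RandomSpec("participant")],
                      CodingScheme("deviation"))
        est = fit.fixed.set_index("term")["estimate"]
        assert est["(Intercept)"] == pytest.approx(37.0, abs=1e-6)
        assert est["group"] == pytest.approx(-5.0, abs=1e-6)

    def test_intercept_sd(self, fit):
        assert fit.components["participant"]["sd"]["1"] == pytest.approx(
            10.957, abs=5e-4)

    def test_t_and_df_match_classical_t_test(self, fit, wm_between):
        pm = participant_means(wm_between, "group")
        classical = t_independent(pm["65yr"].dropna(), pm["75yr"].dropna(),
                                  variant="student")
        row = fit.fixed.set_index("term").loc["group"]
        assert row["t"] == pytest.approx(-classical.t, abs=5e-4)
        assert satterthwaite_df(fit, "group") == pytest.approx(18.0, abs=0.02)

    def test_marginal_r2(self, fit):
        assert marginal_r2(fit) == pytest.approx(0.0498, abs=5e-5)


class TestRandomSlopes:
    def test_longitudinal_t_matches_paired_t(self, wm_longitudinal):
        fit = fit_lmm(wm_longitudinal, ["age"],
                      [RandomSpec("participant", ("1", "age"))],
                      CodingScheme("deviation"))
        row = fit.fixed.set_index("term").loc["age"]
        assert row["t"] == pytest.approx(-3.23, abs=0.01)
        assert satterthwaite_df(fit, "age") == pytest.approx(9.0, abs=0.05)
        assert marginal_r2(fit) == pytest.approx(0.0230, abs=5e-5)

    def test_lme4_cross_check(self, wm_longitudinal, tmp_path):
        """Independent oracle: lme4/lmerTest (via Rscript) on the same
        model reproduces our fixed estimates, SEs and variance components."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lme4 cross-check")
        csv = tmp_path / "long.csv"
        wm_longitudinal.data.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$age <- ifelse(d$age == "yr75", .5, -.5)
            m <- lmer(score ~ age + (1 + age | participant), data=d, REML=TRUE)
            fe <- fixef(m); se <- sqrt(diag(vcov(m)))
            vc <- as.data.frame(VarCorr(m))
            cat(fe[1], fe[2], se[2], vc$sdcor[vc$var1 == "(Intercept)" & vc$grp == "participant"][1],
                sigma(m), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-"], input=script, text=True,
                             capture_output=True, check=True).stdout.split()
        r_int, r_age, r_se, r_sd, r_sigma = map(float, out)
        fit = fit_lmm(wm_longitudinal, ["age"],
                      [RandomSpec("participant", ("1", "age"))],
                      CodingScheme("deviation"))
        est = fit.fixed.set_index("term")
        assert est.loc["(Intercept)", "estimate"] == pytest.approx(r_int, rel=1e-5)
        assert est.loc["age", "estimate"] == pytest.approx(r_age, rel=1e-5)
        assert est.loc["age", "SE"] == pytest.approx(r_se, rel=1e-3)
        assert fit.components["participant"]["sd"]["1"] == pytest.approx(
            r_sd, rel=1e-3)
        assert fit.residual_sd == pytest.approx(r_sigma, rel=1e-3)


class TestTwoByTwo:
    def test_fixed_estimates_exact(self, twobytwo_fit):
        est = twobytwo_fit.fixed["estimate"].to_numpy()
        assert np.allclose(est, [5.275, 0.400, 0.150, -2.000], atol=1e-6)

    def test_standard_errors(self, twobytwo_fit):
        se = twobytwo_fit.fixed.set_index("term")["SE"]
        assert se["(Intercept)"] == pytest.approx(0.493, abs=1e-3)
        assert se["day"] == pytest.approx(0.357, abs=1e-3)
        assert se["stimulus_type"] == pytest.approx(0.291, abs=1e-3)
        assert se["day:stimulus_type"] == pytest.approx(0.687, abs=1e-3)

    def test_satterthwaite_dfs(self, twobytwo_fit):
        assert satterthwaite_df(twobytwo_fit, "day") == pytest.approx(9.18, abs=0.05)
        assert satterthwaite_df(twobytwo_fit, "stimulus_type") == pytest.approx(14.07, abs=0.1)
        assert satterthwaite_df(twobytwo_fit, "day:stimulus_type") == pytest.approx(9.01, abs=0.05)

    def test_random_components(self, twobytwo_fit):
        sds = twobytwo_fit.components["participant"]["sd"]
        assert sds["1"] == pytest.approx(1.511, abs=2e-3)
        assert sds["day"] == pytest.approx(0.835, abs=2e-3)
        assert sds["stimulus_type"] == pytest.approx(0.522, abs=2e-3)
        assert sds["day:stimulus_type"] == pytest.approx(1.556, abs=2e-3)
        assert twobytwo_fit.residual_sd == pytest.approx(1.073, abs=2e-3)

    def test_marginal_r2(self, twobytwo_fit):
        assert marginal_r2(twobytwo_fit) == pytest.approx(0.0725, abs=5e-5)

    def test_eta2w_centered_refit(self, twobytwo):
        vals = eta2w_lmm(
            twobytwo, ["day", "stimulus_type", "day:stimulus_type"],
            [RandomSpec("participant",
                        ("1", "day", "stimulus_type", "day:stimulus_type"))],
            "participant")
        assert vals["day"] == pytest.approx(0.0237, abs=5e-4)
        assert vals["stimulus_type"] == pytest.approx(0.0033, abs=5e-4)
        assert vals["day:stimulus_type"] == pytest.approx(0.1480, abs=1e-3)
        assert sum(vals.values()) == pytest.approx(0.175, abs=2e-3)

    @pytest.mark.parametrize("kind", ["sum", "deviation", "dummy"])
    def test_marginal_r2_coding_invariant(self, twobytwo, kind):
        fit = fit_lmm(twobytwo, ["day", "stimulus_type", "day:stimulus_type"],
                      [RandomSpec("participant",
                                  ("1", "day", "stimulus_type",
                                   "day:stimulus_type"))],
                      CodingScheme(kind))
        assert marginal_r2(fit) == pytest.approx(0.0725, abs=2e-4)

    def test_semipartial_invariant_sum_vs_deviation(self, twobytwo, twobytwo_fit):
        fit_sum = fit_lmm(twobytwo,
                          ["day", "stimulus_type", "day:stimulus_type"],
                          [RandomSpec("participant",
                                      ("1", "day", "stimulus_type",
                                       "day:stimulus_type"))],
                          CodingScheme("sum"))
        sp_dev = semipartial_r2(twobytwo_fit)
        sp_sum = semipartial_r2(fit_sum)
        for term in sp_dev:
            assert sp_sum[term] == pytest.approx(sp_dev[term], abs=2e-4)

    def test_dummy_coding_pitfall(self, twobytwo):
        """With dummy coding the 'main effects' are simple effects at the
        other factor's reference level and turn significant, while the
        centered codings correctly find no main effects; the interaction
        test is unaffected."""
        fixed = ["day", "stimulus_type", "day:stimulus_type"]
        rs = [RandomSpec("participant",
                         ("1", "day", "stimulus_type", "day:stimulus_type"))]
        dummy = effect_report(twobytwo, fixed, rs, CodingScheme("dummy"),
                              center_by="participant").table.set_index("term")
        dev = effect_report(twobytwo, fixed, rs, CodingScheme("deviation"),
                            center_by="participant").table.set_index("term")
        assert dummy.loc["day", "p"] < 0.05
        assert dummy.loc["stimulus_type", "p"] < 0.05
        assert dev.loc["day", "p"] > 0.25
        assert dev.loc["stimulus_type", "p"] > 0.5
        assert dummy.loc["day:stimulus_type", "p"] == pytest.approx(
            dev.loc["day:stimulus_type", "p"], abs=1e-3)
        assert round(dev.loc["day:stimulus_type", "p"], 3) == 0.017


class TestCrossedRandomEffects:
    def test_faces_combined(self, faces_fit):
        row = faces_fit.fixed.set_index("term").loc["age"]
        assert abs(row["t"]) == pytest.approx(1.549, abs=3e-3)
        df = satterthwaite_df(faces_fit, "age")
        assert df == pytest.approx(14.0, abs=0.2)
        from scipy import stats
        p = 2 * stats.t.sf(abs(row["t"]), df)
        assert p == pytest.approx(0.144, abs=3e-3)

    def test_faces_effect_sizes(self, faces_fit, faces):
        assert semipartial_r2(faces_fit)["age"] == pytest.approx(0.032, abs=5e-4)
        rs = [RandomSpec("participant"), RandomSpec("stimulus", ("1", "age"))]
        w = eta2w_lmm(faces, ["age"], rs, "stimulus")
        assert w["age"] == pytest.approx(0.053, abs=1e-3)

    def test_faces_between_participant_effect_has_no_participant_eta2w(self, faces):
        rs = [RandomSpec("participant"), RandomSpec("stimulus", ("1", "age"))]
        w = eta2w_lmm(faces, ["age"], rs, "participant")
        assert w["age"] is None

    def test_reading_combined(self, reading_fit):
        row = reading_fit.fixed.set_index("term").loc["language:background"]
        assert row["estimate"] == pytest.approx(-3.883, abs=1e-3)
        assert row["t"] == pytest.approx(-1.620, abs=5e-3)
        assert satterthwaite_df(
            reading_fit, "language:background") == pytest.approx(18.7, abs=0.15)

    def test_reading_effect_sizes(self, reading_fit, reading):
        sp = semipartial_r2(reading_fit)
        assert sp["language"] == pytest.approx(0.0411, abs=1e-3)
        assert sp["background"] == pytest.approx(0.1193, abs=1e-3)
        assert sp["language:background"] == pytest.approx(0.0147, abs=1e-3)
        rs = [RandomSpec("participant",
                         ("1", "language", "background",
                          "language:background")),
              RandomSpec("text")]
        w = eta2w_lmm(reading, ["language", "background",
                                "language:background"], rs, "participant")
        assert w["language"] == pytest.approx(0.068, abs=2e-3)
        assert w["background"] == pytest.approx(0.198, abs=2e-3)
        assert w["language:background"] == pytest.approx(0.0245, abs=1e-3)


class TestDegenerateAndErrors:
    def test_zero_variance_limit_equals_ols(self):
        spec = SimSpec(n_participants=12, seed=5,
                       factors={"a": "within_participant"},
                       intercept=2.0, fixed={"a": 1.0},
                       participant_components={"1": 0.0},
                       residual_sd=1.0, replicates=4)
        t = simulate_crossed(spec)
        fit = fit_lmm(t, ["a"], [RandomSpec("participant")])
        from etawithin.contrasts import build_design_matrix
        X = build_design_matrix(t, ["a"], CodingScheme()).array
        y = t.data["response"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.fixed["estimate"], beta, atol=1e-5)
        assert fit.singular  # intercept variance estimated at the boundary

    def test_singular_fit_returned_not_raised(self, twobytwo):
        c = ew.center_by_unit(twobytwo, "participant")
        fit = fit_lmm(c, ["day", "stimulus_type", "day:stimulus_type"],
                      [RandomSpec("participant",
                                  ("1", "day", "stimulus_type",
                                   "day:stimulus_type"))])
        assert fit.singular and fit.converged

    def test_between_unit_slope_rejected(self, faces):
        with pytest.raises(ValueError, match="constant within"):
            fit_lmm(faces, ["age"],
                    [RandomSpec("participant", ("1", "age"))])

    def test_unknown_term_df(self, faces_fit):
        with pytest.raises(KeyError):
            satterthwaite_df(faces_fit, "height")

    def test_eta2w_requires_random_grouping(self, faces):
        rs = [RandomSpec("participant"), RandomSpec("stimulus", ("1", "age"))]
        with pytest.raises(ValueError, match="grouping"):
            eta2w_lmm(faces, ["age"], rs, "age")


class TestEffectReport:
    def test_composition(self, faces):
        rs = [RandomSpec("participant"), RandomSpec("stimulus", ("1", "age"))]
        rep = effect_report(faces, ["age"], rs)
        assert rep.center_by == "stimulus"  # age only varies within stimuli
        row = rep.table.set_index("term").loc["age"]
        from scipy import stats
        assert row["p"] == pytest.approx(
            2 * stats.t.sf(abs(row["t"]), row["df"]), rel=1e-12)
        assert rep.r2_marginal >= row["eta2"] - 1e-9

    def test_eta2p_on_request_with_warning(self, twobytwo):
        fixed = ["day", "stimulus_type", "day:stimulus_type"]
        rs = [RandomSpec("participant",
                         ("1", "day", "stimulus_type", "day:stimulus_type"))]
        with pytest.warns(UserWarning, match="partial eta squared"):
            rep = effect_report(twobytwo, fixed, rs, center_by="participant",
                                include_eta2p=True)
        tab = rep.table.set_index("term")
        t, df = tab.loc["day", "t"], tab.loc["day", "df"]
        assert tab.loc["day", "eta2_p"] == pytest.approx(t**2 / (t**2 + df))

    def test_residual_df_fallback(self, wm_between):
        rep = effect_report(wm_between, ["group"], [RandomSpec("participant")],
                            df_method="residual")
        assert (rep.table["df"] == 38).all()

    def test_intercept_only_model(self, wm_between):
        rep = effect_report(wm_between, [], [RandomSpec("participant")])
        assert list(rep.table["term"]) == ["(Intercept)"]
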