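"""Mixed model, ICC/R² arithmetic, GWR and OLS comparison."""

import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from crowdstress.errors import ModelError
from crowdstress.models import (
    GlmmResult,
    GlmmSpec,
    fit_glmm,
    fit_gwr,
    fit_ols,
    gaussian_kernel,
    icc,
    r2_mixed,
    significance_stars,
)


def make_result(tau: dict, sigma2: float, var_fixed: float = 0.0) -> GlmmResult:
    return GlmmResult(
        site="x", n_obs=100, n_groups={}, fixed_effects={}, tau=tau, sigma2=sigma2,
        var_fixed=var_fixed, icc=math.nan, r2_marginal=math.nan,
        r2_conditional=math.nan, converged=True, optimizer="test",
    )


class TestIcc:
    def test_arithmetic_matches_printed_value(self):
        # variance components of a participant-clustered fit:
        # 28.28 / (28.28 + 263.67) = 0.0969 -> prints 0.10
        res = make_result({"participant_id": 28.28, "timeslot": 0.0, "gender": 0.0}, 263.67)
        assert round(icc(res), 2) == 0.10

    def test_zero_random_variance_undefined(self):
        res = make_result({"participant_id": 0.0}, 263.0)
        assert math.isnan(icc(res))

    def test_symmetry(self):
        res = make_result({"participant_id": 5.0}, 5.0)
        assert icc(res) == pytest.approx(0.5)


class TestR2Mixed:
    def test_no_fixed_variance_marginal_zero(self):
        res = make_result({"participant_id": 10.0}, 90.0, var_fixed=0.0)
        marginal, conditional = r2_mixed(res)
        assert marginal == pytest.approx(0.0)
        assert conditional == pytest.approx(0.1)

    def test_degenerate_random_part_conditional_undefined(self):
        res = make_result({"participant_id": 0.0}, 90.0, var_fixed=10.0)
        marginal, conditional = r2_mixed(res)
        assert marginal == pytest.approx(0.1)
        assert math.isnan(conditional)

    def test_marginal_never_exceeds_conditional(self):
        res = make_result({"participant_id": 3.0}, 50.0, var_fixed=7.0)
        marginal, conditional = r2_mixed(res)
        assert marginal <= conditional


@pytest.mark.parametrize(
    "p,stars",
    [(0.0005, "***"), (0.001, "**"), (0.005, "**"), (0.01, "*"), (0.049, "*"),
     (0.05, "ns"), (0.5, "ns")],
)
def test_significance_stars_thresholds(p, stars):
    assert significance_stars(p) == stars


def _mixed_dataset(seed: int = 0, n_person: int = 12, per_person: int = 80) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    b_person = rng.normal(0, 4.0, n_person)
    for i in range(n_person):
        x1 = rng.poisson(0.5, per_person)
        x2 = rng.poisson(1.5, per_person)
        y = 10 + 2.5 * x1 - 0.8 * x2 + b_person[i] + rng.normal(0, 6.0, per_person)
        rows.append(
            pd.DataFrame(
                {
                    "CS": y, "persons_personal": x1, "persons_close": x2,
                    "participant_id": f"P{i:02d}",
                    "timeslot": "9-12" if i % 2 else "13-16",
                    "gender": "f" if i % 2 else "m",
                    "site": "s1",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestFitGlmm:
    spec = GlmmSpec(
        fixed=("persons_personal", "persons_close"),
        random_intercepts=("participant_id",),
        per_site=False,
    )

    def test_recovers_effects_and_variance(self):
        df = _mixed_dataset()
        res = fit_glmm(df, self.spec)["all"]
        assert res.fixed_effects["persons_personal"]["estimate"] == pytest.approx(2.5, abs=0.6)
        assert res.fixed_effects["persons_close"]["estimate"] == pytest.approx(-0.8, abs=0.5)
        assert res.tau["participant_id"] == pytest.approx(16.0, rel=0.9)
        assert res.sigma2 == pytest.approx(36.0, rel=0.25)

    def test_serialization_roundtrip(self, tmp_path):
        res = fit_glmm(_mixed_dataset(), self.spec)["all"]
        path = tmp_path / "glmm.json"
        res.to_json(path)
        back = GlmmResult.from_json(path)
        for key, fe in res.fixed_effects.items():
            assert back.fixed_effects[key]["estimate"] == pytest.approx(
                fe["estimate"], rel=1e-12
            )
        assert back.sigma2 == pytest.approx(res.sigma2, rel=1e-12)
        assert back.tau == pytest.approx(res.tau, rel=1e-12)

    def test_insufficient_records_raise(self):
        with pytest.raises(ModelError, match="floor"):
            fit_glmm(_mixed_dataset().head(10), self.spec)

    def test_missing_column_raises(self):
        df = _mixed_dataset().drop(columns=["persons_close"])
        with pytest.raises(ModelError, match="persons_close"):
            fit_glmm(df, self.spec)

    def test_single_level_grouping_dropped_with_warning(self):
        df = _mixed_dataset()
        df["gender"] = "f"
        spec = GlmmSpec(
            fixed=("persons_personal",), random_intercepts=("participant_id", "gender"),
            per_site=False,
        )
        with pytest.warns(UserWarning, match="gender"):
            res = fit_glmm(df, spec)["all"]
        assert "gender" in res.dropped_groupings

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_against_lme4_oracle(self, tmp_path):
        """Independent cross-check: lme4's REML fit of the same random-
        intercept model agrees on fixed effects and variance components."""
        df = _mixed_dataset(seed=3)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(TRUE)[1])
            m <- lmer(CS ~ persons_personal + persons_close + (1|participant_id),
                      data = d, REML = TRUE)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            cat(jsonlite::toJSON(list(
              fe = as.list(fe),
              tau = vc$vcov[vc$grp == "participant_id"],
              sigma2 = vc$vcov[vc$grp == "Residual"]), auto_unbox = TRUE))
            """
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(csv)],
            capture_output=True, text=True, check=True,
        )
        oracle = json.loads(out.stdout)
        res = fit_glmm(df, self.spec)["all"]
        assert res.fixed_effects["persons_personal"]["estimate"] == pytest.approx(
            oracle["fe"]["persons_personal"], abs=1e-4
        )
        assert res.fixed_effects["persons_close"]["estimate"] == pytest.approx(
            oracle["fe"]["persons_close"], abs=1e-4
        )
        assert res.tau["participant_id"] == pytest.approx(oracle["tau"], rel=1e-3)
        assert res.sigma2 == pytest.approx(oracle["sigma2"], rel=1e-3)


def _spatial_dataset(seed: int = 0, n: int = 300) -> pd.DataFrame:
    """Points along a ~500 m west-east strip with Poisson predictors."""
    rng = np.random.default_rng(seed)
    lat0, lon0 = 47.8, 13.04
    x_m = rng.uniform(0, 500, n)
    y_m = rng.uniform(0, 60, n)
    lat = lat0 + y_m / 111_194.9
    lon = lon0 + x_m / (111_194.9 * math.cos(math.radians(lat0)))
    df = pd.DataFrame(
        {
            "lat": lat, "lon": lon,
            "bikes": rng.poisson(1.5, n),
            "motor_vehicles": rng.poisson(1.0, n),
            "x_m": x_m,
        }
    )
    df["CS"] = (
        20 + 1.2 * df["bikes"] - 0.5 * df["motor_vehicles"] + rng.normal(0, 2.0, n)
    )
    return df


class TestGwr:
    def test_kernel_weight_one_at_zero_distance(self):
        assert gaussian_kernel(np.array([0.0]), 100.0)[0] == 1.0

    def test_huge_bandwidth_reproduces_global_ols(self):
        df = _spatial_dataset()
        preds = ["bikes", "motor_vehicles"]
        gwr = fit_gwr(df, preds, bandwidth=1e6)
        ols = fit_ols(df, preds)
        for name in ("intercept", *preds):
            local = gwr.local[name].to_numpy()
            ref = ols["coefficients"][name]
            assert np.max(np.abs(local - ref)) / abs(ref) < 1e-6

    def test_spatially_varying_coefficient_recovered(self):
        """A bikes-effect ramping linearly west->east is recovered by the
        local coefficients (Pearson r >= 0.8 with the true ramp)."""
        rng = np.random.default_rng(7)
        df = _spatial_dataset(seed=7, n=600)
        beta_true = 0.5 + 2.0 * df["x_m"] / 500.0  # 0.5 in the west, 2.5 in the east
        df["CS"] = 20 + beta_true * df["bikes"] + rng.normal(0, 1.0, len(df))
        gwr = fit_gwr(df, ["bikes"], bandwidth=80.0)
        r = np.corrcoef(gwr.local["bikes"], beta_true)[0, 1]
        assert r >= 0.8

    def test_auto_bandwidth_is_finite_and_positive(self):
        df = _spatial_dataset(n=150)
        gwr = fit_gwr(df, ["bikes"], bandwidth="auto")
        assert 0 < gwr.bandwidth_m < 1e7
        assert math.isfinite(gwr.aicc)

    def test_standardized_residuals_centered(self):
        df = _spatial_dataset(n=200)
        gwr = fit_gwr(df, ["bikes"], bandwidth=200.0)
        assert abs(float(gwr.local["std_resid"].mean())) < 0.2

    def test_locally_constant_predictor_flagged_not_crash(self):
        df = _spatial_dataset(n=120)
        df["bikes"] = 2  # globally constant -> locally singular everywhere
        gwr = fit_gwr(df, ["bikes"], bandwidth=100.0)
        assert gwr.local["bikes"].isna().all()
        assert gwr.local["fitted"].notna().all()

    def test_geojson_output(self, tmp_path):
        df = _spatial_dataset(n=60)
        gwr = fit_gwr(df, ["bikes"], bandwidth=200.0)
        path = tmp_path / "gwr.geojson"
        gwr.to_geojson(path, df)
        doc = json.loads(path.read_text())
        assert len(doc["features"]) == 60
        assert "bikes" in doc["features"][0]["properties"]


class TestOls:
    def test_identity_predictor(self):
        df = pd.DataFrame({"CS": np.arange(50.0)})
        df["bikes"] = df["CS"]
        out = fit_ols(df, ["bikes"])
        assert out["coefficients"]["bikes"] == pytest.approx(1.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_orthogonal_noise_predictor_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"CS": rng.normal(0, 1, 2000), "bikes": rng.poisson(1, 2000)})
        out = fit_ols(df, ["bikes"])
        assert abs(out["coefficients"]["bikes"]) < 0.1

    def test_rank_deficiency_names_column(self):
        df = pd.DataFrame({"CS": np.arange(30.0), "bikes": np.ones(30)})
        df["motor_vehicles"] = df["bikes"] * 2
        with pytest.raises(ModelError, match="motor_vehicles"):
            fit_ols(df, ["bikes", "motor_vehicles"])
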