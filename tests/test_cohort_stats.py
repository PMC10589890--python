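"""Group models, partial Spearman correlation, paired tests and secondary
regressions, with external cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcmrf import (
    glm_group,
    make_cohort,
    paired_volumes_test,
    partial_spearman,
    secondary_regressions,
)
from mcmrf.synthetic_data import CohortSpec


def _table(n_per=10, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per):
        patient = i < n_per
        rows.append(
            {
                "id": i,
                "group": "patient" if patient else "control",
                "site": "A" if i % 2 else "B",
                "age_years": rng.uniform(20, 60),
                "sex": "F" if rng.random() < 0.5 else "M",
                "vol": rng.normal(0.005 + effect * patient, 0.001),
            }
        )
    return pd.DataFrame(rows)


class TestGlmGroup:
    def test_identical_groups_give_null_effect(self):
        base = _table(n_per=8, seed=1)
        # mirror the patient rows into the control group exactly
        mirrored = base[base.group == "patient"].copy()
        mirrored["group"] = "control"
        mirrored["id"] = mirrored["id"] + 100
        table = pd.concat([base[base.group == "patient"], mirrored])
        out = glm_group(table, "vol")
        assert abs(out["b"]) < 1e-12
        assert out["p"] > 0.999

    def test_positive_coefficient_means_larger_patient_volume(self):
        table = _table(n_per=20, seed=2, effect=0.004)
        out = glm_group(table, "vol")
        assert out["b"] > 0
        assert out["ci95"][0] <= out["b"] <= out["ci95"][1]
        assert 0 <= out["p"] <= 1

    def test_reduces_to_t_test_with_constant_covariates(self):
        table = _table(n_per=12, seed=3, effect=0.002)
        table["age_years"] = 30.0
        table["sex"] = "F"
        out = glm_group(table, "vol")
        pat = table[table.group == "patient"]["vol"]
        con = table[table.group == "control"]["vol"]
        t, p = stats.ttest_ind(pat, con)
        assert out["p"] == pytest.approx(p, abs=1e-10)
        assert out["b"] == pytest.approx(pat.mean() - con.mean(), rel=1e-10)

    def test_collinear_covariate_named(self):
        table = _table(n_per=6, seed=4)
        table["age2"] = table["age_years"]
        with pytest.raises(ValueError, match="age2|age_years"):
            glm_group(table, "vol", covariates=("age_years", "age2", "sex"))

    def test_single_subject_group_rejected(self):
        table = _table(n_per=5, seed=5)
        table = table[(table.group == "patient") | (table.id == 5)]
        with pytest.raises(ValueError):
            glm_group(table, "vol")


class TestPartialSpearman:
    def test_perfect_monotone_association(self):
        x = np.arange(20, dtype=float)
        table = pd.DataFrame(
            {"score": x, "vol": np.exp(x / 5), "site": ["A", "B"] * 10}
        )
        out = partial_spearman(table, "score", "vol", ("site",))
        assert out["rho"] == pytest.approx(1.0, abs=1e-10)

    def test_single_level_site_equals_plain_spearman(self, rng):
        table = pd.DataFrame(
            {
                "score": rng.integers(0, 15, 40).astype(float),
                "vol": rng.random(40),
                "site": ["A"] * 40,
            }
        )
        out = partial_spearman(table, "score", "vol", ("site",))
        rho, p = stats.spearmanr(table["score"], table["vol"])
        assert out["rho"] == pytest.approx(rho, abs=1e-12)

    def test_site_confound_removed(self, rng):
        n = 60
        site = np.repeat(["A", "B"], n // 2)
        x = rng.random(n)
        y = x + np.where(site == "A", 0.0, 5.0)
        table = pd.DataFrame({"score": x, "vol": y, "site": site})
        naive = stats.spearmanr(x, y).statistic
        out = partial_spearman(table, "score", "vol", ("site",))
        assert out["rho"] > 0.95
        assert naive < out["rho"]

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 50
        table = pd.DataFrame(
            {
                "score": rng.random(n),
                "vol": rng.random(n),
                "site_num": rng.integers(0, 2, n).astype(float),
            }
        )
        ours = partial_spearman(table, "score", "vol", ("site_num",))
        ref = pingouin.partial_corr(
            table, x="score", y="vol", covar="site_num", method="spearman"
        )
        assert ours["rho"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_null_calibration(self):
        rejections = 0
        rhos = []
        n_sim = 400
        for seed in range(n_sim):
            g = np.random.default_rng(seed)
            table = pd.DataFrame(
                {
                    "score": g.random(30),
                    "vol": g.random(30),
                    "site": ["A", "B"] * 15,
                }
            )
            out = partial_spearman(table, "score", "vol", ("site",))
            rhos.append(out["rho"])
            rejections += out["p"] < 0.05
        assert abs(np.mean(rhos)) < 0.02
        assert 0.03 < rejections / n_sim < 0.07

    def test_constant_variable_rejected(self):
        table = pd.DataFrame({"score": [1.0] * 10, "vol": np.arange(10.0), "site": ["A"] * 10})
        with pytest.raises(ValueError):
            partial_spearman(table, "score", "vol", ("site",))


class TestPairedVolumes:
    def test_equal_columns_degenerate_convention(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        out = paired_volumes_test(table, "a", "b")
        assert out["mean_diff"] == 0.0
        assert np.isnan(out["p"])

    def test_constant_nonzero_difference_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.5, 1.5, 2.5]})
        with pytest.raises(ValueError):
            paired_volumes_test(table, "a", "b")

    def test_small_systematic_difference_detected(self, rng):
        n = 48
        b = rng.random(n) * 0.01
        a = b + 0.002 + rng.normal(0, 1e-4, n)
        out = paired_volumes_test(pd.DataFrame({"a": a, "b": b}), "a", "b")
        assert out["p"] < 1e-16
        assert out["mean_diff"] == pytest.approx(0.002, abs=2e-4)

    def test_sign_flip_antisymmetry(self, rng):
        a = rng.random(10)
        b = rng.random(10)
        table = pd.DataFrame({"a": a, "b": b})
        fwd = paired_volumes_test(table, "a", "b")
        rev = paired_volumes_test(table, "b", "a")
        assert fwd["t"] == pytest.approx(-rev["t"], rel=1e-12)


class TestSecondaryRegressions:
    def test_perfectly_linear_outcome(self):
        table = pd.DataFrame({"edss": np.arange(10.0), "vol": 2.0 + 0.003 * np.arange(10.0)})
        out = secondary_regressions(table, "vol", ("edss",))
        assert out.loc[0, "r_squared"] == pytest.approx(1.0)
        assert out.loc[0, "b"] == pytest.approx(0.003)

    def test_ci_coverage_near_nominal(self):
        true_b = 0.002
        covered = 0
        n_sim = 300
        for seed in range(n_sim):
            g = np.random.default_rng(seed)
            x = g.uniform(0, 8, 40)
            y = 0.004 + true_b * x + g.normal(0, 0.002, 40)
            out = secondary_regressions(pd.DataFrame({"edss": x, "vol": y}), "vol", ("edss",))
            covered += out.loc[0, "ci_low"] <= true_b <= out.loc[0, "ci_high"]
        assert 0.92 < covered / n_sim < 0.98

    def test_edss_slope_recovered_from_generated_cohort(self):
        spec = CohortSpec(edss_slope=0.00117, seed=11)
        table = make_cohort(spec)
        out = secondary_regressions(table, "wm_long_volume", ("edss",))
        b = out.loc[0, "b"]
        se = (out.loc[0, "ci_high"] - out.loc[0, "ci_low"]) / (2 * 1.96)
        assert abs(b - 0.00117) < 3 * se
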