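"""Tests of orientation, filtering, transforms, residualization, z-scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogconn import CognitiveDataset, CohortConfig, GroupSpec, MeasureMeta, generate_cohort
from cogconn.preprocessing import (
    PreprocessError,
    domain_composites,
    filter_missing,
    orient_measures,
    preprocess,
    residualize,
    transform_skew,
    zscore_reference,
)


def tiny_dataset(values: dict, meta: dict | None = None, n=None) -> CognitiveDataset:
    cols = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    n = n or len(next(iter(cols.values())))
    rng = np.random.default_rng(12345)
    table = pd.DataFrame(
        {
            "group": ["g"] * n,
            "age": rng.normal(70, 8, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(16, 3, n),
            **cols,
        }
    )
    meta = meta or {
        m: MeasureMeta(domain="d1") for m in cols
    }
    return CognitiveDataset(table=table, measure_meta=meta)


class TestOrientMeasures:
    def test_higher_worse_is_negated(self):
        data = tiny_dataset(
            {"tmt_a": [30, 60, 45, 50]},
            {"tmt_a": MeasureMeta(domain="d1", orientation="higher_worse")},
        )
        out, rep = orient_measures(data)
        assert list(out.table["tmt_a"]) == [-30, -60, -45, -50]
        assert rep.inverted_measures == ["tmt_a"]
        assert out.measure_meta["tmt_a"].orientation == "higher_better"

    def test_higher_better_untouched(self):
        data = tiny_dataset({"m": [1, 2, 3, 4]})
        out, rep = orient_measures(data)
        assert list(out.table["m"]) == [1, 2, 3, 4]
        assert rep.inverted_measures == []

    def test_second_application_is_noop(self):
        data = tiny_dataset(
            {"m": [5, 7, 6, 8]},
            {"m": MeasureMeta(domain="d1", orientation="higher_worse")},
        )
        once, _ = orient_measures(data)
        twice, rep = orient_measures(once)
        pd.testing.assert_frame_equal(once.table, twice.table)
        assert rep.inverted_measures == []


class TestFilterMissing:
    def _with_missing(self, n_missing, n=100):
        x = np.random.default_rng(0).normal(size=n)
        x[:n_missing] = np.nan
        return tiny_dataset({"m_bad": x, "m_ok": np.arange(n, dtype=float)}, n=n)

    def test_sixteen_percent_excluded(self):
        out, rep = filter_missing(self._with_missing(16))
        assert "m_bad" in rep.excluded_measures
        assert out.measures == ["m_ok"]

    def test_exactly_fifteen_percent_retained(self):
        out, rep = filter_missing(self._with_missing(15))
        assert rep.excluded_measures == {}
        assert set(out.measures) == {"m_bad", "m_ok"}
        # retained rows are complete cases
        assert not out.table[out.measures].isna().any().any()
        assert rep.n_rows_dropped == 15

    def test_no_missing_is_identity(self):
        data = self._with_missing(0)
        out, rep = filter_missing(data)
        pd.testing.assert_frame_equal(out.table, data.table)
        assert rep.excluded_measures == {}

    def test_all_excluded_raises(self):
        x = np.full(20, np.nan)
        x[:2] = 1.0
        with pytest.raises(PreprocessError):
            filter_missing(tiny_dataset({"m": x}))

    def test_order_independent(self):
        data = self._with_missing(20)
        reordered = data.with_table(
            data.table[["group", "age", "sex", "education", "m_ok", "m_bad"]]
        )
        out1, _ = filter_missing(data)
        out2, _ = filter_missing(reordered)
        assert set(out1.measures) == set(out2.measures)
        pd.testing.assert_frame_equal(
            out1.table[out1.measures], out2.table[out1.measures]
        )


class TestTransformSkew:
    def test_exponential_measure_has_skew_reduced(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(size=500))
        data = tiny_dataset({"m": x})
        assert abs(stats.skew(x)) > 1
        out, rep = transform_skew(data)
        assert rep.transforms_applied["m"] == "log1p_shifted"
        assert abs(stats.skew(out.table["m"])) < abs(stats.skew(x))

    def test_left_skew_uses_reflected_transform(self):
        rng = np.random.default_rng(2)
        x = -np.exp(rng.normal(size=500))
        out, rep = transform_skew(tiny_dataset({"m": x}))
        assert rep.transforms_applied["m"] == "reflected_log1p"
        assert abs(stats.skew(out.table["m"])) < abs(stats.skew(x))

    def test_gaussian_measure_untouched(self):
        x = np.random.default_rng(3).normal(size=500)
        data = tiny_dataset({"m": x})
        out, rep = transform_skew(data)
        assert "m" not in rep.transforms_applied
        np.testing.assert_array_equal(out.table["m"], x)

    def test_constant_measure_flagged_not_transformed(self):
        data = tiny_dataset({"m": np.ones(50)})
        out, rep = transform_skew(data)
        assert rep.transforms_applied["m"] == "none:degenerate_constant"
        np.testing.assert_array_equal(out.table["m"], np.ones(50))

    def test_spearman_correlations_preserved(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(size=300))
        y = rng.normal(size=300) + 0.5 * np.log(x)
        data = tiny_dataset({"mx": x, "my": y})
        before = stats.spearmanr(x, y).statistic
        out, _ = transform_skew(data)
        after = stats.spearmanr(out.table["mx"], out.table["my"]).statistic
        assert before == pytest.approx(after, abs=1e-12)


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(5)
        n = 200
        data = tiny_dataset({"m": np.zeros(n)}, n=n)
        data.table["m"] = 2.0 * data.table["age"] + rng.normal(size=n)
        out, rep = residualize(data)
        r = np.corrcoef(out.table["m"], data.table["age"])[0, 1]
        assert abs(r) < 1e-10
        assert rep.regression_models["m"] == "linear"

    def test_planted_education_effect_removed(self):
        cfg = CohortConfig(
            groups=[GroupSpec("g", 2000)],
            covariate_effects={"memory_1": {"education": 0.5}},
            mean_shifts={}, skewed_measures=(), inverted_measures=(), seed=9,
        )
        data = generate_cohort(cfg)
        out, _ = residualize(data)
        res = stats.linregress(out.table["education"], out.table["memory_1"])
        assert abs(res.slope) <= 3 * res.stderr

    def test_binary_measure_uses_logistic_model(self):
        rng = np.random.default_rng(6)
        n = 300
        data = tiny_dataset({"m": np.zeros(n)}, n=n)
        age = data.table["age"].to_numpy()
        p = 1 / (1 + np.exp(-(age - 70) / 5))
        data.table["m"] = (rng.random(n) < p).astype(float)
        data = data.with_meta(
            {"m": MeasureMeta(domain="d1", scale_type="discrete_bounded")}
        )
        out, rep = residualize(data)
        assert rep.regression_models["m"] == "logistic"
        # residuals are observed minus fitted probability: mean ~ 0
        assert abs(out.table["m"].mean()) < 0.05

    def test_zero_variance_covariate_raises_with_name(self):
        data = tiny_dataset({"m": np.arange(20, dtype=float)})
        data.table["sex"] = 0.0
        with pytest.raises(PreprocessError, match="sex"):
            residualize(data)

    def test_too_few_rows_raises(self):
        data = tiny_dataset({"m": np.arange(5, dtype=float)})
        with pytest.raises(PreprocessError):
            residualize(data)


class TestZScoreAndComposites:
    def _two_groups(self, shift=-1.0, n=400, seed=10):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {
                "group": ["ref"] * n + ["pat"] * n,
                "age": rng.normal(70, 5, 2 * n),
                "sex": rng.integers(0, 2, 2 * n).astype(float),
                "education": rng.normal(16, 2, 2 * n),
                "m1": np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n)]),
                "m2": np.concatenate([rng.normal(5, 2, n), rng.normal(5 + 2 * shift, 2, n)]),
            }
        )
        meta = {"m1": MeasureMeta(domain="d1"), "m2": MeasureMeta(domain="d1")}
        return CognitiveDataset(table=table, measure_meta=meta)

    def test_reference_group_standardized(self):
        out = zscore_reference(self._two_groups(), "ref")
        ref = out.group_table("ref")
        for m in ("m1", "m2"):
            assert ref[m].mean() == pytest.approx(0, abs=1e-12)
            assert ref[m].std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_shifted_group_composite_near_minus_one(self):
        out = zscore_reference(self._two_groups(shift=-1.0), "ref")
        comp = domain_composites(out)
        pat = comp.loc[out.table["group"] == "pat", "d1"]
        assert pat.mean() == pytest.approx(-1.0, abs=0.15)

    def test_single_row_reference_raises(self):
        data = self._two_groups(n=200)
        data.table = data.table.drop(data.table[data.table["group"] == "ref"].index[1:])
        with pytest.raises(PreprocessError):
            zscore_reference(data, "ref")

    def test_zero_reference_sd_raises_with_measure_name(self):
        data = self._two_groups()
        data.table.loc[data.table["group"] == "ref", "m2"] = 3.0
        with pytest.raises(PreprocessError, match="m2"):
            zscore_reference(data, "ref")

    def test_composite_is_mean_of_member_zscores(self):
        data = self._two_groups()
        data.table["m1"] = np.linspace(-1, 1, len(data.table))
        data.table["m2"] = np.linspace(1, -1, len(data.table))
        comp = domain_composites(data)
        np.testing.assert_allclose(
            comp["d1"], (data.table["m1"] + data.table["m2"]) / 2
        )

    def test_single_measure_domain_equals_that_measure(self):
        data = self._two_groups()
        data = data.with_meta({"m2": MeasureMeta(domain="d2")})
        comp = domain_composites(data)
        np.testing.assert_allclose(comp["d2"], data.table["m2"])


class TestFullChain:
    def test_preprocess_is_deterministic(self, demo_cohort):
        c1, _ = preprocess(demo_cohort, "hc")
        c2, _ = preprocess(demo_cohort, "hc")
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_preprocess_orients_all_measures(self, demo_cohort):
        clean, rep = preprocess(demo_cohort, "hc")
        assert all(
            clean.measure_meta[m].orientation == "higher_better"
            for m in clean.measures
        )
        assert set(rep.inverted_measures) == {"attention_1", "executive_4"}
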