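import numpy as np
import pandas as pd
import pytest

from oracles import binom_two_tailed, chi2_sf_numeric
from ssdfate import datasets
from ssdfate.classify import RetentionCall
from ssdfate.stats import (
    age_class_test,
    chi_square_gof,
    expected_counts,
    filter_saturated,
    null_rejection_rate,
    pearson_test,
    pooled_summary,
    row_enrichment_tests,
    tissue_enrichment,
)

MECH_TABLE = datasets.grass_duplication_mechanism_counts()


class TestExpectedCounts:
    def test_published_mechanism_table(self):
        exp = expected_counts(MECH_TABLE)
        assert exp.loc["conservation"].round(2).tolist() == [455.98, 36.02]
        assert exp.loc["neofunctionalization_parent"].round(2).tolist() == [38.00, 3.00]
        assert exp.loc["neofunctionalization_child"].round(2).tolist() == [134.39, 10.61]
        assert exp.loc["specialization"].round(2).tolist() == [80.63, 6.37]

    def test_single_row_collapses_to_observed(self):
        obs = pd.DataFrame({"DNA": [10], "RNA": [4]}, index=["only"])
        assert np.allclose(expected_counts(obs), obs)

    def test_margins_preserved_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            obs = pd.DataFrame(rng.integers(0, 40, size=(4, 3)))
            if obs.to_numpy().sum() == 0:
                continue
            exp = expected_counts(obs)
            assert np.allclose(exp.sum(axis=1), obs.sum(axis=1))
            assert np.allclose(exp.sum(axis=0), obs.sum(axis=0))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            expected_counts(pd.DataFrame({"a": [0], "b": [0]}))


class TestChiSquare:
    def test_published_p_values_round_to_table(self):
        expected_p = {"conservation": 0.17, "neofunctionalization_parent": 0.55,
                      "neofunctionalization_child": 0.01, "specialization": 0.79}
        for res in row_enrichment_tests(MECH_TABLE):
            assert res.df == 1
            assert round(res.p, 2) == expected_p[res.label]

    def test_null_identity(self):
        chi2, df, p = chi_square_gof([5, 5], [5.0, 5.0])
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            chi_square_gof([1, 2], [0.0, 3.0])

    @pytest.mark.parametrize("df", [1, 2, 3])
    def test_upper_tail_matches_integration_oracle(self, df):
        rng = np.random.default_rng(df)
        for _ in range(10):
            e = rng.uniform(5, 50, size=df + 1)
            o = e + rng.normal(0, np.sqrt(e))
            o = np.maximum(o, 0)
            chi2, _, p = chi_square_gof(o, e * o.sum() / e.sum())
            assert p == pytest.approx(chi2_sf_numeric(chi2, df), abs=1e-8)


def _call(mech, age):
    return RetentionCall("t", "p", "c", 0, 0, 0, 1, mech, None, age_class=age)


class TestAgeClassTest:
    def test_uniform_frequencies_give_p_one(self):
        calls = [_call(m, a) for m in ("conservation", "specialization") for a in (1, 2, 3) for _ in range(10)]
        for res in age_class_test(calls):
            assert res.p == pytest.approx(1.0)

    def test_planted_age_effect_detected(self):
        calls = [_call("conservation", 1) for _ in range(80)]
        calls += [_call("conservation", 2) for _ in range(20)]
        calls += [_call("specialization", 1) for _ in range(50)]
        calls += [_call("specialization", 2) for _ in range(50)]
        res = {r.label: r for r in age_class_test(calls)}
        assert res["conservation"].p < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            age_class_test([_call("conservation", 1)])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        res = pearson_test(x, -x)
        assert res.r == pytest.approx(-1.0)

    def test_t_statistic_closed_form(self):
        # construct vectors with r exactly 0.5 at n = 11:
        # t = 0.5 * sqrt(9) / sqrt(0.75) = sqrt(3)
        rng = np.random.default_rng(1)
        x = rng.normal(size=11)
        e = rng.normal(size=11)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        ec = e - e.mean() - ((e - e.mean()) @ xc) * xc
        ec /= np.linalg.norm(ec)
        y = 0.5 * xc + np.sqrt(0.75) * ec
        res = pearson_test(x, y)
        assert res.r == pytest.approx(0.5)
        assert res.t == pytest.approx(np.sqrt(3.0), abs=1e-9)
        assert res.n == 11

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_test([1, 2], [1, 2])

    def test_ks_saturation_filter(self):
        df = pd.DataFrame({"ks": [0.5, 2.9, 3.0, 4.2], "ka": [1, 2, 3, 4]})
        kept = filter_saturated(df)
        assert kept["ks"].tolist() == [0.5, 2.9]


class TestTissueEnrichment:
    def test_symmetric_all_successes(self):
        # 5 successes out of 5 at p = 0.5: two-tailed P = 2/32
        res = tissue_enrichment({"a": 5, "b": 0}, {"a": 1, "b": 1})
        r = {x.tissue: x for x in res}
        assert r["a"].p == pytest.approx(0.0625)
        assert r["a"].p_adjusted == pytest.approx(min(1.0, 0.0625 * 2))
        assert r["a"].direction == 1 and r["b"].direction == -1

    def test_observation_at_expectation_gives_p_one(self):
        res = tissue_enrichment({"a": 5, "b": 5}, {"a": 50, "b": 50})
        assert all(x.p == pytest.approx(1.0) for x in res)

    @pytest.mark.parametrize(
        "k,n,p", [(30, 100, 0.15), (0, 40, 0.2), (250, 500, 0.45), (499, 500, 0.97)]
    )
    def test_matches_enumeration_oracle(self, k, n, p):
        counts = {"x": k, "y": n - k}
        null = {"x": int(p * 1000), "y": 1000 - int(p * 1000)}
        p_null = null["x"] / 1000
        res = {x.tissue: x for x in tissue_enrichment(counts, null)}
        assert res["x"].p == pytest.approx(binom_two_tailed(k, n, p_null), rel=1e-12)

    def test_bonferroni_uses_number_of_tissues(self):
        dup = {"t%d" % i: (20 if i == 0 else 2) for i in range(9)}
        sc = {"t%d" % i: 100 for i in range(9)}
        res = tissue_enrichment(dup, sc)
        for x in res:
            assert x.p_adjusted == pytest.approx(min(1.0, x.p * 9))

    def test_mismatched_tissue_sets_rejected(self):
        with pytest.raises(ValueError):
            tissue_enrichment({"a": 1}, {"b": 1})


class TestPooledSummary:
    def test_published_retention_table(self):
        summary = pooled_summary(datasets.grass_retention_counts())
        assert summary.percentages == {
            "conservation": 60.6,
            "neofunctionalization": 23.8,
            "subfunctionalization": 0.4,
            "specialization": 15.2,
        }
        assert summary.child_bias == {
            "B. distachyon": 72,
            "O. sativa japonica": 70,
            "S. bicolor": 89,
        }

    def test_inconsistent_neo_total_rejected(self):
        df = datasets.grass_retention_counts().copy()
        df["neofunctionalization"] = 999
        with pytest.raises(ValueError, match="neofunctionalization"):
            pooled_summary(df)

    def test_all_zero_rejected(self):
        df = datasets.grass_retention_counts() * 0
        with pytest.raises(ValueError):
            pooled_summary(df)


class TestNullCalibration:
    def test_type_one_error_near_nominal(self):
        # independence of category and row labels: rejection rate at
        # alpha = 0.05 within binomial sampling error over 2000 tables
        rate = null_rejection_rate(n_tables=2000, row_total=500, p=0.1, seed=0)
        assert abs(rate - 0.05) <= 0.016
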