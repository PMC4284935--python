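"""Cohort statistics against hand-coded textbook oracles."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from onhcolor.exceptions import InsufficientSampleError, ValidationError
from onhcolor.stats import (
    bonferroni_alpha,
    compare_groups,
    correlate,
    normality_gate,
    report_tables,
)


def _pooled_t_oracle(x1, x2):
    """Textbook pooled-variance two-sample t, written independently."""
    n1, n2 = len(x1), len(x2)
    v1 = np.sum((x1 - np.mean(x1)) ** 2) / (n1 - 1)
    v2 = np.sum((x2 - np.mean(x2)) ** 2) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (np.mean(x1) - np.mean(x2)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def _pearson_oracle(x, y):
    """Textbook Pearson r with the exact t-transform p-value."""
    xc, yc = x - x.mean(), y - y.mean()
    r = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


def _two_group_frame(x1, x2, name="v"):
    return pd.DataFrame({
        "group": ["healthy"] * len(x1) + ["PD"] * len(x2),
        name: np.concatenate([x1, x2]),
    })


class TestNormalityGate:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(42).normal(size=500)
        res = normality_gate(x)
        assert res.normal

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(42).exponential(size=500)
        res = normality_gate(x)
        assert not res.normal

    def test_constant_sample_degenerate(self):
        res = normality_gate(np.ones(50))
        assert not res.normal
        assert res.p_value == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            normality_gate([1.0, 2.0, 3.0])

    def test_type_one_error_near_nominal(self):
        """Lilliefors gate rejects ~5% of genuinely normal samples."""
        rng = np.random.default_rng(0)
        rejections = sum(
            not normality_gate(rng.normal(size=100), alpha=0.05).normal
            for _ in range(200)
        )
        assert 2 <= rejections <= 25  # 5% nominal, generous band


class TestBonferroni:
    @pytest.mark.parametrize("base,m,expected", [
        (0.05, 25, 0.002),
        (0.05, 1, 0.05),
        (0.05, 17, 0.05 / 17),
        (0.05, 9, 0.05 / 9),
    ])
    def test_exact_division(self, base, m, expected):
        assert bonferroni_alpha(base, m) == pytest.approx(expected, abs=1e-15)

    def test_monotone_decreasing_in_m(self):
        alphas = [bonferroni_alpha(0.05, m) for m in range(1, 40)]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValidationError):
            bonferroni_alpha(1.5, 3)


class TestCompareGroups:
    def test_identical_groups_null(self):
        x = np.arange(10.0)
        rows = compare_groups(_two_group_frame(x, x), ["v"])
        assert rows[0].t_stat == pytest.approx(0.0, abs=1e-12)
        assert rows[0].p_value == pytest.approx(1.0)
        assert not rows[0].significant

    def test_matches_pooled_oracle_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n1, n2 = rng.integers(3, 50, 2)
            x1 = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n1)
            x2 = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n2)
            row = compare_groups(_two_group_frame(x1, x2), ["v"])[0]
            t, p = _pooled_t_oracle(x1, x2)
            assert row.t_stat == pytest.approx(t, abs=1e-10)
            assert row.p_value == pytest.approx(p, abs=1e-10)

    def test_cohort_scale_difference_significant(self):
        """Groups drawn at the reference cohort's mean-Hb scale separate at
        the 0.002 family level."""
        rng = np.random.default_rng(123)
        healthy = rng.normal(67, 11, 91)
        pd_grp = rng.normal(58, 19, 155)
        row = compare_groups(_two_group_frame(healthy, pd_grp), ["v"],
                             base_alpha=0.002)[0]
        t, p = _pooled_t_oracle(healthy, pd_grp)
        assert row.t_stat == pytest.approx(t, abs=1e-10)
        assert row.p_value < 0.002
        assert row.significant

    def test_single_variable_alpha_uncorrected(self):
        x = np.random.default_rng(1).normal(size=(2, 20))
        rows = compare_groups(_two_group_frame(x[0], x[1]), ["v"], base_alpha=0.05)
        assert rows[0].alpha_corrected == 0.05

    def test_zero_variance_degenerate_flagged(self):
        rows = compare_groups(_two_group_frame(np.ones(5), np.zeros(5)), ["v"])
        assert rows[0].degenerate
        rows = compare_groups(_two_group_frame(np.ones(5), np.ones(5)), ["v"])
        assert not rows[0].degenerate and rows[0].p_value == 1.0

    def test_null_calibration(self):
        """Under the null the family-level false-positive rate sits near the
        base alpha (within +/-50% relative) over 500 simulated cohorts."""
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(500):
            x1, x2 = rng.normal(size=(2, 30))[0], rng.normal(size=30)
            if compare_groups(_two_group_frame(x1, x2), ["v"], base_alpha=0.05)[0].significant:
                hits += 1
        assert 0.025 <= hits / 500 <= 0.075

    def test_welch_variant_differs_under_unequal_variance(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(0, 1, 20)
        x2 = rng.normal(0, 5, 60)
        pooled = compare_groups(_two_group_frame(x1, x2), ["v"])[0]
        welch = compare_groups(_two_group_frame(x1, x2), ["v"], welch=True)[0]
        assert pooled.p_value != welch.p_value


class TestCorrelate:
    def test_exact_linear_relations(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
        out = correlate(df, ["x"], ["y", "z"])
        assert out.loc[out.right == "y", "pearson_r"].item() == pytest.approx(1.0)
        assert out.loc[out.right == "z", "pearson_r"].item() == pytest.approx(-1.0)

    def test_self_correlation_is_one(self):
        x = np.random.default_rng(2).normal(size=50)
        df = pd.DataFrame({"x": x})
        out = correlate(df, ["x"], ["x"])
        assert out.pearson_r.item() == pytest.approx(1.0)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            x, y = rng.normal(size=(2, n))
            out = correlate(pd.DataFrame({"x": x, "y": y}), ["x"], ["y"])
            r, p = _pearson_oracle(x, y)
            assert out.pearson_r.item() == pytest.approx(r, abs=1e-10)
            assert out.p_value.item() == pytest.approx(p, abs=1e-10)

    def test_independent_columns_calibrated(self):
        """p-values of independent columns are ~uniform: the rejection rate
        at alpha=0.05 stays near 5% over 200 replicates (n=246 each)."""
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            x, y = rng.normal(size=(2, 246))
            ps.append(correlate(pd.DataFrame({"x": x, "y": y}), ["x"], ["y"]).p_value.item())
        ps = np.asarray(ps)
        assert np.abs(ps.mean() - 0.5) < 0.1
        assert 0.005 <= np.mean(ps < 0.05) <= 0.12

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        out = correlate(df, ["x"], ["y"])
        assert out.flagged.item()
        assert np.isnan(out.pearson_r.item())

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(InsufficientSampleError):
            correlate(df, ["x"], ["y"])


class TestReportTables:
    def _rows(self, n_vars=3, seed=0):
        rng = np.random.default_rng(seed)
        frames = {}
        for i in range(n_vars):
            frames[f"v{i}"] = np.concatenate([rng.normal(67, 11, 20), rng.normal(58, 19, 30)])
        df = pd.DataFrame(frames)
        df["group"] = ["healthy"] * 20 + ["PD"] * 30
        return compare_groups(df, [f"v{i}" for i in range(n_vars)])

    def test_structure_one_row(self):
        csv_text, md_text = report_tables(self._rows(1))
        assert len(csv_text.strip().splitlines()) == 2  # header + 1 data line
        assert "Variable" in md_text

    def test_family_of_25_rows(self):
        rows = self._rows(25)
        csv_text, md_text = report_tables(rows)
        assert len(csv_text.strip().splitlines()) == 26
        assert f"{rows[0].alpha_corrected:.4g}" in md_text

    def test_csv_round_trip(self):
        rows = self._rows(5, seed=3)
        csv_text, _ = report_tables(rows)
        back = pd.read_csv(io.StringIO(csv_text))
        for i, r in enumerate(rows):
            assert back.loc[i, "variable"] == r.variable
            assert back.loc[i, "p_value"] == pytest.approx(r.p_value, abs=1e-12)
            assert back.loc[i, "t_stat"] == pytest.approx(r.t_stat, abs=1e-12)
            assert back.loc[i, "mean1"] == pytest.approx(r.mean1, abs=1e-12)
            assert bool(back.loc[i, "significant"]) == r.significant
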