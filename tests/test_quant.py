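import math

import numpy as np
import pandas as pd
import pytest

from saltmir.quant import (
    densitometry_relative,
    luciferase_compare,
    paired_t,
    pfaffl_ratio,
    qpcr_relative_expression,
    significance_stars,
    simulate_luciferase_table,
    simulate_qpcr_table,
)


class TestPfaffl:
    def test_reference_cases(self):
        assert pfaffl_ratio(2.0, 1.0, 2.0, 0.0) == pytest.approx(2.0)
        assert pfaffl_ratio(2.0, 2.0, 2.0, 2.0) == pytest.approx(1.0)

    def test_against_log_space_computation(self):
        ratio = pfaffl_ratio(1.9, 1.5, 2.0, 0.5)
        log_ratio = 1.5 * math.log(1.9) - 0.5 * math.log(2.0)
        assert ratio == pytest.approx(math.exp(log_ratio))

    def test_reduces_to_two_power_neg_ddct(self):
        for dct_t, dct_r in [(1.0, 0.5), (-2.0, 1.0), (0.0, 0.0)]:
            ddct = dct_r - dct_t  # ddCt convention: treated-shift difference
            assert pfaffl_ratio(2.0, dct_t, 2.0, dct_r) == pytest.approx(2.0 ** -ddct)

    def test_efficiency_range_enforced(self):
        with pytest.raises(ValueError):
            pfaffl_ratio(2.5, 1.0)
        with pytest.raises(ValueError):
            pfaffl_ratio(1.0, 1.0)


class TestPairedT:
    def test_identical_vectors_give_p_one(self):
        assert paired_t([24.1, 24.5, 23.9], [24.1, 24.5, 23.9]) == 1.0

    def test_consistent_shift_is_significant(self):
        rng = np.random.default_rng(0)
        x = 24 + rng.normal(0, 0.01, 6)
        y = x + 1.0 + rng.normal(0, 0.01, 6)
        assert paired_t(list(x), list(y)) < 0.001

    def test_single_pair_is_error(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestDensitometry:
    def test_normalisation_direction(self):
        assert densitometry_relative(100, 50, 100, 50) == pytest.approx(1.0)
        assert densitometry_relative(100, 50, 200, 50) == pytest.approx(2.0)
        assert densitometry_relative(100, 50, 100, 25) == pytest.approx(2.0)

    def test_scale_invariance(self):
        base = densitometry_relative(120, 80, 90, 60)
        for c in (0.1, 3.0, 1e4):
            assert densitometry_relative(120 * c, 80 * c, 90 * c, 60 * c) == (
                pytest.approx(base)
            )

    def test_nonpositive_intensity_error(self):
        with pytest.raises(ValueError):
            densitometry_relative(0, 50, 100, 50)


class TestLuciferase:
    @staticmethod
    def _table(ratio_overexp, sd_frac=0.05, n=9, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group, mu in (("sensor_only", 1.0),
                          ("sensor_plus_overexpressor", ratio_overexp)):
            for leaf in range(n):
                r = rng.uniform(0.9, 1.1)
                rows.append({"pair": "LAO", "group": group, "leaf": leaf,
                             "f_luc": mu * (1 + rng.normal(0, sd_frac)) * r,
                             "r_luc": r})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        df = self._table(1.0, sd_frac=0.02)
        res = luciferase_compare(df, "LAO")
        assert res["p_value"] > 0.05
        assert res["stars"] == ""

    def test_halved_ratio_highly_significant(self):
        res = luciferase_compare(self._table(0.5), "LAO")
        assert res["p_value"] < 0.001
        assert res["stars"] == "***"
        assert res["mean_with_overexpressor"] < res["mean_sensor_only"]

    def test_zero_renilla_error(self):
        df = self._table(0.5)
        df.loc[0, "r_luc"] = 0.0
        with pytest.raises(ValueError):
            luciferase_compare(df, "LAO")

    def test_small_group_error(self):
        df = self._table(0.5, n=2)
        with pytest.raises(ValueError):
            luciferase_compare(df, "LAO")


class TestStars:
    def test_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.05) == ""


class TestQpcrRecovery:
    def test_programmed_fold_recovered(self):
        """Parameter recovery: the Pfaffl estimator applied to simulated
        qPCR data (n = 6, sigma(Ct) = 0.2) recovers the programmed fold; the
        median over replicate experiments lands within 15%."""
        fold = 0.4
        estimates = []
        for rep in range(25):
            table = simulate_qpcr_table({"LAO": fold}, seed=rep,
                                        tissues=("root",))
            res = qpcr_relative_expression(table)
            estimates.append(float(res["ratio"].iloc[0]))
        median = float(np.median(estimates))
        assert abs(median - fold) / fold <= 0.15

    def test_flat_gene_not_significant_and_shifted_gene_is(self):
        table = simulate_qpcr_table({"flat": 1.0, "up": 4.0}, seed=1,
                                    tissues=("root",), ct_sd=0.1)
        res = qpcr_relative_expression(table).set_index("gene")
        assert res.loc["up", "p_value"] < 0.01
        assert res.loc["up", "ratio"] > 2.0
        assert res.loc["flat", "p_value"] > 0.01
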