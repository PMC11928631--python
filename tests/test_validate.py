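"""LOB/LOD/LOQ, repeatability CV and probit hit-rate analysis."""

import numpy as np
import pytest
from scipy.stats import binom, norm

from dropquant.validate import (
    BlankPanel,
    cv_percent,
    limit_of_blank,
    limit_of_detection,
    limit_of_quantification,
    probit_c50,
    probit_hit_rate,
    repeatability_summary,
)

from conftest import TABLE1, TABLE1_GRAND_MEAN_CV


class TestCvPercent:
    @pytest.mark.parametrize("sample", sorted(TABLE1))
    def test_reproduces_printed_repeatability_rows(self, sample):
        reps, printed_mean, printed_cv = TABLE1[sample]
        mean, _, cv = cv_percent(reps)
        assert mean == pytest.approx(printed_mean, abs=5e-4)
        assert cv == pytest.approx(printed_cv, abs=5e-4)

    def test_constant_replicates_have_zero_cv(self):
        _, sd, cv = cv_percent([5.0, 5.0, 5.0])
        assert sd == 0.0 and cv == 0.0

    def test_uses_sample_standard_deviation(self):
        mean, sd, cv = cv_percent([1.0, 3.0])
        assert sd == pytest.approx(np.sqrt(2.0))  # n-1 denominator

    def test_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            cv_percent([1.0])
        with pytest.raises(ValueError, match="zero mean"):
            cv_percent([-1.0, 1.0])


class TestRepeatabilitySummary:
    def test_grand_mean_cv_matches_printed_table(self):
        table, mean_cv = repeatability_summary(
            {k: v[0] for k, v in TABLE1.items()}
        )
        assert len(table) == 8
        assert mean_cv == pytest.approx(TABLE1_GRAND_MEAN_CV, abs=0.01)

    def test_single_sample_mean_equals_its_cv(self):
        table, mean_cv = repeatability_summary({"a": [1.0, 2.0, 3.0]})
        assert mean_cv == pytest.approx(table.loc[0, "cv_pct"])

    def test_mean_of_two_cvs(self):
        # CVs engineered at 10% and 30% via scaled copies of one triple
        base = np.array([0.9, 1.0, 1.1])  # CV = 10%
        table, mean_cv = repeatability_summary(
            {"a": base, "b": 1 + 3 * (base - 1)}
        )
        assert mean_cv == pytest.approx(20.0, rel=1e-6)

    def test_error_tags_offending_sample(self):
        with pytest.raises(ValueError, match="bad_sample"):
            repeatability_summary({"ok": [1.0, 2.0], "bad_sample": [3.0]})


class TestLimitOfBlank:
    def test_22_clean_blanks_give_zero(self):
        assert limit_of_blank(BlankPanel((0.0,) * 22)) == 0.0

    def test_one_outlier_blank(self):
        lob = limit_of_blank(BlankPanel((0.0, 0.0, 0.0, 1.0)))
        assert lob == pytest.approx(0.25 + 1.645 * 0.5)

    def test_constant_nonzero_blanks_give_that_constant(self):
        assert limit_of_blank(BlankPanel((0.3,) * 10)) == pytest.approx(0.3)

    def test_panel_validation(self):
        with pytest.raises(ValueError):
            BlankPanel((0.0,))
        with pytest.raises(ValueError):
            BlankPanel((0.0, -1.0))


class TestLimitOfDetection:
    def test_worked_example_at_lowest_dilution(self):
        lod = limit_of_detection(0.0, sd=0.00007)
        assert lod == pytest.approx(0.000115, abs=1e-6)
        # reported to one significant figure
        assert float(f"{lod:.1g}") == pytest.approx(0.0001)

    def test_zero_sd_reduces_to_lob(self):
        assert limit_of_detection(0.42, sd=0.0) == 0.42

    def test_arithmetic(self):
        assert limit_of_detection(0.5, sd=0.1) == pytest.approx(0.6645)

    def test_sd_computed_from_replicates(self):
        reps = [1.0, 1.2, 0.8]
        lod = limit_of_detection(0.0, lowest_level_replicates=reps)
        assert lod == pytest.approx(1.645 * np.std(reps, ddof=1))

    def test_lod_at_least_lob(self):
        assert limit_of_detection(0.9, sd=0.05) >= 0.9

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            limit_of_detection(0.0)


def _level_with_cv(mean, cv_pct):
    """Three replicates with exactly the requested mean and CV.

    For [m-d, m, m+d] the sample (ddof=1) SD is exactly d.
    """
    d = cv_pct / 100.0 * mean
    reps = [mean - d, mean, mean + d]
    got = 100 * np.std(reps, ddof=1) / np.mean(reps)
    return reps, got


class TestLimitOfQuantification:
    def test_lowest_qualifying_level_selected(self):
        # CV pattern 27 / 40 / 25 / 20 with cap 35: the lowest level wins
        # even though an intermediate level fails
        levels = []
        for conc, cv in zip([0.016, 0.0016, 0.0006, 0.0003],
                            [27.0, 40.0, 25.0, 20.0]):
            reps, _ = _level_with_cv(conc, cv)
            levels.append((f"dil_{conc:g}", conc, reps))
        label, mean_conc, cv = limit_of_quantification(levels, cv_max_pct=35.0)
        assert label == "dil_0.0003"
        assert mean_conc == pytest.approx(0.0003)
        assert cv < 35.0

    def test_no_level_qualifies(self):
        reps, _ = _level_with_cv(1.0, 80.0)
        label, mean_conc, cv = limit_of_quantification(
            [("only", 1.0, reps)], cv_max_pct=35.0
        )
        assert label == "not reached" and mean_conc is None

    def test_cv_cap_is_inclusive(self):
        reps, got_cv = _level_with_cv(1.0, 35.0)
        label, _, cv = limit_of_quantification(
            [("only", 1.0, reps)], cv_max_pct=got_cv
        )
        assert label == "only"
        assert cv == pytest.approx(got_cv)

    def test_unsorted_levels_rejected(self):
        reps, _ = _level_with_cv(1.0, 10.0)
        with pytest.raises(ValueError, match="descending"):
            limit_of_quantification([("lo", 0.1, reps), ("hi", 1.0, reps)])
        with pytest.raises(ValueError, match="levels"):
            limit_of_quantification([])


def _grid_probit_ml(data, a_grid, b_grid):
    """Independent maximum-likelihood oracle on a parameter grid."""
    best = (-np.inf, None, None)
    logc = np.log10([c for _, _, c in data])
    ks = np.array([k for k, _, _ in data])
    ns = np.array([n for _, n, _ in data])
    for a in a_grid:
        p = np.clip(norm.cdf(a + np.outer(b_grid, logc)), 1e-12, 1 - 1e-12)
        ll = binom.logpmf(ks, ns, p).sum(axis=1)
        i = int(np.argmax(ll))
        if ll[i] > best[0]:
            best = (ll[i], a, b_grid[i])
    return best


class TestProbitHitRate:
    def test_all_levels_detected_is_degenerate(self):
        table, fit = probit_hit_rate(
            [(3, 3, 0.016), (3, 3, 0.0016), (3, 3, 0.0006), (3, 3, 0.0003)]
        )
        assert (table["hit_rate"] == 1.0).all()
        assert fit == "degenerate"

    def test_single_all_miss_level_is_degenerate(self):
        table, fit = probit_hit_rate([(0, 3, 0.001)])
        assert table.loc[0, "hit_rate"] == 0.0
        assert fit == "degenerate"

    def test_varying_rates_match_grid_search_ml_oracle(self):
        data = [(9, 10, 1.0), (5, 10, 0.1), (1, 10, 0.01)]
        table, fit = probit_hit_rate(data)
        assert isinstance(fit, tuple)
        a, b = fit
        ll_fit = _grid_probit_ml(data, [a], np.array([b]))[0]
        ll_grid, ga, gb = _grid_probit_ml(
            data, np.linspace(-5, 5, 201), np.linspace(0.05, 5, 200)
        )
        assert ll_fit >= ll_grid - 1e-3  # GLM at least as good as the grid
        assert probit_c50(fit) == pytest.approx(10 ** (-ga / gb), rel=0.05)

    def test_separated_rates_put_c50_between_outer_levels(self):
        table, fit = probit_hit_rate(
            [(10, 10, 1.0), (5, 10, 0.1), (0, 10, 0.01)]
        )
        assert isinstance(fit, tuple)
        assert fit[1] > 0  # monotone increasing in concentration
        assert 0.01 < probit_c50(fit) < 1.0

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError, match="zero replicates"):
            probit_hit_rate([(0, 0, 0.1)])
        with pytest.raises(ValueError):
            probit_hit_rate([(5, 3, 0.1)])
        with pytest.raises(ValueError):
            probit_hit_rate([])
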