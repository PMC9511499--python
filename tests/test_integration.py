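"""Matched-control z-normalization and bimodal peak normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from arrestmap.integration import (
    UnimodalError,
    apply_matched_normalization,
    detect_bimodal_peaks,
    fit_control_stats,
    peak_normalize,
)
from arrestmap.io import FeatureTable


def _table(control_vals, treated_vals, feat="x_nucleus_median"):
    n_c, n_t = len(control_vals), len(treated_vals)
    return FeatureTable(
        pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n_c + n_t)],
                "condition": ["control"] * n_c + ["etoposide_d3"] * n_t,
                "replicate": "r1",
                feat: list(control_vals) + list(treated_vals),
            }
        )
    )


class TestControlStats:
    def test_sample_sd_on_1_2_3(self):
        params = fit_control_stats(_table([1, 2, 3], []), "control")
        assert params.mean["x_nucleus_median"] == 2.0
        assert params.std["x_nucleus_median"] == 1.0  # (n-1) sd

    def test_constant_feature_excluded(self):
        params = fit_control_stats(_table([5, 5, 5], []), "control")
        assert "x_nucleus_median" in params.excluded
        assert "x_nucleus_median" not in params.mean

    def test_matches_brute_force_on_random_table(self, rng):
        vals = rng.normal(10, 3, size=200)
        params = fit_control_stats(_table(vals, rng.normal(0, 1, 50)), "control")
        assert params.mean["x_nucleus_median"] == pytest.approx(vals.mean())
        assert params.std["x_nucleus_median"] == pytest.approx(vals.std(ddof=1))

    def test_no_control_cells_is_an_error(self):
        with pytest.raises(ValueError, match="no cells"):
            fit_control_stats(_table([], [1, 2, 3]), "control")

    def test_missing_values_never_enter_stats(self, rng):
        vals = list(rng.normal(0, 1, 50)) + [np.nan, np.nan]
        params = fit_control_stats(_table(vals, []), "control")
        finite = np.array(vals[:-2])
        assert params.mean["x_nucleus_median"] == pytest.approx(finite.mean())


class TestMatchedNormalization:
    def test_control_subset_mean0_sd1(self, rng):
        table = _table(rng.normal(7, 2, 300), rng.normal(12, 2, 100))
        out = apply_matched_normalization(table, fit_control_stats(table, "control"))
        ctrl = out.data[out.data["condition"] == "control"]["x_nucleus_median"]
        assert ctrl.mean() == pytest.approx(0.0, abs=1e-12)
        assert ctrl.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_treated_cell_two_sigma_above_control_maps_to_2(self):
        table = _table([1, 2, 3], [2 + 2 * 1.0])
        out = apply_matched_normalization(table, fit_control_stats(table, "control"))
        treated = out.data[out.data["condition"] != "control"]["x_nucleus_median"]
        assert treated.iloc[0] == pytest.approx(2.0)

    def test_rank_order_of_treated_cells_preserved(self, rng):
        raw = rng.lognormal(2, 1, 150)
        table = _table(rng.normal(5, 1, 100), raw)
        out = apply_matched_normalization(table, fit_control_stats(table, "control"))
        normed = out.data[out.data["condition"] != "control"]["x_nucleus_median"]
        assert spearmanr(raw, normed).statistic == pytest.approx(1.0)

    def test_feature_missing_from_params_is_an_error(self, rng):
        table = _table(rng.normal(0, 1, 20), [])
        params = fit_control_stats(table, "control")
        bigger = table.with_columns(extra_nucleus_median=np.ones(20))
        with pytest.raises(ValueError, match="extra_nucleus_median"):
            apply_matched_normalization(bigger, params)

    def test_fit_apply_twice_equals_once(self, rng):
        """Refit on normalized controls gives mu=0, sd=1: second pass is identity."""
        table = _table(rng.normal(7, 2, 200), rng.normal(9, 3, 80))
        once = apply_matched_normalization(table, fit_control_stats(table, "control"))
        twice = apply_matched_normalization(once, fit_control_stats(once, "control"))
        np.testing.assert_allclose(
            twice.data["x_nucleus_median"], once.data["x_nucleus_median"], atol=1e-12
        )

    def test_normalization_commutes_with_treated_subsetting(self, rng):
        table = _table(rng.normal(7, 2, 100), rng.normal(9, 3, 80))
        params = fit_control_stats(table, "control")
        full = apply_matched_normalization(table, params)
        mask = (table.data["condition"] != "control") & (np.arange(180) % 2 == 0)
        sub = apply_matched_normalization(table.subset(mask), params)
        np.testing.assert_allclose(
            sub.data["x_nucleus_median"].to_numpy(),
            full.data.loc[mask.to_numpy(), "x_nucleus_median"].to_numpy(),
        )


class TestPeakDetection:
    def test_equal_mixture_of_tight_gaussians(self, rng):
        vals = np.concatenate([rng.normal(100, 5, 2500), rng.normal(200, 5, 2500)])
        lo, hi = detect_bimodal_peaks(vals)
        assert abs(lo - 100) / 100 < 0.02
        assert abs(hi - 200) / 200 < 0.02

    def test_single_gaussian_raises_unimodal(self, rng):
        with pytest.raises(UnimodalError):
            detect_bimodal_peaks(rng.normal(100, 5, 5000))

    def test_unequal_weights_both_modes_recovered(self, rng):
        vals = np.concatenate([rng.normal(100, 5, 4000), rng.normal(200, 5, 1000)])
        lo, hi = detect_bimodal_peaks(vals)
        assert abs(lo - 100) / 100 < 0.05
        assert abs(hi - 200) / 200 < 0.05

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            detect_bimodal_peaks(rng.normal(0, 1, 50))


class TestPeakNormalize:
    def test_affine_midpoint(self):
        out = peak_normalize(np.array([150.0]), 100, 200, 2, 4)
        assert out[0] == pytest.approx(3.0)

    def test_identity_when_peaks_equal_targets(self, rng):
        vals = rng.normal(3, 1, 100)
        np.testing.assert_allclose(peak_normalize(vals, 2, 4, 2, 4), vals)

    def test_exact_at_both_anchors(self):
        out = peak_normalize(np.array([0.3, 0.9]), 0.3, 0.9, 0.0, 1.0)
        np.testing.assert_allclose(out, [0.0, 1.0])

    def test_degenerate_peaks_rejected(self):
        with pytest.raises(ValueError):
            peak_normalize(np.array([1.0]), 5, 5, 0, 1)

    @settings(deadline=None, derandomize=True)
    @given(
        lo=st.floats(-100, 100),
        width=st.floats(0.1, 100),
        lo_t=st.floats(-10, 10),
        width_t=st.floats(0.1, 10),
        v=st.floats(-500, 500),
    )
    def test_swapped_anchor_composition_is_identity(self, lo, width, lo_t, width_t, v):
        """peak_normalize then the inverse anchor map returns the input."""
        hi, hi_t = lo + width, lo_t + width_t
        forward = peak_normalize(np.array([v]), lo, hi, lo_t, hi_t)
        back = peak_normalize(forward, lo_t, hi_t, lo, hi)
        assert back[0] == pytest.approx(v, abs=1e-6 * max(1.0, abs(v)))

    def test_population_dna_modes_land_on_2_and_4(self, small_population):
        """Raw 2C/4C modes map to modes at 2 and 4 of the normalized sample."""
        vals = small_population.data["dna_nucleus_integrated"].to_numpy()
        lo, hi = detect_bimodal_peaks(vals)
        normed = peak_normalize(vals, lo, hi, 2, 4)
        lo2, hi2 = detect_bimodal_peaks(normed)
        assert lo2 == pytest.approx(2.0, abs=0.1)
        assert hi2 == pytest.approx(4.0, abs=0.2)
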