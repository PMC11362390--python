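"""Midline distances, distance categories, and Cohen's kappa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from lsci.agreement import (
    MidlinePath,
    cohens_kappa,
    fraction_within,
    placement_categories,
    signed_midline_distance,
    simulate_placements,
)
from lsci.errors import ConfigurationError, DataError, UsageError


@pytest.fixture
def straight_midline():
    return MidlinePath(points=[(256.0, 0.0), (256.0, 511.0)], pixel_size=0.01,
                       ischemic_direction="end")


class TestSignedDistance:
    def test_identity_is_zero(self, straight_midline):
        assert signed_midline_distance(straight_midline, (256, 300), (256, 300)) == 0.0

    def test_arclength_difference_scaled_to_cm(self, straight_midline):
        # 120 px along the line at 0.01 cm/px, toward the ischemic end
        d = signed_midline_distance(straight_midline, (256, 300), (258, 420))
        assert d == pytest.approx(1.2)

    def test_direction_reversal_flips_sign(self):
        ml = MidlinePath(points=[(256.0, 0.0), (256.0, 511.0)], pixel_size=0.01,
                         ischemic_direction="start")
        d = signed_midline_distance(ml, (256, 300), (258, 420))
        assert d == pytest.approx(-1.2)

    def test_point_off_midline_rejected(self, straight_midline):
        with pytest.raises(DataError):
            signed_midline_distance(straight_midline, (256, 300), (400, 300))

    def test_projection_on_bent_midline(self):
        ml = MidlinePath(points=[(0.0, 0.0), (0.0, 100.0), (100.0, 100.0)],
                         pixel_size=0.01)
        # nearest point of (50, 90) is (50, 100) at arclength 150 px
        d = signed_midline_distance(ml, (0, 0), (50, 90))
        assert d == pytest.approx(1.5)

    def test_degenerate_midline_rejected(self):
        with pytest.raises(ConfigurationError):
            MidlinePath(points=[(0.0, 0.0)], pixel_size=0.01)
        with pytest.raises(ConfigurationError):
            MidlinePath(points=[(0.0, 0.0), (0.0, 0.0)], pixel_size=0.01)


class TestFractionWithin:
    @pytest.mark.parametrize(
        "limit, expected", [(1.0, 0.5), (2.0, 0.75)]
    )
    def test_reported_fractions(self, limit, expected):
        res = fraction_within([0.5, -0.8, 1.2, 2.5], limit)
        assert res.fraction == pytest.approx(expected)

    def test_all_zero_distances(self):
        assert fraction_within([0.0, 0.0, 0.0], 1.0).fraction == 1.0

    def test_missing_excluded_and_counted(self):
        res = fraction_within([0.5, np.nan, 1.5], 1.0)
        assert res.fraction == pytest.approx(0.5)
        assert res.n_used == 2 and res.n_missing == 1

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            fraction_within([], 1.0)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30),
           st.floats(0.1, 3.0), st.floats(0.0, 2.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_limit(self, dists, limit, bump):
        lo = fraction_within(dists, limit).fraction
        hi = fraction_within(dists, limit + bump).fraction
        assert hi >= lo


class TestCategories:
    def test_default_bins(self):
        cats = placement_categories([0.0, -1.5, 1.0, -1.0, 2.0, np.nan])
        assert cats == ["within", "toward_well", "within", "toward_well",
                        "toward_ischemic", "missing"]

    def test_bad_edges_rejected(self):
        with pytest.raises(ConfigurationError):
            placement_categories([0.0], bin_edges=(1.0, -1.0))


class TestCohensKappa:
    def test_identical_raters(self):
        res = cohens_kappa(["a", "b", "a", "c"], ["a", "b", "a", "c"])
        assert res.kappa == pytest.approx(1.0)

    def test_chance_level_agreement(self):
        res = cohens_kappa([1, 1, 2, 2], [1, 2, 1, 2])
        assert res.kappa == pytest.approx(0.0)
        assert res.p_observed == pytest.approx(0.5)
        assert res.p_expected == pytest.approx(0.5)

    def test_known_confusion_table(self):
        # table [[20, 5], [10, 15]]: po = 0.7, pe = 0.5, kappa = 0.4
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        res = cohens_kappa(a, b, seed=1)
        assert res.kappa == pytest.approx(0.4)
        assert res.p_observed == pytest.approx(0.7)
        assert res.p_expected == pytest.approx(0.5)
        assert res.ci_low < 0.4 < res.ci_high

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        k1 = cohens_kappa(a, b, n_bootstrap=50).kappa
        k2 = cohens_kappa(b, a, n_bootstrap=50).kappa
        assert k1 == pytest.approx(k2)
        relabel = np.array(["low", "mid", "high"])
        k3 = cohens_kappa(relabel[a], relabel[b], n_bootstrap=50).kappa
        assert k3 == pytest.approx(k1)

    def test_undefined_when_both_raters_constant(self):
        res = cohens_kappa(["a", "a", "a"], ["a", "a", "a"])
        assert not res.defined and np.isnan(res.kappa)

    @given(
        st.lists(st.integers(0, 2), min_size=2, max_size=12),
        st.data(),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_contingency_oracle(self, a, data):
        b = data.draw(st.lists(st.integers(0, 2), min_size=len(a), max_size=len(a)))
        res = cohens_kappa(a, b, n_bootstrap=0)
        n = len(a)
        po = sum(x == y for x, y in zip(a, b)) / n
        pe = sum(
            (sum(x == c for x in a) / n) * (sum(y == c for y in b) / n)
            for c in set(a) | set(b)
        )
        if pe >= 1.0:
            assert not res.defined
        else:
            assert res.kappa == pytest.approx((po - pe) / (1 - pe))
            assert res.kappa == pytest.approx(cohen_kappa_score(a, b))


class TestObserverModel:
    def test_configured_drift_fraction_recovered(self, straight_midline):
        """Fraction of placements toward ischemia matches Phi(mean/sd)."""
        refs = pd.DataFrame(
            [
                {"loop_id": f"L{i:02d}", "timepoint": tp, "side": "watershed_left",
                 "row": 256.0, "col": 250.0}
                for i in range(12)
                for tp in ("T0", "T60", "T120")
            ]
        )
        placements = simulate_placements(
            straight_midline, refs, shift_mean_cm=0.6, shift_sd_cm=0.8,
            missing_rate=0.0, seed=10,
        )
        d = np.array(
            [
                signed_midline_distance(straight_midline, (256.0, 250.0), (r, c))
                for r, c in zip(placements.row, placements.col)
            ]
        )
        from scipy.stats import norm

        p_expected = norm.cdf(0.6 / 0.8)
        p_hat = float(np.mean(d > 0))
        se = np.sqrt(p_expected * (1 - p_expected) / len(d))
        assert abs(p_hat - p_expected) < 3 * se

    def test_missing_rate_produces_nan_rows(self, straight_midline):
        refs = pd.DataFrame(
            [{"loop_id": "L01", "timepoint": "T0", "side": "watershed_left",
              "row": 256.0, "col": 250.0}] * 30
        )
        placements = simulate_placements(
            straight_midline, refs, missing_rate=0.5, seed=0
        )
        assert 0 < placements.row.isna().sum() < len(placements)
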