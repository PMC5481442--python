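"""Isotopic niche metrics: delta notation, trophic levels, Layman metrics,
standard ellipses and overlap."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import layman_brute_force, points_with_moments, unit_circle_points
from isofoodweb.exceptions import (
    DegenerateGeometryError,
    InsufficientDataError,
    MissingBaselineError,
    UndefinedInputError,
)
from isofoodweb.niche import (
    bayesian_sea,
    delta_notation,
    ellipse_overlap,
    layman_metrics,
    select_baseline,
    standard_ellipse_area,
    summarize_niche,
    trophic_level,
    trophic_level_table,
)


class TestDeltaNotation:
    @pytest.mark.parametrize(
        "rs, rstd, expected",
        [(0.011, 0.011, 0.0), (0.011 * 1.001, 0.011, 1.0), (0.0, 0.011, -1000.0)],
    )
    def test_examples(self, rs, rstd, expected):
        assert delta_notation(rs, rstd) == pytest.approx(expected, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(UndefinedInputError):
            delta_notation(0.01, 0.0)


class TestTrophicLevel:
    def test_baseline_maps_to_lambda(self):
        assert trophic_level(4.2, 4.2) == pytest.approx(2.0, abs=1e-15)

    def test_one_full_step(self):
        assert trophic_level(6.7, 4.2, delta_n=2.5) == pytest.approx(3.0)

    def test_printed_upper_value(self):
        # a consumer 3.075 permil above the baseline sits at TL 3.23
        assert trophic_level(3.075, 0.0) == pytest.approx(3.23, abs=1e-12)

    def test_affine_with_slope_one_over_delta_n(self):
        b = 1.7
        pts = np.array([0.0, 2.0, 5.0])
        tls = trophic_level(pts, b, delta_n=2.5)
        slopes = np.diff(tls) / np.diff(pts)
        assert np.allclose(slopes, 1 / 2.5, atol=1e-12)

    def test_no_clamping_below_lambda(self):
        assert trophic_level(0.0, 1.0) < 2.0

    def test_domain_error(self):
        with pytest.raises(UndefinedInputError):
            trophic_level(1.0, 0.0, delta_n=0.0)


class TestSelectBaseline:
    def records(self):
        return pd.DataFrame(
            {
                "entity": ["A"] * 3 + ["B"] * 5 + ["C"] * 2,
                "entity_class": "consumer",
                "site": "s1",
                "d15N": [1.0, 1.1, 0.9, 0.2, 0.1, 0.15, 0.2, 0.1, 5.0, 5.1],
                "d13C": 0.0,
            }
        )

    def test_single_candidate(self):
        assert select_baseline(self.records(), {"A"}, site="s1") == "A"

    def test_argmin_of_mean(self):
        assert select_baseline(self.records(), {"A", "B"}, site="s1") == "B"

    def test_tie_breaks_by_n_then_label(self):
        df = pd.DataFrame(
            {
                "entity": ["A"] * 2 + ["B"] * 3 + ["C"] * 3,
                "site": "s1",
                "d15N": [1.0, 1.0] + [1.0] * 3 + [1.0] * 3,
            }
        )
        # equal means: larger n wins; equal n: lexicographic
        assert select_baseline(df, {"A", "B", "C"}, site="s1") == "B"

    def test_missing_baseline(self):
        with pytest.raises(MissingBaselineError):
            select_baseline(self.records(), {"Z"}, site="s1")


class TestTrophicLevelTable:
    def test_baseline_entity_sits_at_lambda(self):
        df = pd.DataFrame(
            {
                "entity": ["base"] * 4 + ["cons"] * 4,
                "entity_class": "consumer",
                "site": "s1",
                "d15N": [1.0, 1.2, 0.8, 1.0, 3.5, 3.6, 3.4, 3.5],
                "d13C": 0.0,
            }
        )
        tab = trophic_level_table(df, "base", site="s1").set_index("entity")
        assert tab.loc["base", "TL"] == pytest.approx(2.0)
        assert tab.loc["cons", "TL"] == pytest.approx(2.0 + 2.5 / 2.5, abs=0.01)
        assert (tab["TL_sd"] >= 0).all()


class TestLaymanMetrics:
    def test_unit_square(self):
        nr, cr, cd, nnd, sdnnd = layman_metrics(
            [(0, 0), (1, 0), (0, 1), (1, 1)]
        )
        assert (nr, cr) == (1.0, 1.0)
        assert cd == pytest.approx(math.sqrt(2) / 2)
        assert nnd == pytest.approx(1.0)
        assert sdnnd == pytest.approx(0.0)

    def test_two_point_345_triangle(self):
        nr, cr, cd, nnd, sdnnd = layman_metrics([(0, 0), (3, 4)])
        assert (nr, cr, cd, nnd, sdnnd) == pytest.approx((4, 3, 2.5, 5, 0))

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_matches_brute_force_oracle(self, n, rng):
        for _ in range(20):
            pts = rng.normal(size=(n, 2)) * 3
            got = layman_metrics(pts)
            expected = layman_brute_force(pts)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_translation_invariance_and_scale_equivariance(self, rng):
        pts = rng.normal(size=(6, 2))
        base = np.array(layman_metrics(pts))
        shifted = np.array(layman_metrics(pts + [13.0, -4.0]))
        assert shifted == pytest.approx(base, abs=1e-9)
        scaled = np.array(layman_metrics(pts * 2.5))
        assert scaled == pytest.approx(base * 2.5, abs=1e-9)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            layman_metrics([(0, 0)])


class TestStandardEllipse:
    def test_identity_covariance_gives_pi(self, rng):
        pts = points_with_moments(40, (0, 0), np.eye(2), rng)
        assert standard_ellipse_area(pts, corrected=False) == pytest.approx(
            math.pi, abs=1e-9
        )

    def test_correction_factor_exact(self, rng):
        for n in range(3, 51):
            pts = rng.normal(size=(n, 2))
            sea = standard_ellipse_area(pts, corrected=False)
            seac = standard_ellipse_area(pts, corrected=True)
            assert seac / sea == pytest.approx((n - 1) / (n - 2), rel=1e-12)
            assert seac > sea

    def test_monte_carlo_limit(self, rng):
        pts = rng.normal(size=(10_000, 2)) * [2.0, 1.0]
        assert standard_ellipse_area(pts) == pytest.approx(2 * math.pi, rel=0.05)

    def test_rotation_and_axis_exchange_invariance(self, rng):
        pts = rng.normal(size=(30, 2)) * [3.0, 1.0]
        sea = standard_ellipse_area(pts)
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        assert standard_ellipse_area(pts @ rot.T) == pytest.approx(sea, rel=1e-9)
        assert standard_ellipse_area(pts[:, ::-1]) == pytest.approx(sea, rel=1e-9)

    def test_collinear_points_degenerate(self):
        pts = [(0, 0), (1, 1), (2, 2), (3, 3)]
        with pytest.raises(DegenerateGeometryError):
            standard_ellipse_area(pts)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            standard_ellipse_area([(0, 0), (1, 1)])


class TestBayesianSEA:
    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(25, 2))
        a = bayesian_sea(pts, n_draws=2000, seed=5)
        b = bayesian_sea(pts, n_draws=2000, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, bayesian_sea(pts, n_draws=2000, seed=6))

    def test_draws_strictly_positive(self, rng):
        pts = rng.normal(size=(10, 2))
        assert (bayesian_sea(pts, n_draws=2000, seed=0) > 0).all()

    def test_posterior_concentrates_on_analytic_area(self, rng):
        pts = points_with_moments(200, (0, 0), np.eye(2), rng)
        draws = bayesian_sea(pts, n_draws=4000, seed=1)
        assert np.median(draws) == pytest.approx(math.pi, rel=0.10)

    def test_insufficient_points(self, rng):
        with pytest.raises(InsufficientDataError):
            bayesian_sea(rng.normal(size=(3, 2)), seed=0)


class TestEllipseOverlap:
    def test_identical_sets_overlap_equals_seac(self, rng):
        pts = rng.normal(size=(30, 2))
        seac = standard_ellipse_area(pts)
        ov = ellipse_overlap(pts, pts, resolution=800)
        assert ov == pytest.approx(seac, rel=0.01)

    def test_separated_ellipses_zero(self, rng):
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(20, 2)) + [100.0, 100.0]
        assert ellipse_overlap(a, b, resolution=400) == 0.0

    def test_unit_circle_lens_closed_form(self, rng):
        a = unit_circle_points(50, (0.0, 0.0), rng)
        b = unit_circle_points(50, (1.0, 0.0), rng)
        lens = 2 * math.pi / 3 - math.sqrt(3) / 2
        assert ellipse_overlap(a, b, resolution=2000) == pytest.approx(
            lens, rel=0.01
        )

    def test_symmetric_and_bounded(self, rng):
        a = rng.normal(size=(25, 2))
        b = rng.normal(size=(25, 2)) + [0.5, 0.5]
        o1 = ellipse_overlap(a, b, resolution=600)
        o2 = ellipse_overlap(b, a, resolution=600)
        assert o1 == pytest.approx(o2, rel=1e-12)
        assert o1 <= min(standard_ellipse_area(a), standard_ellipse_area(b))


class TestNicheSummary:
    def test_summary_consistent_with_components(self, rng):
        spec = rng.normal(size=(40, 2))
        spp = rng.normal(size=(8, 2))
        ns = summarize_niche(spec, spp, n_draws=1500, seed=3)
        assert ns.SEAc == pytest.approx(standard_ellipse_area(spec))
        assert ns.NR == pytest.approx(layman_metrics(spp).NR)
        assert ns.n_points == 40
        assert (ns.SEA_posterior > 0).all()
        assert ns.SEAc > ns.SEA
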