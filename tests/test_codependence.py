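import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hbnet.codependence import (
    LBSubset,
    adjacency_correlation,
    class_extrema,
    compare_regressions,
    conic_fit,
    correlation_table,
    lineweaver_burk,
    marker_group_tests,
    per_state_conic_fits,
    rank_order_category,
    sign_reversal_table,
    tprime_scores,
    vector_amplitude,
)
from hbnet.network import adjacency_suite
from hbnet.state_space import decode_transition, transition_class


def _hyperbola_points(a=1.0, b=1.0, n=80, angle=0.0, center=(0.0, 0.0), rng=None,
                      noise=0.0):
    """Points on (x/a)^2 - (y/b)^2 = 1 (both branches), optionally rotated."""
    t = np.linspace(-1.5, 1.5, n // 2)
    x = np.concatenate([a * np.cosh(t), -a * np.cosh(t)])
    y = np.concatenate([b * np.sinh(t), b * np.sinh(t)])
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        x, y = c * x - s * y, s * x + c * y
    x, y = x + center[0], y + center[1]
    if noise and rng is not None:
        x = x + rng.normal(0, noise, x.shape)
        y = y + rng.normal(0, noise, y.shape)
    return np.column_stack([x, y])


class TestAdjacencyCorrelation:
    def test_perfect_positive(self, rng):
        a = rng.normal(size=100)
        assert adjacency_correlation(a, 2 * a) == pytest.approx(1.0)

    def test_perfect_negative(self, rng):
        a = rng.normal(size=100)
        assert adjacency_correlation(a, -a + 3.0) == pytest.approx(-1.0)

    def test_missing_values_excluded(self, rng):
        a = rng.normal(size=100)
        b = 2 * a
        b[:50] = np.nan
        assert adjacency_correlation(a, b) == pytest.approx(1.0)

    def test_too_few_points(self):
        a = np.full(100, np.nan)
        a[:2] = [1.0, 2.0]
        with pytest.raises(ValueError):
            adjacency_correlation(a, a)

    def test_153_unique_pairs(self, geometry, small_series):
        suite = adjacency_suite(small_series[0], geometry)
        table = correlation_table(suite)
        assert len(table) == 153


class TestConicFit:
    def test_canonical_hyperbola(self):
        fit = conic_fit(_hyperbola_points())
        assert fit.kind == "hyperbola"
        assert fit.discriminant > 0
        verts = fit.vertices[np.argsort(fit.vertices[:, 0])]
        np.testing.assert_allclose(verts, [[-1, 0], [1, 0]], atol=1e-6)
        np.testing.assert_allclose(fit.evaluate(verts[:, 0], verts[:, 1]), 0, atol=1e-9)

    def test_canonical_circle_is_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        fit = conic_fit(np.column_stack([np.cos(t), np.sin(t)]))
        assert fit.kind == "ellipse"
        assert fit.discriminant < 0

    def test_collinear_degenerate_flag_no_crash(self):
        x = np.linspace(0, 1, 10)
        fit = conic_fit(np.column_stack([x, 2 * x + 1]))
        assert fit.degenerate

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            conic_fit(np.zeros((5, 2)))

    def test_vertices_and_foci_on_conic(self, rng):
        fit = conic_fit(_hyperbola_points(a=2.0, b=0.5, angle=0.6, center=(1.0, -2.0)))
        assert fit.kind == "hyperbola"
        scale = np.max(np.abs(fit.coeffs))
        for pts in (fit.vertices,):
            np.testing.assert_allclose(
                fit.evaluate(pts[:, 0], pts[:, 1]) / scale, 0.0, atol=1e-8
            )
        # foci satisfy the focal-distance property |d1 - d2| = 2a
        t = np.linspace(-1.0, 1.0, 7)
        branch = np.column_stack([2.0 * np.cosh(t), 0.5 * np.sinh(t)])
        c, s = np.cos(0.6), np.sin(0.6)
        branch = branch @ np.array([[c, s], [-s, c]]) + [1.0, -2.0]
        d1 = np.hypot(*(branch - fit.foci[0]).T)
        d2 = np.hypot(*(branch - fit.foci[1]).T)
        np.testing.assert_allclose(np.abs(d1 - d2), 4.0, rtol=1e-6)

    def test_rational_curve_vertex_recovery(self, rng):
        # y = 5x/(2+x) is the hyperbola (2+x)y - 5x = 0; recovery from noisy
        # samples is checked against a noise-free dense refit oracle
        x = np.linspace(-1.0, 8.0, 200)
        y = 5.0 * x / (2.0 + x)
        dense = conic_fit(np.column_stack([x, y]))
        noisy = conic_fit(
            np.column_stack(
                [x, y + np.random.default_rng(0).normal(0, 0.01, x.shape)]
            )
        )
        assert dense.kind == "hyperbola" and noisy.kind == "hyperbola"
        ref = dense.vertices[np.argsort(dense.vertices[:, 0])]
        got = noisy.vertices[np.argsort(noisy.vertices[:, 0])]
        span = np.linalg.norm(ref[0] - ref[1])
        assert np.linalg.norm(got - ref, axis=1).max() < 0.05 * span

    def test_prescale_reported_in_original_units(self):
        pts = _hyperbola_points(a=1e-6, b=1.0)
        fit = conic_fit(pts, prescale_x=1e6)
        assert fit.kind == "hyperbola"
        verts = fit.vertices[np.argsort(fit.vertices[:, 0])]
        np.testing.assert_allclose(verts[:, 0], [-1e-6, 1e-6], rtol=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.3, 3.0), st.floats(0.3, 3.0), st.booleans())
    def test_kind_matches_discriminant_sign(self, a, b, hyper):
        if hyper:
            pts = _hyperbola_points(a=a, b=b)
        else:
            t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
            pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
        fit = conic_fit(pts)
        if fit.kind == "hyperbola":
            assert fit.discriminant > 0
        elif fit.kind == "ellipse":
            assert fit.discriminant < 0


class TestPerStateConicFits:
    def test_partition_combinatorics(self):
        k = np.arange(1, 101)
        s1, s2 = decode_transition(k)
        for state in range(1, 11):
            assert (s1 == state).sum() == 10
            assert (s2 == state).sum() == 10

    def test_identical_hyperbola_per_group(self):
        pts = _hyperbola_points(n=10)
        x = np.tile(pts[:10, 0], 10)
        y = np.tile(pts[:10, 1], 10)
        fits = per_state_conic_fits(x, y, group_by="pre_state")
        kinds = {s: f.kind for s, f in fits.items() if f is not None}
        assert len(fits) == 10
        coeffs = [f.coeffs for f in fits.values() if f is not None]
        for c in coeffs[1:]:
            np.testing.assert_allclose(np.abs(c), np.abs(coeffs[0]), atol=1e-8)

    def test_scaled_copies_recover_ordering(self):
        base = _hyperbola_points(n=10)[:10]
        scales = np.linspace(1.0, 3.0, 10)
        x = np.concatenate([s * base[:, 0] for s in scales])
        y = np.concatenate([s * base[:, 1] for s in scales])
        fits = per_state_conic_fits(x, y, group_by="pre_state")
        recovered = []
        for state in range(1, 11):
            f = fits[state]
            assert f is not None and f.kind == "hyperbola"
            semi = np.linalg.norm(f.vertices[0] - f.vertices[1]) / 2
            recovered.append(semi)
        assert np.all(np.diff(recovered) > 0)

    def test_post_state_grouping(self):
        pts = _hyperbola_points(n=10)
        fits = per_state_conic_fits(
            np.tile(pts[:10, 0], 10), np.tile(pts[:10, 1], 10), group_by="post_state"
        )
        assert len(fits) == 10

    def test_bad_group_by(self):
        with pytest.raises(ValueError):
            per_state_conic_fits(np.zeros(100), np.zeros(100), group_by="state")


class TestClassExtrema:
    def test_six_classes(self):
        df = class_extrema(np.ones(100), np.ones(100))
        assert list(df["class_m"]) == [0, 1, 2, 3, 4, 5]
        assert list(df["n_types"]) == [10, 20, 20, 20, 20, 10]

    def test_class_value_maxima(self):
        k = np.arange(1, 101)
        s1, s2 = decode_transition(k)
        m = transition_class(s1, s2).astype(float)
        df = class_extrema(np.ones(100), m)
        np.testing.assert_allclose(df["max_abs_y"], [0, 1, 2, 3, 4, 5])

    def test_saturating_flux_fixture(self):
        k = np.arange(1, 101)
        s1, s2 = decode_transition(k)
        m = transition_class(s1, s2)
        flux = np.minimum(m, 3).astype(float)  # saturates at Class 3
        df = class_extrema(np.ones(100), flux)
        seq = df["max_abs_y"].to_numpy()
        assert np.all(np.diff(seq) >= 0)
        assert seq[3] == seq[4] == seq[5]


class TestSignReversalTable:
    def test_category_sizes(self, geometry, small_series):
        suite = adjacency_suite(small_series[0], geometry)
        df = sign_reversal_table({"T": [suite], "N": [suite]}, geometry)
        row = df[(df["group"] == "T") & (df["coefficient"] == "P")].iloc[0]
        assert row["n_0"] == 40 and row["n_1"] == 50

    def test_identical_categories_give_p_one(self, geometry, small_series):
        suite = adjacency_suite(small_series[0], geometry)
        # overwrite one coefficient with a constant: no category difference
        suite.coefficients["P"] = np.ones(100)
        df = sign_reversal_table({"T": [suite], "N": [suite]}, geometry,
                                 coefficients=("P",))
        row = df[(df["group"] == "T")].iloc[0]
        assert row["mean_0"] == row["mean_1"]
        assert row["p_0_vs_1"] == pytest.approx(1.0)

    def test_injected_attenuation_recovered(self, geometry, rng):
        from hbnet.network import COEFFICIENT_CLASSES, AdjacencySuite
        from hbnet.state_space import transition_types

        flags = np.array(
            [t.reversal_flags["total"] for t in transition_types(geometry)]
        )
        base = 1.0 + 0.05 * rng.normal(size=(8, 100))
        values = np.where(flags, 0.5, 1.0) * base  # category-1 attenuation 0.5
        suites = []
        for row in values:
            coeffs = {name: row.copy() for name in COEFFICIENT_CLASSES}
            suites.append(AdjacencySuite(coefficients=coeffs, counts=np.ones(100)))
        df = sign_reversal_table({"T": suites, "N": suites}, geometry,
                                 coefficients=("P",))
        row = df[df["group"] == "T"].iloc[0]
        assert row["mean_1"] / row["mean_0"] == pytest.approx(0.5, rel=0.05)
        assert row["p_0_vs_1"] < 0.01


class TestTPrime:
    def test_self_reference(self, rng):
        x = rng.normal(size=100)
        t = tprime_scores(x, x)
        assert t.mean() == pytest.approx(0.0, abs=1e-12)
        assert t.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_constant_shift(self, rng):
        ref = rng.normal(size=100)
        s = ref.std(ddof=1)
        shifted = tprime_scores(ref + 2.5, ref)
        np.testing.assert_allclose(shifted - tprime_scores(ref, ref), 2.5 / s, rtol=1e-9)

    def test_formula_oracle(self, rng):
        x = rng.normal(size=100)
        ref = rng.normal(size=100)
        expected = (x - ref.mean()) / ref.std(ddof=1)
        np.testing.assert_allclose(tprime_scores(x, ref), expected, rtol=1e-12)

    def test_zero_reference_sd(self):
        with pytest.raises(ValueError):
            tprime_scores(np.ones(100), np.ones(100))


class TestVectorAmplitude:
    def test_pythagorean(self):
        a = vector_amplitude(np.array([3.0]), np.array([4.0]), np.array([0.0]))
        assert a[0] == pytest.approx(5.0)

    def test_zeros(self):
        np.testing.assert_array_equal(
            vector_amplitude(np.zeros(4), np.zeros(4), np.zeros(4)), 0.0
        )

    def test_permutation_invariance(self, rng):
        a, b, c = rng.normal(size=(3, 100))
        np.testing.assert_allclose(
            vector_amplitude(a, b, c), vector_amplitude(c, a, b), rtol=1e-12
        )

    def test_rescaling_invariance_through_pipeline(self, rng):
        # common rescaling of both breasts leaves t' and amplitudes unchanged
        x, ref = rng.normal(size=(2, 100))
        t1 = tprime_scores(x, ref)
        t2 = tprime_scores(10.0 * x, 10.0 * ref)
        np.testing.assert_allclose(t1, t2, rtol=1e-10)


class TestRankOrder:
    def test_simple_ordering(self):
        cat = rank_order_category(np.array([3.0]), np.array([2.0]), np.array([1.0]))
        assert cat[0] == 1

    def test_all_categories(self):
        t_tot = np.array([3.0, 3.0, 2.0, 1.0, 1.0, 2.0])
        t_sat = np.array([2.0, 1.0, 3.0, 3.0, 2.0, 1.0])
        t_dwl = np.array([1.0, 2.0, 1.0, 2.0, 3.0, 3.0])
        np.testing.assert_array_equal(
            rank_order_category(t_tot, t_sat, t_dwl), [1, 2, 3, 4, 0, 0]
        )

    def test_tie_break_precedence(self):
        # exact tie: total precedes sat precedes dwell
        cat = rank_order_category(np.array([1.0]), np.array([1.0]), np.array([1.0]))
        assert cat[0] == 1

    def test_classes_3_to_5_have_50_types(self):
        k = np.arange(1, 101)
        s1, s2 = decode_transition(k)
        assert np.isin(transition_class(s1, s2), (3, 4, 5)).sum() == 50


class TestLineweaverBurk:
    def test_exact_mm_identity(self):
        vmax, km = 2.0, 0.5
        P = np.linspace(0.2, 3.0, 100)
        y = vmax * P / (km + P)
        fit = lineweaver_burk(P, y, subset=LBSubset(), transform="reciprocal")
        assert fit.r == pytest.approx(1.0, abs=1e-10)
        assert fit.slope == pytest.approx(km / vmax, abs=1e-10)
        assert fit.intercept == pytest.approx(1 / vmax, abs=1e-10)
        assert fit.vmax == pytest.approx(vmax, rel=1e-9)
        assert fit.km == pytest.approx(km, rel=1e-9)

    def test_constant_y_zero_slope(self):
        P = np.linspace(0.5, 2.0, 100)
        fit = lineweaver_burk(P, np.full(100, 3.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_class_subset_restricts_n(self, rng):
        P = np.linspace(0.5, 2.0, 100)
        y = rng.uniform(1, 2, 100)
        fit = lineweaver_burk(P, y, subset=LBSubset(classes=(3, 4, 5)))
        assert fit.n == 50

    def test_exclusion_region(self, rng):
        P = np.linspace(0.1, 2.0, 100)
        y = rng.uniform(1.0, 2.0, 100)
        subset = LBSubset(exclude_region=(2.5, 0.6))
        fit = lineweaver_burk(P, y, subset=subset)
        # excluded: 1/P < 2.5 AND 1/y > 0.6
        xv, yv = 1 / P, 1 / y
        expected_n = int((~((xv < 2.5) & (yv > 0.6))).sum())
        assert fit.n == expected_n
        assert fit.n + fit.n_dropped == 100

    def test_nonpositive_points_dropped(self):
        P = np.array([1.0, 2.0, -1.0, 1.5, 0.8, 1.2] + [1.0] * 94)
        y = np.ones(100)
        y[5] = 0.0
        fit = lineweaver_burk(P, y)
        assert fit.n_dropped >= 2

    def test_noisy_mm_recovery(self):
        vmax, km = 2.0, 0.5
        errs_v, errs_k = [], []
        for seed in range(100):
            r = np.random.default_rng(seed)
            P = r.uniform(0.2, 3.0, 50)
            y = vmax * P / (km + P)
            y = y * (1 + r.normal(0, 0.05, 50))
            fit = lineweaver_burk(P, y)
            errs_v.append(fit.vmax)
            errs_k.append(fit.km)
        assert np.median(errs_v) == pytest.approx(vmax, rel=0.10)
        assert np.median(errs_k) == pytest.approx(km, rel=0.10)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.1, 50.0), st.floats(0.01, 10.0))
    def test_exact_mm_linear_for_any_parameters(self, vmax, km):
        P = np.linspace(0.1, 5.0, 100)
        y = vmax * P / (km + P)
        fit = lineweaver_burk(P, y)
        assert abs(fit.r) == pytest.approx(1.0, abs=1e-7)


class TestCompareRegressions:
    def _fit(self, slope, seed, noise=0.01, n=50):
        r = np.random.default_rng(seed)
        P = r.uniform(0.2, 3.0, n)
        x = 1.0 / P
        y_line = slope * x + 0.5 + r.normal(0, noise, n)
        # feed back through lineweaver_burk by inverting the transform
        return lineweaver_burk(P, 1.0 / y_line)

    def test_identical_fits_p_one(self):
        fit = self._fit(1.0, seed=1)
        p_slope, p_int = compare_regressions(fit, fit)
        assert p_slope == pytest.approx(1.0)
        assert p_int == pytest.approx(1.0)

    def test_different_slopes_detected(self):
        f1 = self._fit(1.0, seed=2)
        f2 = self._fit(2.0, seed=3)
        p_slope, _ = compare_regressions(f1, f2)
        assert p_slope < 1e-3

    def test_symmetry(self):
        f1 = self._fit(1.0, seed=4)
        f2 = self._fit(1.3, seed=5)
        assert compare_regressions(f1, f2) == compare_regressions(f2, f1)


class TestMarkerGroupTests:
    def test_injected_group_effect_recovered(self):
        r = np.random.default_rng(99)
        amplitudes, labels = {}, {}
        base = r.uniform(2.0, 4.0, 100)
        for i in range(10):
            amplitudes[f"pos{i}"] = base * 1.2 * (1 + r.normal(0, 0.10, 100))
            labels[f"pos{i}"] = True
            amplitudes[f"neg{i}"] = base * (1 + r.normal(0, 0.10, 100))
            labels[f"neg{i}"] = False
        df = marker_group_tests(amplitudes, labels)
        row = df[df["selection"] == "all_classes_3_5"].iloc[0]
        assert row["n_types"] == 50
        assert row["mean_pos"] > row["mean_neg"]
        assert row["p"] < 0.05

    def test_per_category_rows(self, rng):
        amplitudes = {f"s{i}": rng.uniform(1, 2, 100) for i in range(6)}
        labels = {f"s{i}": i % 2 == 0 for i in range(6)}
        cats = rng.integers(1, 5, 100)
        df = marker_group_tests(amplitudes, labels, categories=cats)
        assert set(df["selection"]) == {
            "all_classes_3_5", "rank_order_1", "rank_order_2",
            "rank_order_3", "rank_order_4",
        }
        assert "p_bh" in df.columns

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            marker_group_tests({"a": np.ones(100)}, {"a": True})
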