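import numpy as np
import pytest

from dynrad.dynamic_features import (
    DYNAMIC_TYPE_NAMES,
    FeatureSeries,
    build_dynamic_vector,
    discrete_features,
    dynamic_block_matrix,
    dynamic_matrix,
    ek_curve,
    fit_exponential,
    fit_linear,
    fit_quadratic,
    integrated_features,
)
from oracles import bf_lstsq


def series(vals, t=(1.0, 2.0, 3.0, 4.0)):
    return FeatureSeries("f", np.asarray(vals, dtype=float), t)


class TestIntegrated:
    def test_closed_form(self):
        f = integrated_features(series([1, 2, 3, 4]))
        assert f["mean"] == pytest.approx(2.5)
        assert f["variance"] == pytest.approx(1.25)
        assert f["coefficient_of_variation"] == pytest.approx(np.sqrt(1.25) / 2.5)

    def test_constant_series(self):
        f = integrated_features(series([3, 3, 3, 3]))
        assert f["variance"] == 0.0 and f["coefficient_of_variation"] == 0.0

    def test_zero_mean_gives_nan_not_exception(self):
        f = integrated_features(series([-1, 1, -1, 1]))
        assert np.isnan(f["coefficient_of_variation"])

    def test_permutation_invariance(self, rng):
        v = rng.normal(5, 2, 4)
        a = integrated_features(series(v))
        b = integrated_features(series(v[::-1].copy()))
        assert a["mean"] == pytest.approx(b["mean"])
        assert a["variance"] == pytest.approx(b["variance"])


class TestDiscrete:
    def test_rcr_closed_form(self):
        f = discrete_features(series([10, 20, 30, 30]))
        assert f["RCR_seg1"] == pytest.approx(1.0)
        assert f["RCR_seg2"] == pytest.approx(0.5)
        assert f["RCR_seg3"] == pytest.approx(0.0)

    def test_racr_series_mean_denominator(self):
        f = discrete_features(series([10, 20, 30, 30]))
        assert f["RACR_seg1"] == pytest.approx(10 / 22.5)

    def test_racr_segment_midpoint_mode(self):
        f = discrete_features(series([10, 20, 30, 30]), racr_denominator="segment-midpoint")
        assert f["RACR_seg1"] == pytest.approx(10 / 15.0)

    def test_constant_series_all_zero(self):
        f = discrete_features(series([5, 5, 5, 5]))
        assert all(v == 0.0 for v in f.values())

    def test_zero_denominator_gives_nan(self):
        f = discrete_features(series([0, 1, 2, 3]))
        assert np.isnan(f["RCR_seg1"])

    @pytest.mark.parametrize("scale", [2.0, 17.5, 0.3])
    def test_positive_scaling_invariance(self, rng, scale):
        v = rng.uniform(1, 10, 4)
        a = discrete_features(series(v))
        b = discrete_features(series(scale * v))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)


class TestLinearFit:
    def test_exact_line(self):
        assert fit_linear(series([2, 4, 6, 8])) == pytest.approx((2.0, 0.0), abs=1e-12)

    def test_constant(self):
        k, d = fit_linear(series([7, 7, 7, 7]))
        assert k == pytest.approx(0.0, abs=1e-12)
        assert d == pytest.approx(7.0)

    def test_noiseless_recovery(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        k, d = fit_linear(series(3 * t - 1))
        assert k == pytest.approx(3.0, abs=1e-10)
        assert d == pytest.approx(-1.0, abs=1e-10)


class TestQuadraticFit:
    def test_pure_parabola(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        f = fit_quadratic(series(t ** 2))
        assert f["a"] == pytest.approx(1.0, abs=1e-10)
        assert f["b"] == pytest.approx(0.0, abs=1e-10)
        assert f["c"] == pytest.approx(0.0, abs=1e-10)
        assert f["T_maxQK"] == pytest.approx(0.0, abs=1e-8)  # vertex -b/2a

    def test_curvature_formula_at_vertex(self):
        # QK = |2a| / (1 + (2at+b)^2)^{3/2}: a=1, b=0, t=0 -> 2
        a, b, t = 1.0, 0.0, 0.0
        qk = abs(2 * a) / (1 + (2 * a * t + b) ** 2) ** 1.5
        assert qk == pytest.approx(2.0)

    def test_constant_series_degenerate_convention(self):
        f = fit_quadratic(series([4, 4, 4, 4]))
        assert f["a"] == pytest.approx(0.0, abs=1e-12)
        assert f["QK_max_feature"] == 0.0
        assert f["T_maxQK"] == 1.0  # t1 by convention

    def test_random_series_matches_normal_equations(self, rng):
        for _ in range(20):
            v = rng.normal(0, 3, 4)
            f = fit_quadratic(series(v))
            a, b, c = bf_lstsq([1, 2, 3, 4], v, 2)
            assert f["a"] == pytest.approx(a, abs=1e-8)
            assert f["b"] == pytest.approx(b, abs=1e-8)
            assert f["c"] == pytest.approx(c, abs=1e-8)

    def test_qk_max_feature_at_observed_max(self):
        v = [0.0, 5.0, 3.0, 1.0]  # observed max at t=2
        f = fit_quadratic(series(v))
        a, b = f["a"], f["b"]
        expected = abs(2 * a) / (1 + (2 * a * 2.0 + b) ** 2) ** 1.5
        assert f["QK_max_feature"] == pytest.approx(expected, rel=1e-12)


class TestExponentialFit:
    def test_pure_exponential_recovery(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        f = fit_exponential(series(np.exp(t)))
        assert f["alpha"] == pytest.approx(1.0, abs=1e-8)
        assert f["beta"] == pytest.approx(0.0, abs=1e-8)

    def test_affine_exponential_recovery(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        f = fit_exponential(series(2.5 * np.exp(t) - 4.0))
        assert f["alpha"] == pytest.approx(2.5, abs=1e-8)
        assert f["beta"] == pytest.approx(-4.0, abs=1e-8)

    def test_ek_closed_form_values(self):
        # alpha=1 at t=0: EK = 1 / 2^{3/2}
        assert ek_curve(1.0, np.array([0.0]))[0] == pytest.approx(2 ** -1.5)
        # alpha=0: EK identically 0
        assert np.all(ek_curve(0.0, np.linspace(1, 4, 50)) == 0.0)

    def test_printed_form_invalid_region_is_nan(self):
        # alpha < 0 makes 1 + alpha*e^{2t} <= 0 for large t under the printed form
        vals = ek_curve(-1.0, np.array([0.0, 2.0]))
        assert np.isnan(vals).all()  # 1 - e^{0} = 0 and 1 - e^4 < 0

    def test_corrected_curvature_always_valid(self):
        vals = ek_curve(-1.0, np.array([0.0, 2.0]), corrected=True)
        assert np.isfinite(vals).all()

    def test_t_maxek_matches_dense_grid_oracle(self, rng):
        for alpha in (0.5, 1.7, 0.01):
            f = dynamic_block_matrix(
                np.array([[alpha * np.e ** t for t in (1, 2, 3, 4)]]))[0]
            t_grid = np.linspace(1, 4, 400001)
            oracle = t_grid[np.nanargmax(ek_curve(f[16], t_grid))]
            assert f[18] == pytest.approx(oracle, abs=1e-4)


class TestDynamicVector:
    def test_twenty_types(self):
        assert len(DYNAMIC_TYPE_NAMES) == 20
        fams = [n.split("__")[0] for n in DYNAMIC_TYPE_NAMES]
        assert fams.count("integrated") == 3
        assert fams.count("discrete") == 6
        assert fams.count("linear") == 2
        assert fams.count("quadratic") == 5
        assert fams.count("exponential") == 4

    def test_9680_per_patient(self, phantom_volume):
        from dynrad.static_features import extract_static_vector
        vol, mask = phantom_volume
        svs = [extract_static_vector(vol + 0.1 * i, mask, p)
               for i, p in enumerate(("plain", "arterial", "portal", "equilibrium"))]
        dv = build_dynamic_vector(svs, patient_id="P0")
        assert len(dv.values) == 20 * 484 == 9680

    def test_identical_phases_zero_cascade(self):
        blk = dynamic_block_matrix(np.array([[3.0, 3.0, 3.0, 3.0]]))[0]
        named = dict(zip(DYNAMIC_TYPE_NAMES, blk))
        assert named["integrated__variance"] == 0.0
        assert all(named[f"discrete__RCR_seg{i}"] == 0.0 for i in (1, 2, 3))
        assert named["linear__k"] == pytest.approx(0.0, abs=1e-12)
        assert named["quadratic__a"] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_orderings_rejected(self, phantom_volume):
        from dynrad.static_features import extract_static_vector
        vol, mask = phantom_volume
        svs = [extract_static_vector(vol, mask, "plain") for _ in range(4)]
        svs[2].names = tuple(reversed(svs[2].names))
        with pytest.raises(ValueError, match="mismatched"):
            build_dynamic_vector(svs)

    def test_phase_permutation_changes_fits_not_integrated(self, rng):
        v = rng.normal(10, 2, 4)
        a = dynamic_block_matrix(v[None, :])[0]
        b = dynamic_block_matrix(v[::-1][None, :].copy())[0]
        np.testing.assert_allclose(a[:2], b[:2], rtol=1e-12)  # mean, variance
        assert not np.allclose(a[9], b[9])  # linear slope flips


class TestDynamicMatrix:
    def test_matches_scalar_path(self, rng):
        import pandas as pd
        mats = [pd.DataFrame(rng.normal(10, 1, (3, 5))) for _ in range(4)]
        out = dynamic_matrix(mats)
        assert out.shape == (3, 100)
        v = np.array([mats[ph].iloc[1, 2] for ph in range(4)])
        blk = dynamic_block_matrix(v[None, :])[0]
        got = out.iloc[1, 2 * 20: 3 * 20].to_numpy()
        np.testing.assert_allclose(got, blk, rtol=1e-12, equal_nan=True)

    def test_column_naming_scheme(self, rng):
        import pandas as pd
        mats = [pd.DataFrame(rng.normal(10, 1, (2, 2)), columns=["fa", "fb"])
                for _ in range(4)]
        out = dynamic_matrix(mats)
        assert "integrated__mean__fa" in out.columns
        assert "exponential__EK_max_feature__fb" in out.columns
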