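"""Normalization methods: fixed points, parameter recovery, invariants."""

import numpy as np
import pandas as pd
import pytest

from protprep.normalize import (
    fit_loess,
    glog2,
    glog2_inverse,
    ma_inverse,
    ma_transform,
    normalize_cyclic_loess,
    normalize_log2,
    normalize_rlm,
    normalize_vsn,
)


class TestLog2:
    def test_power_of_two(self):
        matrix = pd.DataFrame({"s": [1024.0]}, index=["f"])
        out, dropped = normalize_log2(matrix, 0.0)
        assert out.loc["f", "s"] == 10.0 and dropped == 0

    def test_value_at_alpha_becomes_missing(self):
        matrix = pd.DataFrame({"s": [50.0, 49.0, 100.0]}, index=list("abc"))
        out, dropped = normalize_log2(matrix, 50.0)
        assert np.isnan(out.loc["a", "s"]) and np.isnan(out.loc["b", "s"])
        assert dropped == 2

    def test_round_trip_inverse(self, rng):
        alpha = 37.5
        matrix = pd.DataFrame(rng.uniform(50, 5000, (20, 3)) + alpha)
        out, _ = normalize_log2(matrix, alpha)
        np.testing.assert_allclose(2.0**out + alpha, matrix, rtol=1e-14)

    def test_everything_below_alpha_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_log2(pd.DataFrame({"s": [1.0, 2.0]}), 10.0)


class TestMATransform:
    def test_direct_arithmetic(self):
        m, a = ma_transform([8.0], [2.0])
        assert m[0] == 2.0 and a[0] == 2.0

    def test_equal_arrays(self):
        m, a = ma_transform([16.0], [16.0])
        assert m[0] == 0.0 and a[0] == 4.0

    def test_round_trip(self, rng):
        y1 = rng.uniform(1, 1e4, 200)
        y2 = rng.uniform(1, 1e4, 200)
        m, a = ma_transform(y1, y2)
        b1, b2 = ma_inverse(m, a)
        np.testing.assert_allclose(b1, y1, rtol=1e-12)
        np.testing.assert_allclose(b2, y2, rtol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ma_transform([1.0, -2.0], [3.0, 4.0])


class TestCyclicLoess:
    def test_identical_arrays_are_a_fixed_point(self, rng):
        col = rng.uniform(10, 1e4, 200)
        matrix = pd.DataFrame({"a1": col, "a2": col.copy(), "a3": col.copy()})
        out = normalize_cyclic_loess(matrix, n_cycles=2)
        np.testing.assert_allclose(out.to_numpy(), matrix.to_numpy(), rtol=1e-10)

    def test_constant_offset_removed(self, rng):
        base = 2.0 ** rng.normal(10, 1.5, 400)
        matrix = pd.DataFrame({"a1": base, "a2": base * 2.0**1.5})
        out = normalize_cyclic_loess(matrix, n_cycles=3)
        resid = np.log2(out["a1"] / out["a2"])
        assert np.abs(resid).max() < 0.01
        # both arrays meet at the geometric mean of the originals
        np.testing.assert_allclose(
            np.log2(out["a1"]), np.log2(np.sqrt(matrix["a1"] * matrix["a2"])), atol=0.01
        )

    def test_intensity_dependent_bow_is_flattened(self, rng):
        base_log = rng.uniform(6, 14, 500)
        bow = 0.8 * np.sin((base_log - 6) / 8 * np.pi)  # injected M = f(A)
        matrix = pd.DataFrame({"a1": 2.0 ** (base_log + bow / 2), "a2": 2.0 ** (base_log - bow / 2)})
        out = normalize_cyclic_loess(matrix, n_cycles=3)
        m_after, a_after = ma_transform(out["a1"].to_numpy(), out["a2"].to_numpy())
        residual_amplitude = fit_loess(a_after, m_after).fitted
        assert np.abs(residual_amplitude).max() < 0.1 * 0.8

    def test_fewer_than_two_arrays_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_cyclic_loess(pd.DataFrame({"a1": [1.0, 2.0]}))

    def test_shape_and_missing_values_preserved(self, rng):
        matrix = pd.DataFrame(rng.uniform(10, 1000, (100, 3)), columns=list("abc"))
        matrix.iloc[3, 1] = np.nan
        out = normalize_cyclic_loess(matrix, n_cycles=1)
        assert out.shape == matrix.shape
        assert np.isnan(out.iloc[3, 1])

    def test_fast_variant_also_removes_offsets(self, rng):
        base = 2.0 ** rng.normal(10, 1.5, 400)
        matrix = pd.DataFrame({"a1": base, "a2": base * 2.0, "a3": base / 2.0})
        out = normalize_cyclic_loess(matrix, n_cycles=3, variant="fast")
        spread = np.log2(out.max(axis=1) / out.min(axis=1))
        assert np.median(spread) < 0.02


class TestRLM:
    @staticmethod
    def _fixture(rng, slide_effects, block_effects=None, outlier=None, noise=0.05):
        slides = [f"sl{i}" for i in range(len(slide_effects))]
        blocks = ["b1", "b2"]
        block_effects = block_effects or {b: 0.0 for b in blocks}
        controls = [f"C{k}" for k in range(4)]
        tau = {c: 11.0 + 0.5 * k for k, c in enumerate(controls)}
        samples, slide_of, block_of = [], {}, {}
        data = {}
        for si, sl in enumerate(slides):
            for b in blocks:
                s = f"{sl}_{b}"
                samples.append(s)
                slide_of[s], block_of[s] = sl, b
                data[s] = [
                    tau[c] + slide_effects[si] + block_effects[b] + rng.normal(0, noise)
                    for c in controls
                ]
        matrix = pd.DataFrame(data, index=pd.Index(controls, name="feature"))
        if outlier is not None:
            matrix.iloc[0, 0] += outlier
        return matrix, controls, slide_of, block_of

    def test_null_effects_recovered_as_zero(self, rng):
        matrix, controls, slide_of, block_of = self._fixture(rng, [0.0, 0.0])
        fit, adjusted = normalize_rlm(matrix, controls, slide_of, block_of)
        assert np.abs(fit.alpha).max() < 3 * fit.scale
        np.testing.assert_allclose(adjusted.to_numpy(), matrix.to_numpy(), atol=0.2)

    def test_injected_slide_effects_recovered(self, rng):
        matrix, controls, slide_of, block_of = self._fixture(rng, [1.0, -1.0])
        fit, adjusted = normalize_rlm(matrix, controls, slide_of, block_of)
        assert fit.alpha["sl0"] == pytest.approx(1.0, abs=0.05)
        assert fit.alpha["sl1"] == pytest.approx(-1.0, abs=0.05)
        assert abs(fit.alpha.sum()) < 1e-8  # sum-to-zero identification
        # post-adjustment the slides agree on the controls
        ctrl = adjusted.loc[controls]
        m0 = ctrl[[s for s in ctrl if s.startswith("sl0")]].to_numpy().mean()
        m1 = ctrl[[s for s in ctrl if s.startswith("sl1")]].to_numpy().mean()
        assert abs(m0 - m1) < 0.05

    def test_within_block_contrasts_exactly_invariant(self, rng):
        matrix, controls, slide_of, block_of = self._fixture(rng, [0.7, -0.7], {"b1": 0.3, "b2": -0.3})
        _, adjusted = normalize_rlm(matrix, controls, slide_of, block_of)
        for s in matrix.columns:
            before = matrix[s].to_numpy()
            after = adjusted[s].to_numpy()
            np.testing.assert_allclose(np.diff(before), np.diff(after), atol=1e-12)

    def test_huber_resists_a_gross_outlier(self, rng):
        """The robust fit moves far less than ordinary least squares does."""
        import statsmodels.formula.api as smf

        clean, controls, slide_of, block_of = self._fixture(rng, [0.5, -0.5])
        dirty = clean.copy()
        dirty.iloc[0, 0] += 8.0  # one contaminated control spot
        fit_clean, _ = normalize_rlm(clean, controls, slide_of, block_of)
        fit_dirty, _ = normalize_rlm(dirty, controls, slide_of, block_of)

        def ols_alpha(matrix):
            long = (
                matrix.reset_index()
                .melt(id_vars="feature", var_name="sample", value_name="value")
            )
            long["slide"] = long["sample"].map(slide_of)
            long["block"] = long["sample"].map(block_of)
            res = smf.ols(
                "value ~ C(slide, Sum) + C(block, Sum) + C(feature, Sum)", data=long
            ).fit()
            return res.params["C(slide, Sum)[S.sl0]"]

        rlm_shift = abs(fit_dirty.alpha["sl0"] - fit_clean.alpha["sl0"])
        ols_shift = abs(ols_alpha(dirty) - ols_alpha(clean))
        assert rlm_shift < 0.2 * ols_shift

    def test_constant_controls_rejected(self):
        matrix = pd.DataFrame(
            {"sl0_b1": [10.0, 10.0], "sl1_b1": [11.0, 12.0]},
            index=pd.Index(["C0", "C1"], name="feature"),
        )
        with pytest.raises(ValueError, match="constant|saturated"):
            normalize_rlm(
                matrix,
                ["C0", "C1"],
                {"sl0_b1": "sl0", "sl1_b1": "sl1"},
                {"sl0_b1": "b1", "sl1_b1": "b1"},
            )


class TestGlog2:
    def test_zero_maps_to_zero(self):
        assert glog2(0.0) == 0.0

    def test_unit_value_and_arsinh_identity(self):
        assert glog2(1.0) == pytest.approx(np.log2(1 + np.sqrt(2)), abs=1e-12)
        u = np.linspace(-50, 50, 101)
        np.testing.assert_allclose(glog2(u), np.arcsinh(u) / np.log(2), atol=1e-12)

    def test_direct_logarithm_formula(self, rng):
        u = rng.uniform(-100, 100, 200)
        np.testing.assert_allclose(glog2(u), np.log2(u + np.sqrt(u**2 + 1)), atol=1e-10)

    def test_asymptotic_log2_for_large_u(self):
        u = 1000.0
        assert abs(glog2(u) - np.log2(2 * u)) < 1e-6

    def test_odd_and_strictly_increasing(self, rng):
        u = np.sort(rng.uniform(-1e4, 1e4, 500))
        np.testing.assert_allclose(glog2(-u), -glog2(u), atol=1e-12)
        assert (np.diff(glog2(u)) > 0).all()

    def test_inverse(self, rng):
        u = rng.uniform(-1e3, 1e3, 100)
        np.testing.assert_allclose(glog2_inverse(glog2(u)), u, rtol=1e-10, atol=1e-10)


class TestGlog2Properties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_matches_arsinh_and_is_odd(self, u):
        assert glog2(u) == pytest.approx(np.arcsinh(u) / np.log(2), abs=1e-12)
        assert glog2(-u) == pytest.approx(-glog2(u), abs=1e-12)

    @given(
        st.floats(min_value=-1e5, max_value=1e5, allow_nan=False),
        st.floats(min_value=1e-6, max_value=1e5, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing(self, u, gap):
        assert glog2(u + gap) > glog2(u)


class TestVSN:
    @staticmethod
    def _two_component_fixture(rng, n_feat=50, n_arrays=6, resid_sd=0.25):
        """Data drawn from the transform-scale form of the two-component
        model: h(y) is exactly normal around per-feature means."""
        m_k = rng.uniform(-1.5, 12, n_feat)
        true_b = np.exp(rng.uniform(np.log(50), np.log(400), n_arrays))
        true_a = rng.uniform(-50, 150, n_arrays)
        z = m_k[:, None] + rng.normal(0, resid_sd, (n_feat, n_arrays))
        y = true_a + true_b * glog2_inverse(z)
        matrix = pd.DataFrame(
            y, columns=[f"arr{i}" for i in range(n_arrays)],
            index=pd.Index([f"f{k}" for k in range(n_feat)], name="feature"),
        )
        return matrix, true_a, true_b

    def test_scale_parameters_recovered(self, rng):
        """Per-array scales are recovered up to the common factor, which is
        on a flat ridge of the profile likelihood at this problem size."""
        matrix, _, true_b = self._two_component_fixture(rng)
        fit, transformed = normalize_vsn(matrix, background_corrected=False)
        bhat = fit.b.to_numpy()
        rel_est = bhat / np.exp(np.mean(np.log(bhat)))
        rel_true = true_b / np.exp(np.mean(np.log(true_b)))
        rel_err = np.abs(rel_est - rel_true) / rel_true
        assert rel_err.max() < 0.15
        assert (fit.b > 0).all()
        assert transformed.shape == matrix.shape

    def test_negative_entries_transform_and_preserve_order(self, rng):
        matrix = pd.DataFrame(rng.normal(100, 300, (30, 3)), columns=list("abc"))
        fit, out = normalize_vsn(matrix, background_corrected=True)
        assert np.isfinite(out.to_numpy()).all()
        for col in matrix:
            before = np.argsort(matrix[col].to_numpy())
            after = np.argsort(out[col].to_numpy())
            np.testing.assert_array_equal(before, after)

    def test_missing_values_stay_missing(self, rng):
        matrix = pd.DataFrame(rng.uniform(10, 1000, (25, 3)), columns=list("abc"))
        matrix.iloc[2, 0] = np.nan
        _, out = normalize_vsn(matrix)
        assert np.isnan(out.iloc[2, 0])
        assert out.notna().sum().sum() == matrix.notna().sum().sum()

    @pytest.mark.parametrize("shape", [(10, 3), (30, 1)])
    def test_input_requirements(self, shape, rng):
        matrix = pd.DataFrame(rng.uniform(1, 100, shape))
        with pytest.raises(ValueError):
            normalize_vsn(matrix)
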