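"""Background-correction methods against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from protprep.background import (
    NormexpParams,
    background_diagnostics,
    correct_background,
    correct_global,
    correct_half_moving_min,
    correct_local,
    correct_log_linear,
    correct_moving_min,
    correct_normexp,
    log_linear_threshold,
    normexp_fit_moments,
    normexp_signal,
)
from protprep.io import SpotTable


def _table(fg, bg, slide=None, block=None):
    n = len(fg)
    return SpotTable(
        pd.DataFrame(
            {
                "slide": slide if slide is not None else ["s1"] * n,
                "block": block if block is not None else [1] * n,
                "row": [1] * n,
                "col": list(range(1, n + 1)),
                "feature": [f"P{i}" for i in range(n)],
                "fg": np.asarray(fg, float),
                "bg": np.asarray(bg, float),
            }
        )
    )


class TestSubtractive:
    def test_local_subtraction_and_negative_flag(self):
        out = correct_local(_table([500, 200, 100], [300, 300, 0]))
        assert out.data["corrected"].tolist() == [200.0, -100.0, 100.0]
        assert out.data["negative_flag"].tolist() == [False, True, False]

    def test_local_with_zero_background_is_identity(self):
        out = correct_local(_table([50, 70], [0, 0]))
        assert out.data["corrected"].tolist() == [50.0, 70.0]

    def test_global_uses_slide_median(self):
        out = correct_global(_table([100, 100, 100], [10, 20, 30]))
        assert out.data["corrected"].tolist() == [80.0, 80.0, 80.0]

    def test_global_on_single_spot_equals_local(self):
        t = _table([120], [45])
        assert correct_global(t).data["corrected"].tolist() == correct_local(t).data["corrected"].tolist()

    def test_global_per_slide_matches_bruteforce(self, rng):
        """Each slide corrected with its own median, never a pooled one."""
        n = 40
        slides = ["s1"] * n + ["s2"] * n
        fg = rng.uniform(100, 1000, 2 * n)
        bg = np.concatenate([rng.uniform(10, 50, n), rng.uniform(200, 400, n)])
        out = correct_global(_table(fg, bg, slide=slides)).data
        for s in ("s1", "s2"):
            mask = np.array(slides) == s
            expected = fg[mask] - np.median(sorted(bg[mask]))  # independent median path
            np.testing.assert_allclose(out.loc[mask, "corrected"], expected)

    def test_moving_min_uses_block_minimum(self):
        out = correct_moving_min(_table([50, 40, 60], [5, 3, 8]))
        assert out.data["corrected"].tolist() == [47.0, 37.0, 57.0]

    def test_moving_min_single_spot_block_equals_local(self):
        t = _table([80], [30])
        assert correct_moving_min(t).data["corrected"].tolist() == [50.0]

    def test_moving_min_ignores_inflated_background(self, rng):
        """An artefact inflating most of a block's bg leaves the correction
        anchored at the untouched minimum."""
        fg = np.full(10, 500.0)
        bg = np.full(10, 100.0)
        clean = correct_moving_min(_table(fg, bg)).data["corrected"]
        bg_artefact = bg.copy()
        bg_artefact[1:] *= 5  # spot 0 untouched: block min unchanged
        dirty = correct_moving_min(_table(fg, bg_artefact)).data["corrected"]
        np.testing.assert_array_equal(clean, dirty)


class TestHalfMovingMin:
    def test_half_minimum_replacement(self):
        # moving-min of zero bg leaves values as given: directly exercises the rule
        out = correct_half_moving_min(_table([-5, 0, 12, 40], [0, 0, 0, 0]))
        assert out.data["corrected"].tolist() == [6.0, 6.0, 12.0, 40.0]

    def test_all_positive_is_identity(self):
        out = correct_half_moving_min(_table([5, 12, 40], [0, 0, 0]))
        assert out.data["corrected"].tolist() == [5.0, 12.0, 40.0]

    def test_pair_example(self):
        out = correct_half_moving_min(_table([-1, 2], [0, 0]))
        assert out.data["corrected"].tolist() == [1.0, 2.0]

    def test_no_positive_value_in_scope_is_an_error(self):
        with pytest.raises(ValueError, match="half-minimum"):
            correct_half_moving_min(_table([5, 5], [10, 5]))  # corrected {0, 0}

    def test_output_strictly_positive_and_scope_respected(self, rng):
        fg = rng.uniform(0, 50, 60)
        bg = rng.uniform(0, 50, 60)
        blocks = [1] * 30 + [2] * 30
        t = _table(fg, bg, block=blocks)
        try:
            out = correct_half_moving_min(t, scope="block")
        except ValueError:
            return  # a block without positives is a legitimate error
        assert (out.data["corrected"] > 0).all()


class TestNormexp:
    @staticmethod
    def _quadrature_expected_signal(p: NormexpParams, x: float) -> float:
        """E[S|X=x] by numerical integration of the convolution model."""
        mode = max(x - p.mu, 0.0)

        def logf(s):
            return -s / p.theta + stats.norm.logpdf(x - s, p.mu, p.sigma)

        shift = logf(mode)
        num = sum(
            integrate.quad(lambda s: s * np.exp(logf(s) - shift), a, b, limit=500)[0]
            for a, b in ((0.0, mode), (mode, np.inf))
        )
        den = sum(
            integrate.quad(lambda s: np.exp(logf(s) - shift), a, b, limit=500)[0]
            for a, b in ((0.0, mode), (mode, np.inf))
        )
        return num / den

    @pytest.mark.parametrize(
        "params", [NormexpParams(100, 10, 200), NormexpParams(0, 50, 500)]
    )
    def test_closed_form_matches_quadrature(self, params):
        xs = np.linspace(params.mu - 3 * params.sigma, params.mu + 8 * params.theta, 40)
        signal = normexp_signal(params, xs)
        expected = np.array([self._quadrature_expected_signal(params, x) for x in xs])
        np.testing.assert_allclose(signal, expected, rtol=1e-6)

    def test_degenerate_background_limit(self):
        """With mu=0 and vanishing sigma the correction tends to the identity."""
        p = NormexpParams(0.0, 1e-4, 500.0)
        xs = np.array([10.0, 100.0, 1000.0])
        np.testing.assert_allclose(normexp_signal(p, xs), xs, rtol=1e-3)

    def test_strictly_increasing_and_positive(self):
        p = NormexpParams(300, 80, 150)
        xs = np.linspace(-500, 5000, 2000)
        sig = normexp_signal(p, xs)
        assert (sig > 0).all()
        assert (np.diff(sig) > 0).all()

    @pytest.mark.parametrize("mu,sigma,theta", [(0, -1, 1), (0, 0, 1), (0, 1, 0), (0, 1, -2)])
    def test_invalid_parameters_rejected(self, mu, sigma, theta):
        with pytest.raises(ValueError):
            NormexpParams(mu, sigma, theta)

    def test_estimation_requires_enough_spots(self):
        with pytest.raises(ValueError, match="30"):
            correct_normexp(_table([100, 200], [10, 20]))

    def test_whole_slide_shares_one_parameter_set(self, rng):
        bg = rng.normal(200, 20, 100).clip(0)
        fg = bg + rng.exponential(400, 100)
        out = correct_normexp(_table(fg, bg))
        assert (out.data["corrected"] > 0).all()
        # same fg must map to (numerically) the same corrected value
        t2 = _table([500.0, 500.0], [100.0, 350.0], slide=["s1", "s1"])
        p = normexp_fit_moments(fg, bg)
        both = correct_normexp(t2, params=p).data["corrected"]
        assert both.iloc[0] == both.iloc[1]

    def test_moment_estimates_are_sane(self, rng):
        true = NormexpParams(mu=200.0, sigma=30.0, theta=500.0)
        bg = rng.normal(true.mu, true.sigma, 2000)
        fg = rng.normal(true.mu, true.sigma, 2000) + rng.exponential(true.theta, 2000)
        est = normexp_fit_moments(fg, bg)
        assert abs(est.mu - true.mu) < 5
        assert abs(est.sigma - true.sigma) < 5
        assert abs(est.theta - true.theta) / true.theta < 0.1


class TestLogLinear:
    def test_linear_branch_for_large_differences(self):
        out = correct_log_linear(_table([1000, 505], [100, 500]))
        # delta = max(min positive diff, 1) = 5; both diffs ≥ delta
        assert out.data["corrected"].tolist() == [900.0, 5.0]

    def test_continuity_at_the_knot(self):
        """fg − bg = δ exactly yields δ from both branches."""
        # one spot pins delta at 2, the probe spot sits exactly on the knot
        t = _table([102.0, 52.0], [100.0, 50.0])
        out = correct_log_linear(t).data["corrected"]
        np.testing.assert_allclose(out, [2.0, 2.0])

    def test_interpolated_value_below_the_knot(self):
        """At fg = 2δ, bg = 3δ (difference −δ) the interpolant gives δ/e."""
        delta = 4.0
        t = _table([104.0, 2 * delta], [100.0, 3 * delta])  # first spot sets delta
        out = correct_log_linear(t).data["corrected"]
        np.testing.assert_allclose(out.iloc[1], delta * np.exp(-1.0), rtol=1e-12)

    def test_monotone_positive_in_fg(self):
        bg = 300.0
        fgs = np.linspace(1.0, 1000.0, 500)
        t = _table(list(fgs) + [bg + 1.0], [bg] * 500 + [bg])
        out = correct_log_linear(t).data["corrected"].to_numpy()[:500]
        assert (out > 0).all()
        assert (np.diff(out) > -1e-12).all()

    def test_no_positive_difference_is_an_error(self):
        with pytest.raises(ValueError, match="positive"):
            correct_log_linear(_table([10, 20], [50, 60]))

    def test_threshold_floor(self):
        assert log_linear_threshold(np.array([0.25, 8.0])) == 1.0
        assert log_linear_threshold(np.array([3.0, 8.0])) == 3.0


class TestProperties:
    @pytest.mark.parametrize(
        "method", ["local", "global", "moving_min", "half_moving_min", "normexp", "log_linear"]
    )
    def test_record_count_and_order_preserved(self, method, rng):
        bg = rng.normal(200, 20, 60).clip(1)
        fg = bg + rng.exponential(300, 60) + 1
        t = _table(fg, bg, block=[1] * 30 + [2] * 30)
        out = correct_background(t, method=method)
        assert len(out.data) == 60
        assert out.data["feature"].tolist() == t.data["feature"].tolist()

    def test_constant_bg_shift_moves_local_and_global_by_minus_c(self, rng):
        bg = rng.uniform(50, 150, 30)
        fg = rng.uniform(200, 900, 30)
        c = 25.0
        for fn in (correct_local, correct_global):
            base = fn(_table(fg, bg)).data["corrected"].to_numpy()
            shifted = fn(_table(fg, bg + c)).data["corrected"].to_numpy()
            np.testing.assert_allclose(shifted, base - c, atol=1e-9)

    def test_provenance_records_the_method(self):
        out = correct_background(_table([10], [5]), method="local")
        assert out.provenance[-1]["params"]["method"] == "local"


class TestDiagnostics:
    def test_constant_background_flags_ties(self):
        diag = background_diagnostics(_table([1, 2, 3], [5, 5, 5]))
        assert diag.fg_bg_spearman["tie_flag"].iloc[0]
        assert np.isnan(diag.fg_bg_spearman["rho"].iloc[0])

    def test_proportional_background_gives_rho_one(self, rng):
        fg = rng.uniform(100, 1000, 50)
        diag = background_diagnostics(_table(fg, 0.3 * fg))
        # independent oracle: correlation of the rank vectors
        r1 = stats.rankdata(fg)
        expected = np.corrcoef(r1, stats.rankdata(0.3 * fg))[0, 1]
        assert diag.fg_bg_spearman["rho"].iloc[0] == pytest.approx(expected)
        assert diag.fg_bg_spearman["rho"].iloc[0] == pytest.approx(1.0)

    def test_missing_buffer_spots_warn(self):
        diag = background_diagnostics(_table([1, 2], [3, 4]))
        assert diag.buffer_spot_summary.empty
        assert any("buffer" in w for w in diag.warnings)

    def test_one_summary_row_per_block(self, corrected):
        table, _ = corrected
        diag = background_diagnostics(table)
        n_blocks = table.data.groupby(["slide", "block"]).ngroups
        assert len(diag.per_block_bg_summary) == n_blocks
        assert not diag.buffer_spot_summary.empty
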