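"""Normalization of feature × sample intensity matrices.

Single-channel protein arrays measure absolute fluorescence, so the
two-colour ratio tricks of DNA arrays do not apply; what must be tamed
instead is the mean–variance dependence (MVD) — replicate scatter that
grows with signal level — together with slide- and block-level
technical offsets.  Four strategies are implemented:

``log2``
    plain log2 of background-corrected values (undefined at or below
    the background estimate; inflates variance near zero);
``cyclic loess``
    pairwise MA-plot normalization between slides: for each pair, a
    LOESS curve of M = log2(y1/y2) against A = ½·log2(y1·y2) is fitted
    and centred to zero, removing intensity-dependent differences;
``rlm``
    robust-linear-model normalization from control spots: log2 control
    intensities are modelled as slide + block + protein fixed effects
    by Huber-weighted IRLS and the estimated slide and block effects
    are subtracted from every value;
``vsn``
    variance-stabilizing normalization: a per-array affine calibration
    followed by the generalised log, h(y) = glog2((y − a_i)/b_i), with
    (a_i, b_i) estimated by a trimmed profile maximum likelihood under
    the two-component (additive + multiplicative) noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "normalize_log2",
    "ma_transform",
    "ma_inverse",
    "LoessCurve",
    "fit_loess",
    "normalize_cyclic_loess",
    "RLMNormalizationFit",
    "normalize_rlm",
    "glog2",
    "glog2_inverse",
    "VSNFit",
    "normalize_vsn",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# log2


def normalize_log2(matrix: pd.DataFrame, alpha_hat: float = 0.0) -> tuple[pd.DataFrame, int]:
    """Elementwise log2(y − α̂) with α̂ a residual-background estimate.

    Values at or below α̂ have no logarithm; they become NaN and their
    count is returned alongside the transformed matrix.  An all-NaN
    result is an error (wrong α̂ or wrong scale).
    """
    shifted = matrix - alpha_hat
    valid = shifted > 0
    n_dropped = int((~valid & matrix.notna()).sum().sum())
    out = pd.DataFrame(
        np.where(valid, np.log2(shifted.where(valid)), np.nan),
        index=matrix.index,
        columns=matrix.columns,
    )
    if matrix.notna().any().any() and not valid.any().any():
        raise ValueError(f"every value is ≤ alpha_hat ({alpha_hat}); log2 normalization undefined")
    return out, n_dropped


# ---------------------------------------------------------------------------
# MA transform and cyclic loess


def ma_transform(y1, y2) -> tuple[np.ndarray, np.ndarray]:
    """MA coordinates of two arrays: M = log2(y1/y2), A = ½·log2(y1·y2)."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if np.any(y1[np.isfinite(y1)] <= 0) or np.any(y2[np.isfinite(y2)] <= 0):
        raise ValueError("MA transform requires strictly positive intensities")
    m = np.log2(y1 / y2)
    a = 0.5 * np.log2(y1 * y2)
    return m, a


def ma_inverse(m, a) -> tuple[np.ndarray, np.ndarray]:
    """Back-transform MA coordinates: y1 = 2^(A+M/2), y2 = 2^(A−M/2)."""
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    return 2.0 ** (a + m / 2.0), 2.0 ** (a - m / 2.0)


@dataclass
class LoessCurve:
    """A fitted LOESS smoother, evaluable over the observed x range.

    Local linear regression with tricube weights and robustness
    iterations; evaluation linearly interpolates between fitted points
    (and extends flat beyond the range).
    """

    x: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int = 1
    iterations: int = 3

    def __call__(self, xnew) -> np.ndarray:
        return np.interp(np.asarray(xnew, dtype=float), self.x, self.fitted)


def fit_loess(x, y, span: float = 0.7, iterations: int = 3) -> LoessCurve:
    """Fit a robust local-linear LOESS curve of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    fitted = _sm_lowess(y[order], x[order], frac=span, it=iterations, return_sorted=False)
    return LoessCurve(x=x[order], fitted=fitted, span=span, iterations=iterations)


def normalize_cyclic_loess(
    matrix: pd.DataFrame,
    span: float = 0.7,
    n_cycles: int = 3,
    iterations: int = 3,
    log_input: bool = False,
    variant: str = "pairs",
) -> pd.DataFrame:
    """Pairwise cyclic-loess normalization across arrays.

    For every distinct pair of arrays, the LOESS trend of M against A
    is estimated and split evenly between the two arrays (M is centred
    on the fitted curve, then backtransformed), sweeping all pairs
    ``n_cycles`` times.  ``variant="fast"`` instead normalizes each
    array against the across-array mean pseudo-array each cycle.

    Accepts raw (positive) or already log2 data via ``log_input``; the
    output is returned on the input scale.  NaNs are left in place and
    excluded from fits.
    """
    if matrix.shape[1] < 2:
        raise ValueError("cyclic loess needs at least 2 arrays")
    if variant not in ("pairs", "fast"):
        raise ValueError(f"variant must be 'pairs' or 'fast', got {variant!r}")
    values = matrix.to_numpy(dtype=float)
    if not log_input:
        if np.nanmin(values) <= 0:
            raise ValueError("raw-scale cyclic loess requires strictly positive intensities")
        work = np.log2(values)
    else:
        work = values.copy()

    n_arrays = work.shape[1]
    for _ in range(n_cycles):
        if variant == "pairs":
            for i in range(n_arrays - 1):
                for j in range(i + 1, n_arrays):
                    ok = np.isfinite(work[:, i]) & np.isfinite(work[:, j])
                    if ok.sum() < 10:
                        continue
                    m = work[ok, i] - work[ok, j]
                    a = 0.5 * (work[ok, i] + work[ok, j])
                    curve = fit_loess(a, m, span=span, iterations=iterations)
                    mhat = curve(a)
                    work[ok, i] -= mhat / 2.0
                    work[ok, j] += mhat / 2.0
        else:
            ref = np.nanmean(work, axis=1)
            for i in range(n_arrays):
                ok = np.isfinite(work[:, i]) & np.isfinite(ref)
                if ok.sum() < 10:
                    continue
                m = work[ok, i] - ref[ok]
                a = 0.5 * (work[ok, i] + ref[ok])
                curve = fit_loess(a, m, span=span, iterations=iterations)
                work[ok, i] -= curve(a)

    out = work if log_input else 2.0**work
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# RLM (control-spot) normalization


@dataclass
class RLMNormalizationFit:
    """Slide/block/protein fixed effects estimated from control spots.

    Effects are identified by sum-to-zero constraints per factor;
    ``scale`` is the robust (MAD-based) residual scale of the Huber
    IRLS fit.
    """

    alpha: pd.Series  # slide effects
    beta: pd.Series  # block effects
    tau: pd.Series  # control-protein effects
    intercept: float
    scale: float
    converged: bool
    n_control_values: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {"term": f"slide[{s}]", "effect": v} for s, v in self.alpha.items()
        ] + [
            {"term": f"block[{b}]", "effect": v} for b, v in self.beta.items()
        ] + [
            {"term": f"protein[{p}]", "effect": v} for p, v in self.tau.items()
        ]
        return pd.DataFrame(rows)


def _sum_coded_effects(levels: list, coefs: dict, prefix: str) -> pd.Series:
    """Recover all level effects from Sum-coded coefficients (last level
    is minus the sum of the others)."""
    effects = {}
    running = 0.0
    for lev in levels[:-1]:
        val = coefs[f"{prefix}[S.{lev}]"]
        effects[lev] = val
        running += val
    effects[levels[-1]] = -running
    return pd.Series(effects, dtype=float)


def normalize_rlm(
    matrix: pd.DataFrame,
    control_features: list[str],
    slide_of: dict[str, str],
    block_of: dict[str, object],
    huber_t: float = 1.345,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[RLMNormalizationFit, pd.DataFrame]:
    """Control-spot robust-linear-model normalization on log2 data.

    Control features (e.g. human IgG / IgM dilutions) are assumed to
    bind constantly up to technical slide and block effects.  Their
    log2 values are fitted to

        y = intercept + slide effect + block effect + protein effect + ε

    by iteratively reweighted least squares with Huber weights
    (tuning constant 1.345, MAD residual scale), sum-to-zero
    constraints making the factors identifiable.  The estimated
    slide-plus-block effect of each sample's position is subtracted
    from *every* feature in that sample; within-sample feature
    contrasts are therefore exactly preserved.

    Parameters
    ----------
    matrix
        log2-scale features × samples matrix (negative raw signals must
        have been replaced before logging, e.g. half-moving-minimum).
    control_features
        Row labels to fit on; must be present on every slide.
    slide_of, block_of
        Maps sample → slide label and sample → block(-position) label.
    """
    controls = [f for f in control_features if f in matrix.index]
    if not controls:
        raise ValueError("none of the control features are present in the matrix")
    samples = list(matrix.columns)
    missing = [s for s in samples if s not in slide_of or s not in block_of]
    if missing:
        raise ValueError(f"samples without slide/block assignment: {missing[:5]}")

    long = (
        matrix.loc[controls]
        .reset_index()
        .melt(id_vars="feature", var_name="sample", value_name="value")
        .dropna(subset=["value"])
    )
    long["slide"] = long["sample"].map(slide_of).astype(str)
    long["block"] = long["sample"].map(block_of).astype(str)
    if long.empty:
        raise ValueError("no control-spot values available for the model fit")

    per_slide_sd = long.groupby("slide")["value"].std()
    if (per_slide_sd.fillna(0.0) == 0.0).any():
        bad = list(per_slide_sd[per_slide_sd.fillna(0.0) == 0.0].index)
        raise ValueError(
            f"control spots constant or single-valued on slide(s) {bad}: "
            "saturated or missing controls cannot identify slide effects"
        )

    slides = sorted(long["slide"].unique())
    blocks = sorted(long["block"].unique())
    feats = sorted(long["feature"].unique())

    terms = []
    if len(slides) > 1:
        terms.append("C(slide, Sum)")
    if len(blocks) > 1:
        terms.append("C(block, Sum)")
    if len(feats) > 1:
        terms.append("C(feature, Sum)")
    formula = "value ~ " + (" + ".join(terms) if terms else "1")

    import statsmodels.formula.api as smf

    model = smf.rlm(formula, data=long, M=sm.robust.norms.HuberT(t=huber_t))
    res = model.fit(maxiter=max_iter, tol=tol, scale_est="mad")
    coefs = dict(zip(res.model.exog_names, res.params))

    alpha = (
        _sum_coded_effects(slides, coefs, "C(slide, Sum)")
        if len(slides) > 1
        else pd.Series({slides[0]: 0.0})
    )
    beta = (
        _sum_coded_effects(blocks, coefs, "C(block, Sum)")
        if len(blocks) > 1
        else pd.Series({blocks[0]: 0.0})
    )
    tau = (
        _sum_coded_effects(feats, coefs, "C(feature, Sum)")
        if len(feats) > 1
        else pd.Series({feats[0]: 0.0})
    )
    fit = RLMNormalizationFit(
        alpha=alpha,
        beta=beta,
        tau=tau,
        intercept=float(coefs.get("Intercept", 0.0)),
        scale=float(res.scale),
        converged=bool(getattr(res, "converged", True)),
        n_control_values=len(long),
    )

    adjust = pd.Series(
        {
            s: alpha.get(str(slide_of[s]), 0.0) + beta.get(str(block_of[s]), 0.0)
            for s in samples
        }
    )
    adjusted = matrix.sub(adjust, axis=1)
    return fit, adjusted


# ---------------------------------------------------------------------------
# glog2 and VSN


def glog2(u):
    """Generalised log2: glog2(u) = log2(u + √(u² + 1)) = arsinh(u)/ln 2.

    Defined for all reals (odd, strictly increasing) and asymptotically
    equal to log2(2u) for large positive u.  Computed through arsinh,
    which is stable for large negative arguments where the direct
    logarithm cancels catastrophically.
    """
    return np.arcsinh(u) / LN2


def glog2_inverse(z):
    """Inverse of glog2: sinh(z·ln 2) = (2^z − 2^−z)/2."""
    return np.sinh(np.asarray(z, dtype=float) * LN2)


@dataclass
class VSNFit:
    """Per-array affine calibration of the variance-stabilizing transform.

    ``a`` (offsets) and ``b`` (scales, kept positive through an
    exponential parameterization) define h_i(y) = glog2((y − a_i)/b_i).
    ``eta_sd``/``eps_sd`` are the implied multiplicative and additive
    noise sds of the two-component model, derived from the stabilized
    residual scale.
    """

    a: pd.Series
    b: pd.Series
    eta_sd: float
    eps_sd: float
    trim_fraction: float
    converged: bool
    objective: float
    n_trimmed: int = 0

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        scaled = (matrix - self.a.reindex(matrix.columns)) / self.b.reindex(matrix.columns)
        return pd.DataFrame(glog2(scaled.to_numpy(float)), index=matrix.index, columns=matrix.columns)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"array": self.a.index, "a": self.a.values, "b": self.b.values})


def _vsn_objective(params: np.ndarray, y: np.ndarray, fit_a: bool, keep: np.ndarray | None):
    """Negative profile log-likelihood of the VSN model.

    Per feature the h-transformed values are normal around a feature
    mean with common variance; the feature means and the variance are
    profiled out, leaving  (N/2)·log RSS − Σ log h'(y)  up to constants.
    ``keep`` restricts the sum to untrimmed features.
    """
    n_arrays = y.shape[1]
    if fit_a:
        a = params[:n_arrays]
        b = np.exp(params[n_arrays:])
    else:
        a = np.zeros(n_arrays)
        b = np.exp(params)
    u = (y - a) / b
    h = np.arcsinh(u) / LN2
    # log-Jacobian of h: -log b - log ln2 - 0.5 log(u²+1)
    logjac = -np.log(b) - np.log(LN2) - 0.5 * np.log1p(u**2)
    mask = np.isfinite(h)
    if keep is not None:
        mask = mask & keep[:, None]
    counts = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, np.nansum(np.where(mask, h, 0.0), axis=1) / np.maximum(counts, 1), 0.0)
    resid = np.where(mask, h - means[:, None], 0.0)
    rss_rows = (resid**2).sum(axis=1)
    n_total = int(mask.sum())
    rss = float(rss_rows.sum())
    if n_total == 0 or rss <= 0:
        return np.inf, rss_rows, counts
    nll = 0.5 * n_total * np.log(rss / n_total) - float(logjac[mask].sum())
    return nll, rss_rows, counts


def normalize_vsn(
    matrix: pd.DataFrame,
    background_corrected: bool = True,
    trim_fraction: float = 0.1,
    max_trim_iter: int = 5,
) -> tuple[VSNFit, pd.DataFrame]:
    """Variance-stabilizing normalization of a features × arrays matrix.

    Under the two-component error model y ≈ μ·e^η + ε (multiplicative
    noise η dominating at high signal, additive noise ε at low signal),
    h(y) = glog2((y − a_i)/b_i) renders the variance approximately
    independent of the mean.  The per-array parameters are estimated by
    maximising the profile likelihood in which every feature has its
    own transformed mean and all features share one residual variance,
    including the Jacobian of h.  Robustness comes from least-trimmed
    refitting: after each fit the ``trim_fraction`` of features with
    the largest standardized residual sums are set aside and the model
    is refitted, to a fixed point.  Two deterministic starting points
    guard against local minima.

    With ``background_corrected=True`` the offsets a_i are fixed at 0
    (the background has already been removed); otherwise they are
    estimated.  Negative values are acceptable either way — glog2 is
    defined on all of ℝ.
    """
    if matrix.shape[1] < 2:
        raise ValueError("VSN needs at least 2 arrays")
    if matrix.shape[0] < 20:
        raise ValueError("VSN needs at least 20 features for a stable fit")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    y = matrix.to_numpy(dtype=float)
    n_arrays = y.shape[1]
    fit_a = not background_corrected

    col_mad = np.array(
        [
            max(float(np.nanmedian(np.abs(c - np.nanmedian(c)))) * 1.4826, 1e-3)
            for c in y.T
        ]
    )
    col_q05 = np.nanquantile(y, 0.05, axis=0)

    starts = []
    for b0 in (col_mad, col_mad / 10.0):
        if fit_a:
            starts.append(np.concatenate([col_q05, np.log(b0)]))
        else:
            starts.append(np.log(b0))

    best = None
    for x0 in starts:
        keep: np.ndarray | None = None
        res = None
        for _ in range(max_trim_iter):
            res = optimize.minimize(
                lambda p: _vsn_objective(p, y, fit_a, keep)[0],
                x0,
                method="L-BFGS-B",
                options={"maxiter": 500},
            )
            x0 = res.x
            if trim_fraction == 0:
                break
            _, rss_rows, counts = _vsn_objective(res.x, y, fit_a, None)
            with np.errstate(divide="ignore", invalid="ignore"):
                score = np.where(counts > 1, rss_rows / np.maximum(counts - 1, 1), np.inf)
            n_keep = max(int(np.ceil((1 - trim_fraction) * y.shape[0])), 20)
            new_keep = np.zeros(y.shape[0], dtype=bool)
            new_keep[np.argsort(score, kind="stable")[:n_keep]] = True
            if keep is not None and np.array_equal(new_keep, keep):
                break
            keep = new_keep
        assert res is not None
        if best is None or res.fun < best[0].fun:
            best = (res, keep)

    res, keep = best
    if not np.isfinite(res.fun):
        raise RuntimeError(f"VSN optimizer failed to converge: {res.message}")
    if fit_a:
        a = pd.Series(res.x[:n_arrays], index=matrix.columns)
        b = pd.Series(np.exp(res.x[n_arrays:]), index=matrix.columns)
    else:
        a = pd.Series(np.zeros(n_arrays), index=matrix.columns)
        b = pd.Series(np.exp(res.x), index=matrix.columns)

    # residual scale on the stabilized scale → implied noise components
    nll, rss_rows, counts = _vsn_objective(res.x, y, fit_a, keep)
    n_total = int(counts.sum())
    tau = float(np.sqrt(rss_rows.sum() / max(n_total, 1)))
    eta_sd = tau * LN2  # high-intensity limit: Var h ≈ ση²/ln2²
    eps_sd = float(np.median(b)) * tau * LN2  # low-intensity limit

    fit = VSNFit(
        a=a,
        b=b,
        eta_sd=eta_sd,
        eps_sd=eps_sd,
        trim_fraction=trim_fraction,
        converged=bool(res.success),
        objective=float(res.fun),
        n_trimmed=int((~keep).sum()) if keep is not None else 0,
    )
    return fit, fit.transform(matrix)
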