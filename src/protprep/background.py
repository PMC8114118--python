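"""Background correction for single-channel protein arrays.

The foreground median of a spot is the total signal and includes the
local background (glass autofluorescence, non-specific binding).  Six
strategies are provided, chosen by how background artefacts distribute
over the slide:

``local``
    subtract each spot's own local background median — unbiased but
    noisy, and negative values appear whenever background exceeds
    foreground;
``global``
    subtract the slide-wide median of the local backgrounds — robust to
    uneven local estimates;
``moving_min``
    subtract the *minimum* local background within the spot's block
    (mini-array) — aimed at block-localized artefacts that inflate many
    local backgrounds at once;
``half_moving_min``
    moving-minimum subtraction followed by replacement of zero/negative
    values with half the minimum *positive* corrected value in scope,
    guaranteeing strictly positive output;
``normexp``
    a convolution model (normal background + exponential signal); the
    corrected intensity is the posterior mean E[S | X = fg], a smooth,
    strictly positive, strictly increasing function of the foreground;
``log_linear``
    keep fg − bg above a slide-derived threshold δ and interpolate
    smaller/negative differences through the log-linear monotone map
    δ·exp(1 − (bg + δ)/fg).

All methods preserve record count and order and write the result into a
``corrected`` column; ``negative_flag`` marks spots whose plain
difference was negative (policy for those is a downstream choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from protprep.io import SpotTable

__all__ = [
    "NormexpParams",
    "BackgroundDiagnostics",
    "correct_local",
    "correct_global",
    "correct_moving_min",
    "correct_half_moving_min",
    "correct_normexp",
    "correct_log_linear",
    "correct_background",
    "normexp_signal",
    "normexp_fit_moments",
    "normexp_loglik",
    "background_diagnostics",
]


@dataclass(frozen=True)
class NormexpParams:
    """Convolution-model parameters: X = B + S, B ~ N(mu, sigma²),
    S ~ Exponential(mean theta)."""

    mu: float
    sigma: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta}")


@dataclass
class BackgroundDiagnostics:
    """Per-slide and per-block summaries that guide method choice."""

    fg_bg_spearman: pd.DataFrame  # slide, rho (NaN + tie_flag when undefined)
    per_block_bg_summary: pd.DataFrame  # slide, block, bg_median, bg_iqr
    buffer_spot_summary: pd.DataFrame  # sample, n, fg_median, fg_iqr
    warnings: list[str]


def _require(table: SpotTable, cols: tuple[str, ...]) -> pd.DataFrame:
    missing = [c for c in cols if c not in table.data.columns]
    if missing:
        raise ValueError(f"spot table lacks columns {missing}")
    return table.data


def correct_local(table: SpotTable) -> SpotTable:
    """Spot-wise subtraction: corrected = fg − bg.

    Negative values are retained and flagged, not replaced.
    """
    data = _require(table, ("fg", "bg")).copy()
    data["corrected"] = data["fg"] - data["bg"]
    data["negative_flag"] = data["corrected"] < 0
    return table.replace_data(data, "background_correction", method="local")


def correct_global(table: SpotTable) -> SpotTable:
    """Subtract the slide-wide median of local backgrounds from fg."""
    data = _require(table, ("slide", "fg", "bg")).copy()
    med = data.groupby("slide")["bg"].transform("median")
    data["corrected"] = data["fg"] - med
    data["negative_flag"] = data["corrected"] < 0
    return table.replace_data(data, "background_correction", method="global")


def correct_moving_min(table: SpotTable) -> SpotTable:
    """Subtract the block-wise minimum local background from fg.

    Using the minimum rather than the median keeps the subtraction
    insensitive to artefacts that inflate many local backgrounds inside
    one block.
    """
    data = _require(table, ("slide", "block", "fg", "bg")).copy()
    mn = data.groupby(["slide", "block"])["bg"].transform("min")
    data["corrected"] = data["fg"] - mn
    data["negative_flag"] = data["corrected"] < 0
    return table.replace_data(data, "background_correction", method="moving_min")


def _half_min_replace(values: np.ndarray) -> np.ndarray:
    """Replace v ≤ 0 with half the minimum positive value; error if none."""
    values = np.asarray(values, dtype=float)
    pos = values[values > 0]
    if (values <= 0).any():
        if pos.size == 0:
            raise ValueError("no positive corrected value in scope; half-minimum replacement undefined")
        values = np.where(values <= 0, pos.min() / 2.0, values)
    return values


def correct_half_moving_min(table: SpotTable, scope: str = "block") -> SpotTable:
    """Moving-minimum subtraction with half-minimum replacement.

    Zero or negative corrected values are set to half the minimum of
    the positive corrected values within ``scope`` (per block by
    default, the unit the method targets; ``"slide"`` also accepted).
    Output is strictly positive.  This deliberately differs from fixed
    floors (e.g. clamping at 0.5): the replacement adapts to the
    intensity range actually observed.
    """
    if scope not in ("block", "slide"):
        raise ValueError(f"scope must be 'block' or 'slide', got {scope!r}")
    moved = correct_moving_min(table)
    data = moved.data.copy()
    keys = ["slide", "block"] if scope == "block" else ["slide"]
    data["corrected"] = (
        data.groupby(keys, group_keys=False)["corrected"].apply(
            lambda s: pd.Series(_half_min_replace(s.to_numpy()), index=s.index)
        )
    )
    data["negative_flag"] = False
    prov = table.provenance + [
        {"step": "background_correction", "params": {"method": "half_moving_min", "scope": scope}}
    ]
    return SpotTable(data, prov)


# ---------------------------------------------------------------------------
# normexp


def normexp_signal(params: NormexpParams, x: np.ndarray) -> np.ndarray:
    """Posterior mean E[S | X = x] of the normal+exponential convolution.

    With mu_s = x − mu − sigma²/theta the closed form is

        E[S | X = x] = mu_s + sigma · φ(mu_s/σ) / Φ(mu_s/σ),

    evaluated on the log scale so the Mills-ratio term stays accurate
    far into the left tail.  The result is strictly positive and
    strictly increasing in x.
    """
    x = np.asarray(x, dtype=float)
    mu_s = x - params.mu - params.sigma**2 / params.theta
    z = mu_s / params.sigma
    log_ratio = stats.norm.logpdf(z) - stats.norm.logcdf(z)
    return mu_s + params.sigma * np.exp(log_ratio)


def normexp_loglik(params: NormexpParams, x: np.ndarray) -> float:
    """Log-likelihood of foreground intensities under the convolution model.

    f(x) = (1/θ)·exp((μ−x)/θ + σ²/(2θ²))·Φ((x − μ − σ²/θ)/σ)
    """
    x = np.asarray(x, dtype=float)
    mu, sigma, theta = params.mu, params.sigma, params.theta
    z = (x - mu - sigma**2 / theta) / sigma
    terms = -np.log(theta) + (mu - x) / theta + sigma**2 / (2 * theta**2) + stats.norm.logcdf(z)
    return float(terms.sum())


def normexp_fit_moments(fg: np.ndarray, bg: np.ndarray) -> NormexpParams:
    """Moment-style initial estimates from one slide.

    mu and sigma come from the median and MAD-derived sd of the local
    backgrounds; theta from the excess of mean foreground over mu,
    floored at 1 intensity unit.
    """
    bg = np.asarray(bg, dtype=float)
    fg = np.asarray(fg, dtype=float)
    mu = float(np.median(bg))
    sigma = float(stats.median_abs_deviation(bg, scale="normal"))
    if sigma <= 0:
        sigma = max(float(np.std(bg, ddof=1)) if bg.size > 1 else 0.0, 1.0)
    theta = max(float(np.mean(fg)) - mu, 1.0)
    return NormexpParams(mu=mu, sigma=sigma, theta=theta)


def normexp_fit_ml(fg: np.ndarray, start: NormexpParams) -> NormexpParams:
    """Maximum-likelihood refinement by direct optimization.

    Optimizes (mu, log sigma, log theta) with L-BFGS-B from the moment
    start; falls back to the start on failure-to-improve.
    """
    fg = np.asarray(fg, dtype=float)

    def nll(p: np.ndarray) -> float:
        params = NormexpParams(p[0], float(np.exp(p[1])), float(np.exp(p[2])))
        return -normexp_loglik(params, fg)

    x0 = np.array([start.mu, np.log(start.sigma), np.log(start.theta)])
    res = optimize.minimize(nll, x0, method="L-BFGS-B")
    if not np.isfinite(res.fun) or res.fun > nll(x0):
        return start
    return NormexpParams(float(res.x[0]), float(np.exp(res.x[1])), float(np.exp(res.x[2])))


def correct_normexp(
    table: SpotTable,
    params: NormexpParams | str = "estimate",
    refine_ml: bool = False,
) -> SpotTable:
    """Model-based correction: corrected = E[S | X = fg].

    One parameter set is fitted (or supplied) per slide — the whole
    slide shares the same smooth positive map, so negative plain
    differences never occur.  With ``params="estimate"`` each slide
    needs at least 30 spots for the moment estimates to be usable;
    ``refine_ml=True`` adds a maximum-likelihood refinement.
    """
    data = _require(table, ("slide", "fg", "bg")).copy()
    fitted: dict[str, NormexpParams] = {}
    corrected = np.empty(len(data))
    for slide, idx in data.groupby("slide").groups.items():
        fg = data.loc[idx, "fg"].to_numpy(float)
        if isinstance(params, NormexpParams):
            p = params
        elif params == "estimate":
            if len(idx) < 30:
                raise ValueError(f"slide {slide!r}: need ≥30 spots to estimate normexp parameters, have {len(idx)}")
            p = normexp_fit_moments(fg, data.loc[idx, "bg"].to_numpy(float))
            if refine_ml:
                p = normexp_fit_ml(fg, p)
        else:
            raise ValueError(f"params must be NormexpParams or 'estimate', got {params!r}")
        fitted[str(slide)] = p
        corrected[data.index.get_indexer(idx)] = normexp_signal(p, fg)
    if not np.all(np.isfinite(corrected)):
        raise RuntimeError("normexp correction produced non-finite values; check parameter estimates")
    data["corrected"] = corrected
    data["negative_flag"] = False
    prov = table.provenance + [
        {
            "step": "background_correction",
            "params": {
                "method": "normexp",
                "per_slide": {s: {"mu": p.mu, "sigma": p.sigma, "theta": p.theta} for s, p in fitted.items()},
            },
        }
    ]
    return SpotTable(data, prov)


# ---------------------------------------------------------------------------
# log-linear (Edwards-style) interpolation


def log_linear_threshold(diff: np.ndarray, floor: float = 1.0) -> float:
    """Slide threshold δ: smallest positive fg − bg, floored at 1 unit."""
    diff = np.asarray(diff, dtype=float)
    pos = diff[diff > 0]
    if pos.size == 0:
        raise ValueError("no positive fg − bg difference on slide; log-linear correction undefined")
    return max(float(pos.min()), floor)


def _log_linear_map(fg: np.ndarray, bg: np.ndarray, delta: float) -> np.ndarray:
    diff = fg - bg
    # exponent floored so strictly-positive output survives underflow
    expo = np.clip(1.0 - (bg + delta) / np.maximum(fg, 1e-12), -700.0, 0.0)
    interp = delta * np.exp(expo)
    return np.where(diff >= delta, diff, interp)


def correct_log_linear(table: SpotTable, floor: float = 1.0) -> SpotTable:
    """Log-linear monotone interpolation for small/negative differences.

    Per slide, differences fg − bg at or above the threshold δ (the
    smallest positive difference observed, floored at ``floor``) are
    kept; smaller ones are replaced by δ·exp(1 − (bg + δ)/fg), which
    meets the linear branch continuously at fg = bg + δ and decays
    smoothly toward zero, so the corrected intensity is a continuous,
    strictly positive, monotone function of the foreground.
    """
    data = _require(table, ("slide", "fg", "bg")).copy()
    corrected = np.empty(len(data))
    deltas: dict[str, float] = {}
    for slide, idx in data.groupby("slide").groups.items():
        fg = data.loc[idx, "fg"].to_numpy(float)
        bg = data.loc[idx, "bg"].to_numpy(float)
        delta = log_linear_threshold(fg - bg, floor=floor)
        deltas[str(slide)] = delta
        corrected[data.index.get_indexer(idx)] = _log_linear_map(fg, bg, delta)
    data["corrected"] = corrected
    data["negative_flag"] = False
    prov = table.provenance + [
        {"step": "background_correction", "params": {"method": "log_linear", "delta": deltas}}
    ]
    return SpotTable(data, prov)


_METHODS = {
    "local": correct_local,
    "global": correct_global,
    "moving_min": correct_moving_min,
    "half_moving_min": correct_half_moving_min,
    "normexp": correct_normexp,
    "log_linear": correct_log_linear,
}


def correct_background(table: SpotTable, method: str = "local", **kwargs) -> SpotTable:
    """Dispatch to one of the six correction methods by name."""
    if method not in _METHODS:
        raise ValueError(f"unknown background method {method!r}; choose from {sorted(_METHODS)}")
    return _METHODS[method](table, **kwargs)


# ---------------------------------------------------------------------------
# diagnostics


def background_diagnostics(table: SpotTable) -> BackgroundDiagnostics:
    """Summaries that guide the choice of correction strategy.

    * per-slide Spearman correlation of foreground vs background medians
      (low values argue for plain local subtraction),
    * per-block background median and IQR (block artefacts show up as
      outlying medians → moving-minimum methods),
    * per-sample summaries of buffer-spot foregrounds (background
      reactivity / printing carry-over monitor).
    """
    data = _require(table, ("slide", "block", "fg", "bg"))
    warnings: list[str] = []

    rows = []
    for slide, grp in data.groupby("slide"):
        fg, bg = grp["fg"].to_numpy(float), grp["bg"].to_numpy(float)
        tie = np.all(bg == bg[0]) or np.all(fg == fg[0]) or len(grp) < 2
        if tie:
            rows.append({"slide": slide, "rho": np.nan, "tie_flag": True})
        else:
            rho = stats.spearmanr(fg, bg).statistic
            rows.append({"slide": slide, "rho": float(rho), "tie_flag": False})
    fg_bg = pd.DataFrame(rows)

    per_block = (
        data.groupby(["slide", "block"])["bg"]
        .agg(
            bg_median="median",
            bg_iqr=lambda s: float(np.subtract(*np.percentile(s, [75, 25]))),
        )
        .reset_index()
    )

    if "feature_class" in data.columns:
        buf = data[data["feature_class"] == "buffer"]
    else:
        buf = data.iloc[0:0]
    if buf.empty:
        warnings.append("no buffer spots found; buffer summary is empty")
        buffer_summary = pd.DataFrame(columns=["sample", "n", "fg_median", "fg_iqr"])
    else:
        key = "sample" if "sample" in buf.columns else "slide"
        buffer_summary = (
            buf.groupby(key)["fg"]
            .agg(
                n="count",
                fg_median="median",
                fg_iqr=lambda s: float(np.subtract(*np.percentile(s, [75, 25]))),
            )
            .reset_index()
            .rename(columns={key: "sample"})
        )
    return BackgroundDiagnostics(fg_bg, per_block, buffer_summary, warnings)
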