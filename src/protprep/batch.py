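"""Empirical-Bayes location/scale batch correction and batch diagnostics.

Samples processed on different days (or by different operators or
instruments) pick up batch-specific shifts and scale changes.  The
location/scale model

    Y_wsk = α_k + X β_k + γ_wk + δ_wk · ε_wsk

(feature k, batch w, sample s; X optional biological covariates to be
preserved) is corrected in the classic empirical-Bayes fashion: after
feature-wise standardization, per-batch location (γ̂) and scale (δ̂²)
estimates are shrunk toward their across-feature priors — normal for
the locations, inverse-gamma for the scales, hyperparameters by method
of moments — and the shrunken effects are removed.  Borrowing strength
across features is what keeps the adjustment stable in small batches.

Both the parametric (conjugate-prior iteration) and nonparametric
(likelihood-weighted averaging across features) posterior estimates are
implemented, plus a mean-only mode that leaves scales untouched for
tiny batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = ["BatchModel", "combat_adjust", "batch_diagnostics"]


@dataclass
class BatchModel:
    """Fitted quantities of the EB location/scale batch adjustment."""

    batches: pd.Series  # sample → batch label
    batch_levels: list
    mode: str
    mean_only: bool
    grand_effects: pd.Series  # α̂_k (+ reference-level standardized mean)
    design_coefficients: pd.DataFrame | None  # β̂_k for preserved covariates
    pooled_scale: pd.Series  # σ̂_k
    gamma_hat: pd.DataFrame  # raw batch locations (batch × feature)
    delta2_hat: pd.DataFrame  # raw batch scales
    gamma_star: pd.DataFrame  # EB posterior locations
    delta2_star: pd.DataFrame  # EB posterior scales
    hyperparameters: pd.DataFrame  # per batch: gamma_bar, tau2_bar, lambda (a), theta (b)
    n_iterations: dict
    dropped_features: list

    def summary(self) -> pd.DataFrame:
        rows = []
        for w in self.batch_levels:
            rows.append(
                {
                    "batch": w,
                    "n_samples": int((self.batches == w).sum()),
                    "median_gamma_hat": float(self.gamma_hat.loc[w].median()),
                    "median_gamma_star": float(self.gamma_star.loc[w].median()),
                    "median_delta2_hat": float(self.delta2_hat.loc[w].median()),
                    "median_delta2_star": float(self.delta2_star.loc[w].median()),
                    "iterations": self.n_iterations.get(w, 0),
                }
            )
        return pd.DataFrame(rows)


def _feature_ols(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Per-feature least-squares coefficients, NaN-aware.

    Complete features are solved in one vectorized call; features with
    missing samples fall back to a per-feature masked solve.
    """
    n_feat = y.shape[0]
    coefs = np.full((design.shape[1], n_feat), np.nan)
    complete = ~np.isnan(y).any(axis=1)
    if complete.any():
        sol, *_ = np.linalg.lstsq(design, y[complete].T, rcond=None)
        coefs[:, complete] = sol
    for k in np.where(~complete)[0]:
        ok = ~np.isnan(y[k])
        if ok.sum() < design.shape[1]:
            continue
        sol, *_ = np.linalg.lstsq(design[ok], y[k, ok], rcond=None)
        coefs[:, k] = sol
    return coefs


def _parametric_posteriors(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    gamma_bar: float,
    tau2_bar: float,
    a_prior: float,
    b_prior: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the conjugate posterior updates of (γ*, δ*²) to a fixed point."""
    n = (~np.isnan(z_batch)).sum(axis=1).astype(float)
    gamma = gamma_hat.copy()
    delta2 = delta2_hat.copy()
    for it in range(1, max_iter + 1):
        gamma_new = (tau2_bar * n * gamma_hat + delta2 * gamma_bar) / (tau2_bar * n + delta2)
        sum2 = np.nansum((z_batch - gamma_new[:, None]) ** 2, axis=1)
        delta2_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            float(np.max(np.abs(gamma_new - gamma) / np.maximum(np.abs(gamma), 1e-12))),
            float(np.max(np.abs(delta2_new - delta2) / np.maximum(np.abs(delta2), 1e-12))),
        )
        gamma, delta2 = gamma_new, delta2_new
        if change < tol:
            break
    return gamma, delta2, it


def _nonparametric_posteriors(
    z_batch: np.ndarray, gamma_hat: np.ndarray, delta2_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-weighted posterior means across the other features."""
    n_feat = z_batch.shape[0]
    gamma_star = np.empty(n_feat)
    delta2_star = np.empty(n_feat)
    for k in range(n_feat):
        obs = z_batch[k][~np.isnan(z_batch[k])]
        others = np.arange(n_feat) != k
        g, d2 = gamma_hat[others], delta2_hat[others]
        loglik = (
            -0.5 * ((obs[None, :] - g[:, None]) ** 2 / d2[:, None]).sum(axis=1)
            - 0.5 * obs.size * np.log(2 * np.pi * d2)
        )
        w = np.exp(loglik - loglik.max())
        w_sum = w.sum()
        gamma_star[k] = float((w * g).sum() / w_sum)
        delta2_star[k] = float((w * d2).sum() / w_sum)
    return gamma_star, delta2_star


def combat_adjust(
    matrix: pd.DataFrame,
    batches: pd.Series | dict,
    design: pd.DataFrame | None = None,
    mode: str = "parametric",
    mean_only: bool = False,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[BatchModel, pd.DataFrame]:
    """Remove batch locations and scales by empirical-Bayes shrinkage.

    Parameters
    ----------
    matrix
        Features × samples matrix, normalized scale (e.g. glog2/VSN).
    batches
        Sample → batch label; every sample needs exactly one.
    design
        Optional samples × covariates frame of *biological* effects to
        preserve (numeric, no intercept or batch columns); these are
        fitted alongside the batch means and added back after
        adjustment.
    mode
        ``"parametric"`` (normal / inverse-gamma conjugate iteration)
        or ``"nonparametric"`` (likelihood-weighted averages; slower,
        needs ≥2 samples per batch).
    mean_only
        Shrink and remove only the batch locations, leaving scales
        untouched — for very small batches whose variances are barely
        estimable.

    Returns
    -------
    (BatchModel, adjusted matrix)
        With a single batch the input is returned unchanged.

    Notes
    -----
    Features with zero pooled variance cannot be standardized; they are
    passed through unadjusted with a warning.
    """
    if mode not in ("parametric", "nonparametric"):
        raise ValueError(f"mode must be 'parametric' or 'nonparametric', got {mode!r}")
    batches = pd.Series(batches).reindex(matrix.columns)
    if batches.isna().any():
        missing = list(batches[batches.isna()].index)
        raise ValueError(f"samples without batch label: {missing[:5]}")
    levels = sorted(batches.unique())
    sizes = batches.value_counts()
    if mode == "nonparametric" and (sizes < 2).any():
        singletons = list(sizes[sizes < 2].index)
        raise ValueError(f"nonparametric mode needs ≥2 samples per batch; singleton batch(es): {singletons}")

    y = matrix.to_numpy(dtype=float)
    n_feat, n_samp = y.shape

    if len(levels) == 1:
        model = BatchModel(
            batches=batches,
            batch_levels=levels,
            mode=mode,
            mean_only=mean_only,
            grand_effects=pd.Series(np.nanmean(y, axis=1), index=matrix.index),
            design_coefficients=None,
            pooled_scale=pd.Series(np.nanstd(y, axis=1), index=matrix.index),
            gamma_hat=pd.DataFrame(0.0, index=levels, columns=matrix.index),
            delta2_hat=pd.DataFrame(1.0, index=levels, columns=matrix.index),
            gamma_star=pd.DataFrame(0.0, index=levels, columns=matrix.index),
            delta2_star=pd.DataFrame(1.0, index=levels, columns=matrix.index),
            hyperparameters=pd.DataFrame(),
            n_iterations={},
            dropped_features=[],
        )
        return model, matrix.copy()

    batch_dummies = np.column_stack([(batches == w).to_numpy(float) for w in levels])
    if design is not None:
        design = design.reindex(matrix.columns)
        if design.isna().any().any():
            raise ValueError("design has missing covariate values")
        x_mat = design.to_numpy(dtype=float)
        full_design = np.hstack([batch_dummies, x_mat])
    else:
        x_mat = None
        full_design = batch_dummies
    if np.linalg.matrix_rank(full_design) < full_design.shape[1]:
        raise ValueError("singular design: covariates are confounded with batch (or with each other)")

    coefs = _feature_ols(y, full_design)  # (b + p) × K
    batch_coefs = coefs[: len(levels)]
    weights = sizes.reindex(levels).to_numpy(float) / n_samp
    grand_mean = weights @ batch_coefs  # α̂_k

    fitted = (full_design @ coefs).T
    resid = y - fitted
    var_pooled = np.nanmean(resid**2, axis=1)  # σ̂²_k (1/N denominator)

    # constant features leave only rounding noise in the residual
    tiny = 1e-20 * max(1.0, float(np.nanmax(np.abs(y))) ** 2)
    zero_var = ~(var_pooled > tiny) | ~np.isfinite(var_pooled)
    dropped = list(matrix.index[zero_var])
    if dropped:
        warnings.warn(
            f"{len(dropped)} feature(s) with zero pooled variance passed through unadjusted",
            stacklevel=2,
        )

    stand_mean = np.tile(grand_mean[:, None], (1, n_samp))
    if x_mat is not None:
        stand_mean = stand_mean + (x_mat @ coefs[len(levels):]).T
    sigma = np.sqrt(var_pooled)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (y - stand_mean) / sigma[:, None]

    ok = ~zero_var
    gamma_hat = np.full((len(levels), n_feat), np.nan)
    delta2_hat = np.full((len(levels), n_feat), np.nan)
    gamma_star = np.full((len(levels), n_feat), np.nan)
    delta2_star = np.ones((len(levels), n_feat))
    hyper_rows = []
    n_iterations: dict = {}

    for wi, w in enumerate(levels):
        cols = (batches == w).to_numpy()
        zw = z[np.ix_(ok, cols)]
        g_hat = np.nanmean(zw, axis=1)
        if cols.sum() > 1:
            d2_hat = np.nanvar(zw, axis=1, ddof=1)
        else:
            d2_hat = np.ones(zw.shape[0])
        gamma_hat[wi, ok] = g_hat
        delta2_hat[wi, ok] = d2_hat

        gamma_bar = float(np.mean(g_hat))
        tau2_bar = float(np.var(g_hat, ddof=1)) if g_hat.size > 1 else 1.0
        m = float(np.mean(d2_hat))
        s2 = float(np.var(d2_hat, ddof=1)) if d2_hat.size > 1 else 1.0
        # inverse-gamma moment matching: λ (shape), θ (rate)
        a_prior = (2 * s2 + m**2) / s2 if s2 > 0 else 3.0
        b_prior = (m * s2 + m**3) / s2 if s2 > 0 else 2.0 * m
        hyper_rows.append(
            {"batch": w, "gamma_bar": gamma_bar, "tau2_bar": tau2_bar, "lambda": a_prior, "theta": b_prior}
        )

        if mean_only:
            n_k = (~np.isnan(zw)).sum(axis=1).astype(float)
            g_star = (tau2_bar * n_k * g_hat + gamma_bar) / (tau2_bar * n_k + 1.0)
            d2_star = np.ones_like(d2_hat)
            n_iterations[w] = 1
        elif mode == "parametric":
            g_star, d2_star, its = _parametric_posteriors(
                zw, g_hat, d2_hat, gamma_bar, tau2_bar, a_prior, b_prior, tol=tol, max_iter=max_iter
            )
            n_iterations[w] = its
        else:
            g_star, d2_star = _nonparametric_posteriors(zw, g_hat, d2_hat)
            n_iterations[w] = 1
        if np.any(d2_star <= 0):
            raise RuntimeError(f"batch {w!r}: non-positive posterior scale; adjustment undefined")
        gamma_star[wi, ok] = g_star
        delta2_star[wi, ok] = d2_star

    adjusted = y.copy()
    for wi, w in enumerate(levels):
        cols = (batches == w).to_numpy()
        zw = z[np.ix_(ok, cols)]
        bayes = (zw - gamma_star[wi, ok][:, None]) / np.sqrt(delta2_star[wi, ok][:, None])
        adjusted[np.ix_(ok, cols)] = bayes * sigma[ok][:, None] + stand_mean[np.ix_(ok, cols)]

    model = BatchModel(
        batches=batches,
        batch_levels=levels,
        mode=mode,
        mean_only=mean_only,
        grand_effects=pd.Series(grand_mean, index=matrix.index),
        design_coefficients=(
            pd.DataFrame(coefs[len(levels):], index=list(design.columns), columns=matrix.index)
            if design is not None
            else None
        ),
        pooled_scale=pd.Series(sigma, index=matrix.index),
        gamma_hat=pd.DataFrame(gamma_hat, index=levels, columns=matrix.index),
        delta2_hat=pd.DataFrame(delta2_hat, index=levels, columns=matrix.index),
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=matrix.index),
        delta2_star=pd.DataFrame(delta2_star, index=levels, columns=matrix.index),
        hyperparameters=pd.DataFrame(hyper_rows),
        n_iterations=n_iterations,
        dropped_features=dropped,
    )
    out = pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)
    return model, out


def batch_diagnostics(matrix: pd.DataFrame, batches: pd.Series | dict) -> dict:
    """Batch-labelled PCA scores, sample distances and per-batch summaries.

    Features are centred (NaNs imputed at the feature mean) before PCA;
    scores for the first components, the fraction of variance each
    explains, the Euclidean sample-distance matrix (hierarchical
    clustering input) and per-batch per-feature means/sds are returned
    as plain tables.
    """
    if matrix.shape[1] < 3:
        raise ValueError("batch diagnostics need at least 3 samples")
    batches = pd.Series(batches).reindex(matrix.columns)
    y = matrix.to_numpy(dtype=float)
    row_mean = np.nanmean(y, axis=1)
    filled = np.where(np.isnan(y), row_mean[:, None], y)
    x = filled.T  # samples × features
    n_comp = min(x.shape[0] - 1, x.shape[1], 10)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x - x.mean(axis=0))
    score_df = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
    )
    score_df["batch"] = batches.values
    dist = pd.DataFrame(squareform(pdist(x)), index=matrix.columns, columns=matrix.columns)
    summaries = []
    for w, cols in batches.groupby(batches).groups.items():
        sub = matrix[list(cols)]
        summaries.append(
            pd.DataFrame(
                {
                    "batch": w,
                    "feature": matrix.index,
                    "mean": sub.mean(axis=1).values,
                    "sd": sub.std(axis=1, ddof=1).values,
                }
            )
        )
    return {
        "pc_scores": score_df,
        "variance_explained": pd.Series(
            pca.explained_variance_ratio_ * 100.0,
            index=[f"PC{i+1}" for i in range(n_comp)],
            name="pct_variance",
        ),
        "sample_distances": dist,
        "per_batch_summary": pd.concat(summaries, ignore_index=True),
    }
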