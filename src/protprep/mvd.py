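"""Mean–variance-dependence (MVD) diagnostics.

Whether a normalization has decoupled the per-feature variability from
the signal level is judged three ways: a meanSd profile (features
ordered by mean rank, running-median sd for display), the Spearman rank
correlation between per-feature means and sds, and formal monotone
trend tests (Cox–Stuart, Mann–Kendall) on the sd sequence taken in
mean-rank order.  Successful stabilization drives the correlation and
trend statistics toward zero.

The trend tests are applied to the *unsmoothed* per-feature sd
sequence: running-window smoothing would induce serial dependence that
breaks both tests' null distributions, whereas raw per-feature sds are
essentially independent under a homoscedastic null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MVDReport",
    "mean_sd_profile",
    "spearman_mvd",
    "cox_stuart_test",
    "mann_kendall_test",
    "trend_test",
    "mvd_report",
]


@dataclass
class MVDReport:
    """Per-feature mean/sd pairs plus summary statistics of their relation."""

    profile: pd.DataFrame  # feature, mean, sd, mean_rank, running_sd
    spearman_rho: float  # NaN with tie_flag when undefined
    tie_flag: bool
    trend_method: str
    trend_statistic: float
    trend_p_value: float

    def to_dict(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "tie_flag": self.tie_flag,
            "trend_method": self.trend_method,
            "trend_statistic": self.trend_statistic,
            "trend_p_value": self.trend_p_value,
        }


def mean_sd_profile(matrix: pd.DataFrame, window_fraction: float = 0.1) -> pd.DataFrame:
    """Per-feature mean and sd across samples, ordered by mean rank.

    Features need ≥2 finite observations to get an sd.  A running
    median of the sd over a centred window of ⌈window_fraction·K⌉
    features is attached for plotting; it is display smoothing only.
    """
    if matrix.shape[1] < 2:
        raise ValueError("mean/sd profile needs at least 2 samples")
    means = matrix.mean(axis=1, skipna=True)
    sds = matrix.std(axis=1, ddof=1, skipna=True)
    ok = matrix.notna().sum(axis=1) >= 2
    prof = pd.DataFrame({"feature": matrix.index, "mean": means.values, "sd": sds.values})[ok.values]
    prof = prof.sort_values("mean", kind="stable").reset_index(drop=True)
    prof["mean_rank"] = np.arange(1, len(prof) + 1)
    window = max(int(np.ceil(window_fraction * len(prof))), 1)
    prof["running_sd"] = (
        prof["sd"].rolling(window=window, center=True, min_periods=1).median()
    )
    return prof


def spearman_mvd(matrix: pd.DataFrame) -> tuple[float, bool]:
    """Spearman rank correlation between per-feature means and sds.

    Returns (rho, tie_flag); rho is NaN with the flag set when either
    the means or the sds are constant (ranks degenerate).  Ties are
    mid-ranked.  Invariant to any strictly monotone transform of the
    means alone.
    """
    if matrix.shape[0] < 3:
        raise ValueError("Spearman MVD needs at least 3 features")
    ok = matrix.notna().sum(axis=1) >= 2
    means = matrix.mean(axis=1, skipna=True)[ok].to_numpy(float)
    sds = matrix.std(axis=1, ddof=1, skipna=True)[ok].to_numpy(float)
    if means.size < 3 or np.all(means == means[0]) or np.all(sds == sds[0]):
        return float("nan"), True
    rho = stats.spearmanr(means, sds).statistic
    return float(rho), False


def cox_stuart_test(sequence) -> tuple[float, float]:
    """Cox–Stuart sign test for monotone trend.

    The sequence is split in half (middle element dropped when the
    length is odd); x_t is paired with x_{t+⌈n/2⌉} and the number of
    positive differences among the untied pairs is referred to an
    exact two-sided binomial(m, ½) test.  Statistic: number of
    positive differences minus m/2.
    """
    x = np.asarray(sequence, dtype=float)
    if x.size < 5:
        raise ValueError(f"Cox–Stuart needs length ≥5, got {x.size}")
    half = x.size // 2
    first = x[:half]
    second = x[x.size - half:]
    diffs = second - first
    diffs = diffs[diffs != 0]
    m = diffs.size
    if m == 0:
        return 0.0, 1.0
    n_pos = int((diffs > 0).sum())
    p = float(stats.binomtest(n_pos, m, 0.5, alternative="two-sided").pvalue)
    return float(n_pos - m / 2.0), min(p, 1.0)


def mann_kendall_test(sequence, continuity: bool = True) -> tuple[float, float]:
    """Mann–Kendall trend test with tie-corrected normal approximation.

    S = Σ_{i<j} sign(x_j − x_i); under no trend E S = 0 and

        Var S = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)] / 18

    with the sum over tie-group sizes t.  The two-sided p-value uses
    the normal approximation with a continuity correction of 1.
    Returns (S, p); an all-tied sequence gives (0, 1).
    """
    x = np.asarray(sequence, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"Mann–Kendall needs length ≥4, got {n}")
    s = float(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)].sum())
    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:
        return 0.0, 1.0
    cc = 1.0 if continuity else 0.0
    if s > 0:
        z = (s - cc) / np.sqrt(var)
    elif s < 0:
        z = (s + cc) / np.sqrt(var)
    else:
        z = 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return s, min(p, 1.0)


_TREND_TESTS = {"cox_stuart": cox_stuart_test, "mann_kendall": mann_kendall_test}


def trend_test(sequence, method: str = "mann_kendall") -> tuple[float, float]:
    """Dispatch to a monotone trend test by name; two-sided p-value."""
    if method not in _TREND_TESTS:
        raise ValueError(f"unknown trend test {method!r}; choose from {sorted(_TREND_TESTS)}")
    return _TREND_TESTS[method](sequence)


def mvd_report(
    matrix: pd.DataFrame,
    window_fraction: float = 0.1,
    trend_method: str = "mann_kendall",
) -> MVDReport:
    """Full mean–variance diagnostic of a features × samples matrix."""
    profile = mean_sd_profile(matrix, window_fraction=window_fraction)
    rho, tie = spearman_mvd(matrix)
    seq = profile["sd"].to_numpy(float)
    if seq.size >= 5:
        statistic, p = trend_test(seq, method=trend_method)
    else:
        statistic, p = float("nan"), float("nan")
    return MVDReport(
        profile=profile,
        spearman_rho=rho,
        tie_flag=tie,
        trend_method=trend_method,
        trend_statistic=statistic,
        trend_p_value=p,
    )
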