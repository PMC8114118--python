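"""Technical-replicate quality control, averaging and tag subtraction.

Each protein is printed several times (triplicate in the reference
design) for every serum sample.  Agreement between these technical
replicates is quantified by the coefficient of variation,

    CV% = 100 · s / x̄,

with the sample standard deviation (n−1 denominator; CV is sensitive to
this at n = 2–3, so the convention is stated).  Replicate sets whose CV
exceeds a cutoff are rescued in two ways:

* *low-intensity exemption* — near the detection floor, tiny absolute
  differences produce huge CVs that say nothing about reliability, so
  sets whose mean falls below an intensity threshold are kept despite
  their CV;
* *best-subset rescue* — otherwise the minimum-CV subset of size ≥
  ``min_replicates_kept`` is searched exhaustively; if it meets the
  cutoff the outliers are dropped and the subset kept.

Surviving replicates are averaged into a features × samples matrix, and
(optionally) the replicate-averaged signal of each antigen's
purification tag (GST, MBP, His/CD4 …) is subtracted from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from protprep.io import ExperimentLayout, SpotTable

__all__ = [
    "CVPolicy",
    "compute_cv",
    "best_cv_subset",
    "filter_replicates",
    "average_replicates",
    "subtract_tag",
    "cv_summary_by_sample",
]

STATUSES = ("pass", "best_subset", "low_intensity_exempt", "fail")


@dataclass(frozen=True)
class CVPolicy:
    """Acceptance rules for replicate sets."""

    cutoff_percent: float = 20.0
    low_intensity_threshold: float = 0.0
    min_replicates_kept: int = 2

    def __post_init__(self) -> None:
        if not self.cutoff_percent > 0:
            raise ValueError("cutoff_percent must be > 0")
        if self.low_intensity_threshold < 0:
            raise ValueError("low_intensity_threshold must be ≥ 0")
        if self.min_replicates_kept < 1:
            raise ValueError("min_replicates_kept must be ≥ 1")


def compute_cv(values) -> tuple[float, float, float]:
    """Mean, sample sd and CV% of a replicate set.

    Returns ``cv_percent = NaN`` when the mean is non-positive (the
    ratio is meaningless there); requires at least two finite values.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError(f"need ≥2 finite replicate values, got {values.size}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else float("nan")
    return mean, sd, cv


def best_cv_subset(values: np.ndarray, min_keep: int) -> tuple[tuple[int, ...], float]:
    """Exhaustive search for the minimum-CV subset of size ≥ min_keep.

    Ties are broken toward the larger subset mean, then the
    lexicographically smallest index tuple; undefined CVs (mean ≤ 0)
    never win against a defined one.  Replicate counts are tiny (3–5),
    so enumeration is exact and cheap.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    best: tuple[int, ...] | None = None
    best_cv = np.inf
    best_mean = -np.inf
    for size in range(max(min_keep, 2), n + 1):
        for idx in combinations(range(n), size):
            sub = values[list(idx)]
            mean = sub.mean()
            cv = 100.0 * sub.std(ddof=1) / mean if mean > 0 else np.inf
            if (cv < best_cv - 1e-12) or (
                abs(cv - best_cv) <= 1e-12 and (mean > best_mean + 1e-12 or (abs(mean - best_mean) <= 1e-12 and (best is None or idx < best)))
            ):
                best, best_cv, best_mean = idx, cv, mean
    assert best is not None
    return best, float(best_cv)


def filter_replicates(
    table: SpotTable,
    policy: CVPolicy = CVPolicy(),
    value_column: str = "corrected",
) -> tuple[SpotTable, pd.DataFrame]:
    """Apply the CV policy to every (sample, feature) replicate set.

    Per set, in order: full-set CV ≤ cutoff → ``pass`` (keep all);
    mean below the low-intensity threshold → ``low_intensity_exempt``
    (keep all — such CVs are ignored, not used to reject); otherwise
    the exhaustive best subset of size ≥ ``min_replicates_kept`` is
    tried → ``best_subset`` if it meets the cutoff, else ``fail``
    (keep none).  Failure is a status, not an error.

    Returns the table with a ``cv_keep`` flag column plus the CV report
    (one row per sample × feature with n, mean, sd, cv_percent, status
    and the retained replicate indices).
    """
    if value_column not in table.data.columns:
        raise ValueError(f"spot table lacks value column {value_column!r}; run background correction first")
    data = table.data.copy()
    report_rows = []
    keep = np.ones(len(data), dtype=bool)
    for (sample, feature), grp in data.groupby(["sample", "feature"], sort=True):
        vals = grp[value_column].to_numpy(float)
        reps = grp["replicate"].to_numpy(int)
        pos = data.index.get_indexer(grp.index)
        if vals.size < 2:
            mean, sd, cv = float(vals.mean()), float("nan"), float("nan")
            status, retained = "pass", tuple(reps)
        else:
            mean, sd, cv = compute_cv(vals)
            if np.isfinite(cv) and cv <= policy.cutoff_percent:
                status, retained = "pass", tuple(reps)
            elif mean < policy.low_intensity_threshold:
                status, retained = "low_intensity_exempt", tuple(reps)
            elif vals.size > policy.min_replicates_kept:
                idx, sub_cv = best_cv_subset(vals, policy.min_replicates_kept)
                if np.isfinite(sub_cv) and sub_cv <= policy.cutoff_percent:
                    status, retained = "best_subset", tuple(int(reps[i]) for i in idx)
                    keep[pos] = np.isin(np.arange(vals.size), idx)
                else:
                    status, retained = "fail", ()
                    keep[pos] = False
            else:
                status, retained = "fail", ()
                keep[pos] = False
        report_rows.append(
            {
                "sample": sample,
                "feature": feature,
                "n_replicates": int(vals.size),
                "mean": mean,
                "sd": sd,
                "cv_percent": cv,
                "status": status,
                "replicates_retained": ",".join(map(str, retained)),
            }
        )
    data["cv_keep"] = keep
    report = pd.DataFrame(report_rows)
    out = table.replace_data(
        data,
        "cv_filter",
        cutoff_percent=policy.cutoff_percent,
        low_intensity_threshold=policy.low_intensity_threshold,
        min_replicates_kept=policy.min_replicates_kept,
        n_fail=int((report["status"] == "fail").sum()),
    )
    return out, report


def average_replicates(
    table: SpotTable,
    report: pd.DataFrame | None = None,
    value_column: str = "corrected",
    feature_classes: tuple[str, ...] = ("antigen", "control", "tag"),
) -> pd.DataFrame:
    """Average retained replicates into a features × samples matrix.

    Cells whose replicate set failed the CV policy become NaN.  Buffer
    spots are excluded by default (they monitor the print run, they are
    not analytes).
    """
    data = table.data[table.data["feature_class"].isin(feature_classes)]
    all_features = pd.Index(sorted(data["feature"].unique()), name="feature")
    all_samples = pd.Index(sorted(data["sample"].unique()), name="sample")
    if "cv_keep" in data.columns:
        data = data[data["cv_keep"]]
    matrix = (
        data.pivot_table(index="feature", columns="sample", values=value_column, aggfunc="mean")
        .reindex(index=all_features, columns=all_samples)
    )
    if report is not None:
        failed = report[report["status"] == "fail"]
        for _, row in failed.iterrows():
            if row["feature"] in matrix.index and row["sample"] in matrix.columns:
                matrix.loc[row["feature"], row["sample"]] = np.nan
    matrix.columns.name = "sample"
    return matrix


def subtract_tag(
    matrix: pd.DataFrame,
    layout: ExperimentLayout,
    floor: float = 0.0,
) -> pd.DataFrame:
    """Subtract each antigen's purification-tag signal, per sample.

    For every antigen with an annotated tag, the tag feature's
    replicate-averaged value in the same sample is subtracted; results
    below ``floor`` are clamped to it.  Untagged antigens and the tag
    rows themselves are untouched.  This step is optional in the
    workflow — it applies only to designs with tagged constructs.
    """
    tag_of = layout.tag_of
    out = matrix.copy()
    for feature, tag in tag_of.items():
        if feature not in out.index:
            continue
        if tag not in matrix.index:
            raise KeyError(f"tag feature {tag!r} (for antigen {feature!r}) missing from matrix")
        adjusted = out.loc[feature] - matrix.loc[tag]
        out.loc[feature] = adjusted.clip(lower=floor)
    return out


def cv_summary_by_sample(report: pd.DataFrame, cutoff_percent: float = 20.0) -> pd.DataFrame:
    """Per-sample tabulation of replicate agreement.

    Counts and percentages of replicate sets at or below / above the
    CV cutoff, plus the number of out-of-range CVs — sets whose CV is
    undefined because the mean is non-positive.
    """
    rows = []
    for sample, grp in report.groupby("sample"):
        cv = grp["cv_percent"]
        defined = cv.notna()
        n_le = int((cv[defined] <= cutoff_percent).sum())
        n_gt = int((cv[defined] > cutoff_percent).sum())
        n_def = int(defined.sum())
        rows.append(
            {
                "sample": sample,
                "n_le_cutoff": n_le,
                "pct_le_cutoff": 100.0 * n_le / n_def if n_def else np.nan,
                "n_gt_cutoff": n_gt,
                "pct_gt_cutoff": 100.0 * n_gt / n_def if n_def else np.nan,
                "n_out_of_range": int((~defined).sum()),
            }
        )
    return pd.DataFrame(rows)
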