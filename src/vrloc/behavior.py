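"""Pointing-response analysis: bias correction, outlier screening, error tables.

Response logs are tidy DataFrames with one row per localization trial and
the columns of :data:`RESPONSE_COLUMNS` (angles in degrees).  The pipeline
applied to a raw log is:

1. :func:`mirror_handedness` — left-handed subjects' target and response
   azimuths are mirrored on the median plane so pointing asymmetries line
   up with the right-handed majority;
2. :func:`estimate_pointing_bias` — each subject's systematic pointing
   offset (azimuth, elevation) is the mean signed error over all targets
   and repetitions of the two visual-search conditions; the group bias is
   the mean of the subject biases;
3. :func:`apply_bias_correction` — the per-subject bias is subtracted from
   responses in every condition except the laser-pointer condition, where
   visual feedback of the pointing ray makes the correction inapplicable;
4. :func:`filter_outliers` — trials farther than 45 deg from the target in
   either azimuth or elevation (strictly greater) are discarded;
5. :func:`summarize_errors` — mean absolute error plus signed-error
   boxplot statistics (median, quartiles, 1.5-IQR whiskers) per grouping
   cell, for azimuth and elevation separately.

Outlier screening runs after bias correction.  Inferential statistics
(mixed models, post-hoc tests) are deliberately out of scope: the long-
format tables these functions emit feed any standard statistics tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import conditions as cond
from .geometry import wrap_azimuth

__all__ = [
    "RESPONSE_COLUMNS",
    "BiasEstimate",
    "OutlierResult",
    "signed_error_columns",
    "mirror_handedness",
    "estimate_pointing_bias",
    "apply_bias_correction",
    "filter_outliers",
    "summarize_errors",
    "hemifield_contrast",
    "analyze_responses",
]

RESPONSE_COLUMNS = (
    "subject",
    "condition",
    "block",
    "target_azimuth_deg",
    "target_elevation_deg",
    "response_azimuth_deg",
    "response_elevation_deg",
    "repetition",
    "handedness",
)

DEFAULT_OUTLIER_THRESHOLD_DEG = 45.0


@dataclass(frozen=True)
class BiasEstimate:
    """Group and per-subject pointing bias in degrees."""

    azimuth: float
    elevation: float
    per_subject: pd.DataFrame  # index: subject; columns: azimuth, elevation


@dataclass(frozen=True)
class OutlierResult:
    kept: pd.DataFrame
    removed: pd.DataFrame
    removed_fraction: float


def _validate(records: pd.DataFrame) -> None:
    missing = [c for c in RESPONSE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"response table is missing columns: {missing}")


def signed_error_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Attach ``azimuth_error_deg`` (wrapped) and ``elevation_error_deg``."""
    _validate(records)
    out = records.copy()
    out["azimuth_error_deg"] = wrap_azimuth(
        out["response_azimuth_deg"].to_numpy()
        - out["target_azimuth_deg"].to_numpy()
    )
    out["elevation_error_deg"] = (
        out["response_elevation_deg"] - out["target_elevation_deg"]
    )
    return out


def mirror_handedness(records: pd.DataFrame) -> pd.DataFrame:
    """Mirror left-handed subjects' data on the median plane (negate azimuths)."""
    _validate(records)
    out = records.copy()
    left = out["handedness"] == "left"
    for col in ("target_azimuth_deg", "response_azimuth_deg"):
        out.loc[left, col] = -out.loc[left, col]
    return out


def estimate_pointing_bias(
    records: pd.DataFrame, visual_conditions: list[str] | None = None
) -> BiasEstimate:
    """Per-subject mean signed error over the visual-search conditions.

    Subjects with no visual-search trials are excluded with a warning.  The
    group bias is the unweighted mean of the subject biases.
    """
    _validate(records)
    if len(records) == 0:
        raise ValueError("cannot estimate a pointing bias from an empty table")
    if visual_conditions is None:
        visual_conditions = cond.visual_search_slugs()
    visual = records[records["condition"].isin(visual_conditions)]
    skipped = sorted(
        set(records["subject"]) - set(visual["subject"])
    )
    if skipped:
        warnings.warn(
            f"no visual-search trials for subjects {skipped}; excluded from bias",
            stacklevel=2,
        )
    if len(visual) == 0:
        raise ValueError("no trials in the visual-search conditions")
    errs = signed_error_columns(visual)
    per_subject = (
        errs.groupby("subject")[["azimuth_error_deg", "elevation_error_deg"]]
        .mean()
        .rename(
            columns={"azimuth_error_deg": "azimuth", "elevation_error_deg": "elevation"}
        )
    )
    return BiasEstimate(
        azimuth=float(per_subject["azimuth"].mean()),
        elevation=float(per_subject["elevation"].mean()),
        per_subject=per_subject,
    )


def apply_bias_correction(
    records: pd.DataFrame,
    bias: BiasEstimate,
    exempt_conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Subtract each subject's bias from responses, except exempt conditions.

    By default the laser-pointer condition is exempt (the visible pointing ray
    provides its own feedback).  A subject present in ``records`` but absent
    from the bias estimate is an error.
    """
    _validate(records)
    if exempt_conditions is None:
        exempt_conditions = cond.bias_exempt_slugs()
    missing = sorted(set(records["subject"]) - set(bias.per_subject.index))
    if missing:
        raise ValueError(f"no bias estimate for subjects: {missing}")
    out = records.copy()
    apply_to = ~out["condition"].isin(exempt_conditions)
    az_bias = out["subject"].map(bias.per_subject["azimuth"]).to_numpy()
    el_bias = out["subject"].map(bias.per_subject["elevation"]).to_numpy()
    mask = apply_to.to_numpy()
    out.loc[mask, "response_azimuth_deg"] = wrap_azimuth(
        out.loc[mask, "response_azimuth_deg"].to_numpy() - az_bias[mask]
    )
    out.loc[mask, "response_elevation_deg"] = (
        out.loc[mask, "response_elevation_deg"].to_numpy() - el_bias[mask]
    )
    return out


def filter_outliers(
    records: pd.DataFrame, threshold: float = DEFAULT_OUTLIER_THRESHOLD_DEG
) -> OutlierResult:
    """Remove trials strictly farther than ``threshold`` deg from the target.

    A trial is an outlier iff |wrapped azimuth error| > threshold OR
    |elevation error| > threshold; an error of exactly the threshold is kept.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    errs = signed_error_columns(records)
    bad = (np.abs(errs["azimuth_error_deg"]) > threshold) | (
        np.abs(errs["elevation_error_deg"]) > threshold
    )
    kept = records[~bad.to_numpy()]
    removed = records[bad.to_numpy()]
    frac = float(len(removed) / len(records)) if len(records) else 0.0
    return OutlierResult(kept=kept, removed=removed, removed_fraction=frac)


def _boxplot_stats(values: np.ndarray) -> dict[str, float]:
    """Median, quartiles and Tukey whiskers of signed errors.

    Quartiles use linear interpolation (numpy's default), so boxplot
    statistics are reproducible bit-for-bit.  Whiskers extend to the most
    extreme datum within 1.5 IQR of the box.
    """
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_limit, hi_limit = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_limit) & (values <= hi_limit)]
    return {
        "median_signed": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
    }


def summarize_errors(
    records: pd.DataFrame,
    keys: tuple[str, ...] = ("condition", "target_azimuth_deg", "target_elevation_deg"),
) -> pd.DataFrame:
    """Long-format error table: one row per grouping cell and error dimension.

    Columns: the grouping keys, ``dimension`` (azimuth/elevation),
    ``mean_absolute``, ``median_signed``, ``q1``, ``q3``, ``whisker_low``,
    ``whisker_high`` and ``n``.  Empty groups are simply absent.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty response table")
    errs = signed_error_columns(records)
    rows = []
    for group_vals, chunk in errs.groupby(list(keys), sort=True):
        if not isinstance(group_vals, tuple):
            group_vals = (group_vals,)
        for dimension, col in (
            ("azimuth", "azimuth_error_deg"),
            ("elevation", "elevation_error_deg"),
        ):
            vals = chunk[col].to_numpy(dtype=float)
            row = dict(zip(keys, group_vals))
            row["dimension"] = dimension
            row["mean_absolute"] = float(np.mean(np.abs(vals)))
            row.update(_boxplot_stats(vals))
            row["n"] = int(len(vals))
            rows.append(row)
    return pd.DataFrame(rows)


def hemifield_contrast(
    table: pd.DataFrame, stat: str = "mean_absolute"
) -> pd.DataFrame:
    """Left-minus-right differences of a statistic at mirrored azimuths.

    ``table`` must be a :func:`summarize_errors` output grouped by signed
    target azimuth.  For each |azimuth| > 0 and each remaining grouping cell,
    the value at -azimuth minus the value at +azimuth is reported; cells with
    a missing mirror partner are skipped with a warning.  Azimuth 0 has no
    mirror and is excluded.
    """
    if "target_azimuth_deg" not in table.columns:
        raise ValueError("table must be grouped by target_azimuth_deg")
    other_keys = [
        c
        for c in table.columns
        if c
        not in (
            "target_azimuth_deg",
            stat,
            "mean_absolute",
            "median_signed",
            "q1",
            "q3",
            "whisker_low",
            "whisker_high",
            "n",
        )
    ]
    rows = []
    abs_az = np.abs(table["target_azimuth_deg"].to_numpy(dtype=float))
    for mag in sorted({a for a in abs_az if a > 0}):
        left = table[table["target_azimuth_deg"] == -mag]
        right = table[table["target_azimuth_deg"] == mag]
        # merge on a constant helper key when azimuth was the only grouping key
        join_keys = other_keys or ["_cell"]
        if not other_keys:
            left = left.assign(_cell=0)
            right = right.assign(_cell=0)
        merged = left.merge(
            right, on=join_keys, suffixes=("_left", "_right"),
            how="outer", indicator=True,
        )
        unmatched = merged[merged["_merge"] != "both"]
        if len(unmatched):
            warnings.warn(
                f"missing mirror cell(s) at |azimuth| {mag}; skipped", stacklevel=2
            )
        both = merged[merged["_merge"] == "both"]
        for _, r in both.iterrows():
            row = {k: r[k] for k in other_keys}
            row["abs_azimuth_deg"] = mag
            row["left_minus_right"] = float(r[f"{stat}_left"] - r[f"{stat}_right"])
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_responses(
    records: pd.DataFrame,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD_DEG,
    summary_keys: tuple[str, ...] = (
        "condition",
        "target_azimuth_deg",
        "target_elevation_deg",
    ),
) -> dict:
    """Run the full behavioral pipeline on a raw response log.

    Returns a dict with the mirrored records, bias estimate, corrected
    records, outlier result, the error table, and per-condition summaries.
    """
    mirrored = mirror_handedness(records)
    bias = estimate_pointing_bias(mirrored)
    corrected = apply_bias_correction(mirrored, bias)
    outliers = filter_outliers(corrected, outlier_threshold)
    table = summarize_errors(outliers.kept, summary_keys)
    by_condition = summarize_errors(outliers.kept, ("condition",))
    return {
        "mirrored": mirrored,
        "bias": bias,
        "corrected": corrected,
        "outliers": outliers,
        "error_table": table,
        "by_condition": by_condition,
    }
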