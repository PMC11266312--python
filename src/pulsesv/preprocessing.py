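"""Data-integrity filters and measured/predicted pairing.

Cleaning happens in a fixed order: the stroke-volume plausibility window
(61–145 mL inclusive, values outside attributed to movement artefact) first,
then the ±2 SD arterial-pressure outlier rule. Group statistics for the
pressure rule are computed in a single pass over the data as it stands, with
no re-iteration after removals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .types import Stratum, ValidationError

__all__ = [
    "CleaningReport",
    "filter_sv_plausibility",
    "filter_bp_outliers",
    "clean",
    "stratum_mask",
    "pair_series",
    "SV_PLAUSIBLE_LOW",
    "SV_PLAUSIBLE_HIGH",
]

SV_PLAUSIBLE_LOW = 61.0    # mL
SV_PLAUSIBLE_HIGH = 145.0  # mL

BP_GROUPINGS = ("global", "per_subject", "per_subject_stratum")


@dataclass
class CleaningReport:
    """Bookkeeping for one cleaning pass; counts partition the input."""

    n_input: int
    n_removed_sv_range: int
    n_removed_bp_outlier: int
    n_retained: int
    grouping_used: str = ""
    small_groups_passed: int = 0

    def __post_init__(self) -> None:
        if self.n_input != (
            self.n_retained + self.n_removed_sv_range + self.n_removed_bp_outlier
        ):
            raise ValidationError("cleaning counts do not partition the input")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_sv_plausibility(
    frame: pd.DataFrame,
    low: float = SV_PLAUSIBLE_LOW,
    high: float = SV_PLAUSIBLE_HIGH,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop records whose measured SV falls outside [low, high] mL (inclusive)."""
    n = len(frame)
    if n == 0:
        return frame.copy(), CleaningReport(0, 0, 0, 0)
    sv = frame["sv_measured"].to_numpy(dtype=float)
    keep = (sv >= low) & (sv <= high)
    out = frame.loc[keep].copy()
    report = CleaningReport(
        n_input=n,
        n_removed_sv_range=int(n - keep.sum()),
        n_removed_bp_outlier=0,
        n_retained=int(keep.sum()),
    )
    return out, report


def _group_keys(frame: pd.DataFrame, grouping: str) -> list:
    if grouping == "global":
        return [np.zeros(len(frame), dtype=int)]
    if grouping == "per_subject":
        return [frame["subject_id"]]
    if grouping == "per_subject_stratum":
        return [frame["subject_id"], frame["posture"], frame["condition"]]
    raise ValidationError(
        f"unknown BP-outlier grouping {grouping!r}; expected one of {BP_GROUPINGS}"
    )


def filter_bp_outliers(
    frame: pd.DataFrame,
    k: float = 2.0,
    grouping: str = "per_subject_stratum",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop records whose SAP *or* DAP deviates >k group SDs from the group mean.

    Group mean/SD (sample SD, n−1) are computed once on the incoming data;
    removal does not trigger re-computation. Groups with fewer than three
    records pass through untouched and are counted in the report.
    """
    n = len(frame)
    if n == 0:
        return frame.copy(), CleaningReport(0, 0, 0, 0, grouping_used=grouping)
    keys = _group_keys(frame, grouping)
    keep = np.ones(n, dtype=bool)
    small_groups = 0
    grouped = frame.groupby(keys, sort=False, observed=True)
    for _, idx in grouped.indices.items():
        sub = frame.iloc[idx]
        if len(sub) < 3:
            small_groups += 1
            continue
        if math.isinf(k):
            continue
        bad = np.zeros(len(sub), dtype=bool)
        for col in ("sap", "dap"):
            v = sub[col].to_numpy(dtype=float)
            mu, sd = v.mean(), v.std(ddof=1)
            if sd > 0:
                bad |= np.abs(v - mu) > k * sd
        keep[idx[bad]] = False
    out = frame.loc[keep].copy()
    report = CleaningReport(
        n_input=n,
        n_removed_sv_range=0,
        n_removed_bp_outlier=int(n - keep.sum()),
        n_retained=int(keep.sum()),
        grouping_used=grouping,
        small_groups_passed=small_groups,
    )
    return out, report


def clean(
    frame: pd.DataFrame,
    sv_low: float = SV_PLAUSIBLE_LOW,
    sv_high: float = SV_PLAUSIBLE_HIGH,
    bp_k: float = 2.0,
    bp_grouping: str = "per_subject_stratum",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Full cleaning pass: SV window first, then BP outliers (fixed order)."""
    after_sv, rep_sv = filter_sv_plausibility(frame, sv_low, sv_high)
    after_bp, rep_bp = filter_bp_outliers(after_sv, bp_k, bp_grouping)
    report = CleaningReport(
        n_input=rep_sv.n_input,
        n_removed_sv_range=rep_sv.n_removed_sv_range,
        n_removed_bp_outlier=rep_bp.n_removed_bp_outlier,
        n_retained=rep_bp.n_retained,
        grouping_used=bp_grouping,
        small_groups_passed=rep_bp.small_groups_passed,
    )
    return after_bp, report


def stratum_mask(frame: pd.DataFrame, stratum: Stratum) -> np.ndarray:
    """Boolean mask selecting the rows of one analysis cell."""
    mask = np.ones(len(frame), dtype=bool)
    if stratum.posture != "both":
        mask &= (frame["posture"] == stratum.posture).to_numpy()
    if stratum.condition != "both":
        mask &= (frame["condition"] == stratum.condition).to_numpy()
    return mask


def pair_series(
    frame: pd.DataFrame,
    predictions: pd.DataFrame,
    formula_id: str,
    stratum: Stratum | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (measured, predicted) arrays for one formula and stratum.

    ``predictions`` holds one column per formula, row-aligned with ``frame``
    (NaN where a formula was inapplicable for that subject); applicability
    exclusions therefore reduce n for that formula only. Returns empty arrays
    when the stratum contains no applicable pairs — callers treat that as an
    empty-stratum signal.
    """
    if len(predictions) != len(frame):
        raise ValidationError("predictions are not row-aligned with the records")
    if formula_id not in predictions.columns:
        raise KeyError(f"no predictions for formula {formula_id!r}")
    mask = (
        stratum_mask(frame, stratum) if stratum is not None else np.ones(len(frame), bool)
    )
    y = predictions[formula_id].to_numpy(dtype=float)
    mask &= np.isfinite(y)
    x = frame["sv_measured"].to_numpy(dtype=float)
    return x[mask], y[mask]
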