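"""Reduce parameter time series to per-channel scalar features.

The headline features are the sample standard deviations of each fitted
spectral parameter across the window time series, computed separately per
channel — a direct measure of how much the parameter fluctuates during the
recording.  Two contrasts are formed per feature: the pre-induction value and
the induction change (post minus pre, "delta").  Goodness-of-fit summaries
(mean and SD of the per-window MSE) are kept as a separate control family,
as is mean Lempel-Ziv complexity when present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .spectral import ParameterTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "MAIN_FEATURES",
    "CONTROL_FEATURES",
    "compute_variability",
    "compute_delta",
    "assemble_feature_tables",
]

#: The five spectral-variability features entering the main decoding family.
MAIN_FEATURES = (
    "sd_alpha_cf",
    "sd_alpha_amplitude",
    "sd_alpha_width",
    "sd_offset",
    "sd_exponent",
)

#: Goodness-of-fit control features, a separate multiple-testing family.
CONTROL_FEATURES = ("mean_mse", "sd_mse")

_SD_PARAM = {
    "sd_alpha_cf": "alpha_cf",
    "sd_alpha_amplitude": "alpha_amplitude",
    "sd_alpha_width": "alpha_width",
    "sd_offset": "offset",
    "sd_exponent": "exponent",
    "sd_mse": "mse",
}


@dataclass
class FeatureTable:
    """Subjects x channels matrix of one scalar feature plus group labels."""

    values: pd.DataFrame  # index: subject ids, columns: channel names
    feature_name: str
    condition_tag: str  # "pre" or "delta"
    labels: pd.Series  # subject id -> "high"/"low"

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels index must match the subject index")
        bad = set(self.labels.unique()) - {"high", "low"}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    @property
    def subject_ids(self) -> List[str]:
        return list(self.values.index)

    def as_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """(X, y) with y = 1 for the high group, 0 for the low group."""
        X = self.values.to_numpy(dtype=np.float64)
        y = (self.labels.to_numpy() == "high").astype(np.int64)
        return X, y


def compute_variability(pts: ParameterTimeSeries, parameter: str) -> pd.Series:
    """Sample SD (n-1 denominator) of one parameter over non-missing windows.

    Channels with fewer than two non-missing windows get NaN.
    """
    series = pts.parameter(parameter)
    n_valid = np.sum(np.isfinite(series), axis=1)
    with np.errstate(invalid="ignore"):
        sd = np.array(
            [
                np.nanstd(row[np.isfinite(row)], ddof=1) if n >= 2 else np.nan
                for row, n in zip(series, n_valid)
            ]
        )
    if np.any(n_valid < 2):
        logger.warning(
            "%d channel(s) have <2 valid windows for %s", int(np.sum(n_valid < 2)), parameter
        )
    return pd.Series(sd, index=pts.channel_names, name=parameter)


def _channel_mean(pts: ParameterTimeSeries, parameter: str) -> pd.Series:
    series = pts.parameter(parameter)
    with np.errstate(invalid="ignore"):
        m = np.nanmean(series, axis=1)
    return pd.Series(m, index=pts.channel_names, name=parameter)


def compute_delta(post: FeatureTable, pre: FeatureTable) -> FeatureTable:
    """Induction change: elementwise post minus pre."""
    if not post.values.index.equals(pre.values.index):
        raise ValueError("post and pre tables have different subjects")
    if list(post.values.columns) != list(pre.values.columns):
        raise ValueError("post and pre tables have different channels")
    return FeatureTable(
        post.values - pre.values,
        feature_name=post.feature_name,
        condition_tag="delta",
        labels=post.labels,
    )


def _feature_series(pts: ParameterTimeSeries, feature: str) -> pd.Series:
    if feature in _SD_PARAM:
        return compute_variability(pts, _SD_PARAM[feature])
    if feature == "mean_mse":
        return _channel_mean(pts, "mse")
    raise KeyError(f"unknown feature {feature!r}")


def assemble_feature_tables(
    cohort: Mapping[Tuple[str, str], ParameterTimeSeries],
    labels: Mapping[str, str],
    features: Iterable[str] = MAIN_FEATURES + CONTROL_FEATURES,
) -> Dict[Tuple[str, str], FeatureTable]:
    """Build every feature x {pre, delta} table for a cohort.

    ``cohort`` maps (subject_id, condition) to its parameter time series;
    both conditions must be present for every subject.  Subjects with any
    channel flagged by the alpha-coverage rule are excluded from all tables
    (their count is logged), mirroring the subject-level exclusion of
    recordings the parametrization cannot model.
    """
    subjects = sorted({sid for sid, _ in cohort})
    for sid in subjects:
        for cond in ("pre", "post"):
            if (sid, cond) not in cohort:
                raise ValueError(f"subject {sid!r} is missing condition {cond!r}")

    excluded = [
        sid
        for sid in subjects
        if cohort[(sid, "pre")].flagged_channels
        or cohort[(sid, "post")].flagged_channels
    ]
    if excluded:
        logger.warning(
            "excluding %d subject(s) by the alpha-coverage rule: %s",
            len(excluded),
            ",".join(excluded),
        )
    kept = [sid for sid in subjects if sid not in excluded]
    if not kept:
        raise ValueError("all subjects excluded by the coverage rule")
    label_series = pd.Series({sid: labels[sid] for sid in kept}, name="group")

    tables: Dict[Tuple[str, str], FeatureTable] = {}
    for feature in features:
        per_cond = {}
        for cond in ("pre", "post"):
            rows = {sid: _feature_series(cohort[(sid, cond)], feature) for sid in kept}
            per_cond[cond] = pd.DataFrame(rows).T.loc[kept]
        pre_tab = FeatureTable(per_cond["pre"], feature, "pre", label_series)
        post_tab = FeatureTable(per_cond["post"], feature, "post", label_series)
        tables[(feature, "pre")] = pre_tab
        tables[(feature, "delta")] = compute_delta(post_tab, pre_tab)
    return tables
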