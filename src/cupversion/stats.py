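"""Precision and agreement statistics for repeated anteversion measurements.

The repeated standard deviation (RSD) pools the within-patient spread of
repeated measurements:

    RSD = sqrt( sum_j sum_i (X_ij - Xbar_j)^2 / sum_j (n_j - 1) )

where X_ij is the i-th measurement of patient j, Xbar_j the patient mean
and n_j the patient's measurement count.  Lower RSD = higher precision.
Twice the RSD serves as the threshold beyond which a change between serial
films is read as a real change in cup orientation rather than measurement
noise.  Inter/intraobserver agreement uses the paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementSeries",
    "AgreementResult",
    "UndefinedRSDError",
    "repeated_sd",
    "change_threshold",
    "observer_agreement",
]


class UndefinedRSDError(ValueError):
    """RSD denominator is zero: no patient has a repeated measurement."""


@dataclass(frozen=True)
class MeasurementSeries:
    """Repeated anteversion values indexed by patient (and optionally
    observer/session), stored as a tidy DataFrame.

    Required columns: ``patient_id``, ``anteversion_deg``; optional:
    ``measurement_index``, ``observer_id``, ``session_id``, ``method``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"patient_id", "anteversion_deg"} - set(self.data.columns)
        if missing:
            raise ValueError(f"series is missing columns: {sorted(missing)}")
        if self.data.empty:
            raise ValueError("series is empty")
        if not np.all(np.isfinite(self.data["anteversion_deg"].to_numpy(float))):
            raise ValueError("anteversion values must be finite")

    @classmethod
    def from_values(cls, values: Mapping[str, Sequence[float]]) -> "MeasurementSeries":
        """Build a series from {patient_id: [values, ...]}."""
        rows = [
            {"patient_id": pid, "measurement_index": i, "anteversion_deg": float(x)}
            for pid, xs in values.items()
            for i, x in enumerate(xs)
        ]
        return cls(pd.DataFrame(rows))


@dataclass(frozen=True)
class AgreementResult:
    """Paired-comparison summary: mean difference (obs1 - obs2), t, p."""

    mean_difference: float
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False  # zero-variance differences: p undefined


def repeated_sd(series: MeasurementSeries) -> float:
    """Pooled within-patient (repeated) standard deviation, degrees.

    Patients with a single measurement contribute nothing to numerator or
    denominator and are skipped (their count is logged).  Raises
    :class:`UndefinedRSDError` when every patient has only one measurement.
    """
    grouped = series.data.groupby("patient_id")["anteversion_deg"]
    n_singleton = int((grouped.size() == 1).sum())
    if n_singleton:
        logger.info("repeated_sd: skipped %d patient(s) with a single measurement",
                    n_singleton)
    numerator = 0.0
    denominator = 0
    for _, values in grouped:
        x = values.to_numpy(float)
        if x.size < 2:
            continue
        numerator += float(np.sum((x - x.mean()) ** 2))
        denominator += x.size - 1
    if denominator == 0:
        raise UndefinedRSDError(
            "RSD undefined: no patient has more than one measurement"
        )
    return float(np.sqrt(numerator / denominator))


def change_threshold(rsd: float) -> float:
    """Significant-change threshold 2 x RSD, same units as the input.

    A difference from a patient's average anteversion exceeding twice the
    RSD on serial films is read as a real orientation change (roughly the
    95% level), e.g. an RSD of 0.795 deg gives a 1.59 deg threshold.
    """
    if rsd < 0:
        raise ValueError(f"RSD cannot be negative, got {rsd}")
    return 2.0 * rsd


def observer_agreement(pairs: Iterable[tuple[float, float]]) -> AgreementResult:
    """Two-sided paired t-test between two observers' measurements.

    The mean difference is reported with sign (observer 1 minus observer 2).
    When the differences have zero variance the t statistic and p-value are
    undefined; the result is flagged ``degenerate`` with NaNs rather than a
    fabricated p-value.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an iterable of (obs1, obs2) tuples")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs for a paired comparison")
    diff = arr[:, 0] - arr[:, 1]
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        return AgreementResult(mean_diff, float("nan"), float("nan"),
                               arr.shape[0], degenerate=True)
    t, p = sps.ttest_rel(arr[:, 0], arr[:, 1])
    return AgreementResult(mean_diff, float(t), float(p), arr.shape[0])
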