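"""Exposure-series reduction and QC.

Each array spot is imaged at several camera exposures; the fluorescence
signal grows (ideally linearly) with exposure time.  The reduction fits an
ordinary least-squares slope of signal on exposure per (sample, peptide)
series, multiplies it by 100 and log2-transforms it, yielding a single
value per peptide per sample.  Peptides whose fits are poor or whose
slopes are non-positive in any sample are removed before any kinase
statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PeptideValueMatrix",
    "fit_exposure_slope",
    "reduce_to_value",
    "process_signals",
    "qc_filter",
]

log = logging.getLogger(__name__)

DEFAULT_R2_MIN = 0.90
DEFAULT_MIN_SLOPE = 0.0  # exclusive


@dataclass
class PeptideValueMatrix:
    """Reduced per-peptide, per-sample values with fit diagnostics.

    All frames are peptides (rows) x samples (columns).  ``value`` is
    log2(100*slope) and is NaN where the slope is non-positive.  ``qc_pass``
    is per-peptide: a peptide is analyzed in all samples or in none.
    """

    slope: pd.DataFrame
    r2: pd.DataFrame
    value: pd.DataFrame
    qc_pass: pd.Series
    groups: pd.Series  # sample_id -> group label

    def passing_values(self) -> pd.DataFrame:
        """Value matrix restricted to QC-passing peptides."""
        return self.value.loc[self.qc_pass[self.qc_pass].index]


def _ols(y: np.ndarray, t: np.ndarray, model: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS of each row of ``y`` on ``t``. Returns (slope, r2).

    ``r2`` is the coefficient of determination against the centered total
    sum of squares (0 when the response has zero variance); clipped to
    [0, 1] so the through-origin variant stays on the same scale.
    """
    y = np.asarray(y, dtype=float)
    if model == "with_intercept":
        tc = t - t.mean()
        sxx = float(np.sum(tc**2))
        ym = y.mean(axis=1, keepdims=True)
        slope = (y - ym) @ tc / sxx
        intercept = ym[:, 0] - slope * t.mean()
        fitted = intercept[:, None] + slope[:, None] * t
    elif model == "through_origin":
        slope = y @ t / float(t @ t)
        fitted = slope[:, None] * t
    else:
        raise ValueError(f"unknown model {model!r}; use 'with_intercept' or 'through_origin'")
    ss_res = np.sum((y - fitted) ** 2, axis=1)
    ss_tot = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return slope, np.clip(r2, 0.0, 1.0)


def fit_exposure_slope(
    exposures, signals, model: str = "with_intercept", label: str = "series"
) -> tuple[float, float]:
    """OLS slope and r2 of one spot's signal vs exposure time series."""
    t = np.asarray(exposures, dtype=float)
    y = np.asarray(signals, dtype=float)
    if t.shape != y.shape:
        raise ValueError(f"{label}: exposures and signals differ in length")
    if np.unique(t).size < 2:
        raise ValueError(f"{label}: needs >=2 distinct exposure times")
    if np.any(t <= 0):
        raise ValueError(f"{label}: exposure times must be strictly positive")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"{label}: non-finite signal")
    slope, r2 = _ols(y[None, :], t, model)
    return float(slope[0]), float(r2[0])


def reduce_to_value(slope) -> np.ndarray | float:
    """log2(100 * slope); non-positive slopes map to NaN (missing), since
    the log of a non-positive rate is undefined and clamping would fake
    signal."""
    s = np.asarray(slope, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0, np.log2(np.maximum(100.0 * s, np.finfo(float).tiny)), np.nan)
    return float(out) if np.isscalar(slope) else out


def process_signals(
    frame: pd.DataFrame,
    model: str = "with_intercept",
    r2_min: float = DEFAULT_R2_MIN,
    min_slope: float = DEFAULT_MIN_SLOPE,
) -> PeptideValueMatrix:
    """Reduce a long-format signal table to a :class:`PeptideValueMatrix`.

    ``frame`` needs columns sample_id, peptide_id, exposure_ms, signal and
    optionally group.  Replicate spots of the same peptide on an array
    (duplicate (sample, peptide, exposure) rows) are averaged on the signal
    scale before fitting, with a log notice.  QC (see :func:`qc_filter`)
    is applied before returning.
    """
    required = {"sample_id", "peptide_id", "exposure_ms", "signal"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"signal table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(frame["signal"].to_numpy(float))):
        bad = frame.loc[~np.isfinite(frame["signal"].to_numpy(float))]
        raise ValueError(
            "non-finite signal for "
            f"(sample={bad.iloc[0]['sample_id']}, peptide={bad.iloc[0]['peptide_id']})"
        )
    if (frame["exposure_ms"] <= 0).any():
        raise ValueError("exposure times must be strictly positive")

    n_dup = frame.duplicated(["sample_id", "peptide_id", "exposure_ms"]).sum()
    if n_dup:
        log.info("averaging %d replicate spot readings before fitting", int(n_dup))
    piv = frame.pivot_table(
        index=["peptide_id", "sample_id"],
        columns="exposure_ms",
        values="signal",
        aggfunc="mean",
        sort=True,
    )
    if piv.isna().any().any():
        bad = piv.index[piv.isna().any(axis=1)][0]
        raise ValueError(f"incomplete exposure series for (peptide={bad[0]}, sample={bad[1]})")
    t = piv.columns.to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("needs >=2 distinct exposure times")

    slope_flat, r2_flat = _ols(piv.to_numpy(), t, model)
    slope = pd.Series(slope_flat, index=piv.index).unstack("sample_id")
    r2 = pd.Series(r2_flat, index=piv.index).unstack("sample_id")
    value = pd.DataFrame(reduce_to_value(slope.to_numpy()), index=slope.index, columns=slope.columns)

    if "group" in frame.columns:
        groups = frame.drop_duplicates("sample_id").set_index("sample_id")["group"]
        groups = groups.reindex(slope.columns)
    else:
        groups = pd.Series(index=slope.columns, dtype=object)
    groups.name = "group"

    matrix = PeptideValueMatrix(
        slope=slope,
        r2=r2,
        value=value,
        qc_pass=pd.Series(True, index=slope.index, name="qc_pass"),
        groups=groups,
    )
    return qc_filter(matrix, r2_min=r2_min, min_slope=min_slope)


def qc_filter(
    matrix: PeptideValueMatrix,
    r2_min: float = DEFAULT_R2_MIN,
    min_slope: float = DEFAULT_MIN_SLOPE,
) -> PeptideValueMatrix:
    """Set per-peptide QC: a peptide passes iff in *every* sample the fit
    r2 >= ``r2_min`` and the slope is strictly above ``min_slope``.

    The rule is per-peptide so that group statistics stay balanced: a
    peptide is either analyzed in all samples or excluded everywhere.
    """
    if not (0.0 <= r2_min <= 1.0):
        raise ValueError(f"r2_min must be in [0, 1], got {r2_min}")
    ok = (
        (matrix.r2 >= r2_min).all(axis=1)
        & (matrix.slope > min_slope).all(axis=1)
        & matrix.value.notna().all(axis=1)
    )
    n_fail = int((~ok).sum())
    if n_fail:
        log.info("QC removed %d/%d peptides (r2_min=%g, min_slope=%g)", n_fail, len(ok), r2_min, min_slope)
    return replace(matrix, qc_pass=ok.rename("qc_pass"))
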