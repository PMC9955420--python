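"""Healthy-control baseline with generalized ESD (Rosner) trimming and Z-scores.

Each array feature (antigen spot) gets its own baseline: the healthy-control
log2 intensities for that spot, minus any HC subjects flagged as outliers by
the generalized extreme studentized deviate (ESD) test of Rosner.  Z-scores
for every subject -- patients and controls alike -- are then the spot value
standardized against that trimmed baseline mean and SD.

The ESD test removes the most mean-distant point up to ``k_max`` times; at
step ``i`` (1-based, current sample size ``n - i + 1``) the test statistic

    R_i = max |x - mean| / sd

is compared with the two-sided critical value

    lambda_i = (n - i) * t_{p, n-i-1} / sqrt((n - i - 1 + t^2) (n - i + 1))

where ``t_{p, v}`` is the upper-``p`` quantile of Student's t with ``v``
degrees of freedom and ``p = alpha / (2 (n - i + 1))``.  The declared
outliers are the first ``j`` removals for the *largest* ``j`` with
``R_j > lambda_j`` (later exceedances re-include earlier removals).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BaselineStats, IntensityMatrix, ValidationError

__all__ = ["rosner_esd", "fit_baseline", "compute_zscores"]

logger = logging.getLogger(__name__)

#: trimmed baselines smaller than this fall back to untrimmed statistics
MIN_BASELINE_N = 5


def _esd_critical_value(n: int, i: int, alpha: float) -> float:
    # two-sided critical value for removal step i of n observations
    p = alpha / (2.0 * (n - i + 1))
    t = stats.t.ppf(1.0 - p, n - i - 1)
    return (n - i) * t / np.sqrt((n - i - 1 + t * t) * (n - i + 1))


def rosner_esd(values, k_max: int = 3, alpha: float = 0.01) -> set[int]:
    """Indices of outliers per the generalized ESD test.

    Parameters
    ----------
    values : array-like of float
        Measurements; must have at least ``k_max + 3`` entries for the test
        to run (otherwise an empty set is returned with a warning).
    k_max : int
        Maximum number of outliers to test for.
    alpha : float
        Two-sided significance level for each step.

    Returns
    -------
    set of int
        Positions (into ``values``) of the declared outliers; empty if none.
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < k_max + 3:
        warnings.warn(
            f"sample of size {n} too short for ESD with k_max={k_max}; no trimming",
            UserWarning,
            stacklevel=2,
        )
        return set()

    remaining = np.arange(n)
    current = x.copy()
    removed: list[int] = []
    exceeded: list[bool] = []
    for i in range(1, k_max + 1):
        mean = current.mean()
        sd = current.std(ddof=1)
        if sd == 0:
            exceeded.append(False)
            # removal order is arbitrary among ties; take the first
            j = 0
        else:
            dev = np.abs(current - mean)
            j = int(np.argmax(dev))
            r_i = dev[j] / sd
            exceeded.append(r_i > _esd_critical_value(n, i, alpha))
        removed.append(int(remaining[j]))
        remaining = np.delete(remaining, j)
        current = np.delete(current, j)

    n_out = 0
    for i in range(k_max, 0, -1):
        if exceeded[i - 1]:
            n_out = i
            break
    return set(removed[:n_out])


def fit_baseline(
    m: IntensityMatrix,
    hc_ids,
    k_max: int = 3,
    alpha: float = 0.01,
    sd_floor: float = 0.1,
) -> BaselineStats:
    """Per-feature trimmed healthy-control baseline.

    For every feature, the HC values are screened with :func:`rosner_esd`;
    flagged subjects are excluded for that feature only, and the mean/SD
    (``ddof=1``) of the remainder become the baseline.  SDs are clipped
    below at ``sd_floor`` (log2 units).  Features whose trimmed baseline
    would drop below ``MIN_BASELINE_N`` values keep the untrimmed
    statistics instead (logged).

    Set ``k_max=0`` to disable trimming entirely.
    """
    hc_ids = list(hc_ids)
    if len(hc_ids) == 0:
        raise ValidationError("HC sample set is empty")
    missing = [s for s in hc_ids if s not in m.sample_ids]
    if missing:
        raise ValidationError(f"HC ids absent from matrix: {missing[:5]}")
    if len(hc_ids) < 6:
        raise ValidationError(f"need >= 6 HC samples for a baseline, got {len(hc_ids)}")
    if m.scale != "log2":
        raise ValidationError("baseline expects a log2-scale matrix")
    if sd_floor <= 0:
        raise ValidationError("sd_floor must be positive")

    hc = m.values[hc_ids]
    arr = hc.to_numpy(dtype=float)
    means = np.empty(arr.shape[0])
    sds = np.empty(arr.shape[0])
    excluded: dict[str, tuple[str, ...]] = {}
    fallback: list[str] = []
    hc_index = np.asarray(hc_ids, dtype=object)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # short-vector warning, per feature
        for r, feat in enumerate(m.feature_ids):
            row = arr[r]
            out: set[int] = set()
            if k_max >= 1:
                out = rosner_esd(row, k_max=k_max, alpha=alpha)
            if out and len(row) - len(out) < MIN_BASELINE_N:
                fallback.append(feat)
                out = set()
            if out:
                keep = np.ones(row.size, dtype=bool)
                keep[list(out)] = False
                vals = row[keep]
                excluded[feat] = tuple(hc_index[sorted(out)])
            else:
                vals = row
            means[r] = vals.mean()
            sds[r] = vals.std(ddof=1) if vals.size > 1 else 0.0

    if fallback:
        logger.info(
            "%d features fell back to untrimmed baselines (too few HC values left)",
            len(fallback),
        )
    sds = np.maximum(sds, sd_floor)
    return BaselineStats(
        mean=pd.Series(means, index=m.feature_ids, name="baseline_mean"),
        sd=pd.Series(sds, index=m.feature_ids, name="baseline_sd"),
        excluded=excluded,
        hc_ids=tuple(hc_ids),
        k_max=k_max,
        alpha=alpha,
        sd_floor=sd_floor,
        fallback_features=tuple(fallback),
    )


def compute_zscores(m: IntensityMatrix, b: BaselineStats) -> pd.DataFrame:
    """Z-score matrix: ``(value - baseline_mean) / baseline_sd`` per feature.

    All samples are scored, including the healthy controls that built the
    baseline.  Returns a feature x sample DataFrame of finite values.
    """
    if not m.feature_ids.equals(b.mean.index):
        raise ValidationError("feature sets of matrix and baseline differ")
    z = m.values.sub(b.mean, axis=0).div(b.sd, axis=0)
    return z
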