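"""Core data containers shared across the pipeline stages.

The pipeline operates on feature x sample matrices (protein-array
intensities, Z-scores, log-expression) carried as pandas DataFrames with
row index = feature IDs and columns = sample IDs.  Thin dataclasses add
the semantic flags (channel, scale) and per-feature baseline statistics
that downstream stages need to validate their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "BaselineStats",
    "AnalysisConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_matrix(values: pd.DataFrame) -> None:
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated feature IDs: {dups[:5]}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated sample IDs: {dups[:5]}")
    if values.isna().any().any():
        raise ValidationError("matrix contains missing values")


@dataclass(frozen=True)
class IntensityMatrix:
    """Feature x sample array intensities.

    Parameters
    ----------
    values : DataFrame
        Rows are antigen (feature) IDs, columns sample IDs.
    channel : {"foreground", "background"}
        Which scanner channel the values came from.
    scale : {"raw", "log2"}
        Raw fluorescence units or log2-transformed.
    """

    values: pd.DataFrame
    channel: str = "foreground"
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.channel not in ("foreground", "background"):
            raise ValidationError(f"unknown channel {self.channel!r}")
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_matrix(self.values)
        arr = self.values.to_numpy(dtype=float)
        if self.scale == "raw":
            if (arr < 0).any():
                raise ValidationError("raw intensities must be >= 0")
        else:
            if not np.isfinite(arr).all():
                raise ValidationError("log2 intensities must be finite")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "IntensityMatrix":
        return replace(self, values=values, scale=scale or self.scale)


@dataclass(frozen=True)
class BaselineStats:
    """Per-feature healthy-control baseline after outlier trimming.

    ``mean``/``sd`` are indexed by feature ID (log2 units); ``excluded``
    maps feature ID -> tuple of HC sample IDs removed by the generalized
    ESD test for that feature.  ``sd`` is clipped below at ``sd_floor``.
    """

    mean: pd.Series
    sd: pd.Series
    excluded: dict[str, tuple[str, ...]]
    hc_ids: tuple[str, ...]
    k_max: int
    alpha: float
    sd_floor: float
    fallback_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValidationError("baseline mean/sd index mismatch")
        if (self.sd < self.sd_floor - 1e-12).any():
            raise ValidationError("baseline sd below sd_floor")
        for feat, excl in self.excluded.items():
            if len(excl) > self.k_max:
                raise ValidationError(
                    f"feature {feat}: {len(excl)} exclusions exceed k_max={self.k_max}"
                )

    def to_frame(self) -> pd.DataFrame:
        """Audit table: one row per feature."""
        return pd.DataFrame(
            {
                "baseline_mean": self.mean,
                "baseline_sd": self.sd,
                "n_excluded": [len(self.excluded.get(f, ())) for f in self.mean.index],
                "excluded_sample_ids": [
                    "|".join(self.excluded.get(f, ())) for f in self.mean.index
                ],
            }
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """All reactivity-analysis thresholds, defaulting to the published values.

    z_reactive
        Z-score cutoff defining a reactivity (default 5).
    prevalence_min
        Minimum within-group prevalence for an antigen to enter the group
        overlap set (default 0.30).
    threshold_grid
        Integer Z thresholds for the count curves (default 1..10).
    n_top_variance
        Features kept for the clustered heatmap (default 100).
    n_top_rank
        Reactivities/clones kept for ranked curves (default 4000).
    volcano_z_min, volcano_p_max
        Volcano significance cutoffs versus HC (defaults 1 and 0.05).
    """

    z_reactive: float = 5.0
    prevalence_min: float = 0.30
    threshold_grid: tuple[float, ...] = tuple(range(1, 11))
    n_top_variance: int = 100
    n_top_rank: int = 4000
    volcano_z_min: float = 1.0
    volcano_p_max: float = 0.05

    def __post_init__(self) -> None:
        if self.z_reactive <= 0:
            raise ValidationError("z_reactive must be positive")
        if not (0 < self.prevalence_min <= 1):
            raise ValidationError("prevalence_min must lie in (0, 1]")
        if len(self.threshold_grid) == 0:
            raise ValidationError("threshold_grid must be nonempty")
        if any(t <= 0 for t in self.threshold_grid):
            raise ValidationError("thresholds must be positive")
        if list(self.threshold_grid) != sorted(self.threshold_grid):
            raise ValidationError("threshold_grid must be ascending")
        if self.n_top_variance <= 0 or self.n_top_rank <= 0:
            raise ValidationError("top-n settings must be positive")
        if self.volcano_z_min <= 0 or not (0 < self.volcano_p_max <= 1):
            raise ValidationError("volcano cutoffs out of range")
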