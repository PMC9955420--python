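"""Reactivity statistics on the Z-score matrix.

Everything downstream of Z-scoring on the array arm: per-subject reactivity
counts across a threshold grid, median Z summaries, group-ranked reactivity
curves, volcano calling versus the healthy controls, shared-reactivity
overlap sets with per-subject overlap fractions, top-variance feature
selection with hierarchical clustering, the hot/cold stratification of the
SLE group, and a PCA embedding of subjects.

Conventions: a *reactivity* is a feature with Z strictly above the
``z_reactive`` cutoff (default 5); overlap membership requires that
fraction of group subjects to be at least ``prevalence_min`` (default 30%).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, linkage
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .containers import AnalysisConfig, ValidationError

__all__ = [
    "count_reactivities",
    "subject_median_z",
    "ranked_reactivity_curve",
    "volcano_vs_hc",
    "group_overlap_set",
    "subject_overlap_fraction",
    "top_variance_heatmap_input",
    "hot_cold_split",
    "pca_embedding",
]

logger = logging.getLogger(__name__)


def _check_samples(z: pd.DataFrame, ids, what: str) -> list[str]:
    ids = list(ids)
    missing = [s for s in ids if s not in z.columns]
    if missing:
        raise ValidationError(f"{what} samples absent from Z matrix: {missing[:5]}")
    return ids


def count_reactivities(z: pd.DataFrame, grid=None) -> pd.DataFrame:
    """Reactivity counts per subject at each threshold of the grid.

    Returns a sample x threshold DataFrame of counts of features with
    Z strictly above each threshold; monotone non-increasing across the
    (ascending) grid.
    """
    grid = tuple(grid) if grid is not None else AnalysisConfig().threshold_grid
    if list(grid) != sorted(grid):
        raise ValidationError("threshold grid must be ascending")
    arr = z.to_numpy(dtype=float)
    counts = {t: (arr > t).sum(axis=0) for t in grid}
    return pd.DataFrame(counts, index=z.columns)


def subject_median_z(z: pd.DataFrame, restrict_above: float | None = None) -> pd.Series:
    """Per-subject median Z, optionally over features with Z above a cutoff.

    Subjects with no qualifying feature get NaN (excluded from group
    summaries by the caller).
    """
    if restrict_above is None:
        return z.median(axis=0)
    masked = z.where(z > restrict_above)
    out = masked.median(axis=0)
    n_undef = int(out.isna().sum())
    if n_undef:
        logger.info("%d subjects have no feature above Z=%g", n_undef, restrict_above)
    return out


def ranked_reactivity_curve(z: pd.DataFrame, group_ids, n_top: int = 4000) -> np.ndarray:
    """Group reactivity curve: within-group median Z per feature, ranked.

    The per-feature group score is the median Z across the group's
    subjects; scores are sorted descending and the first ``n_top``
    returned (all of them when fewer features exist).
    """
    ids = _check_samples(z, group_ids, "group")
    if not ids:
        raise ValidationError("group is empty")
    score = z[ids].median(axis=1).to_numpy()
    score = np.sort(score)[::-1]
    return score[:n_top]


def volcano_vs_hc(
    z: pd.DataFrame,
    group_ids,
    hc_ids,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-feature effect and Welch-t p-value of a disease group versus HC.

    effect = mean Z within the disease group; p = two-sided Welch t test
    of the group's Z values against the HC Z values, per feature.  The
    ``significant`` flag applies the volcano cutoffs (effect above
    ``volcano_z_min`` and p below ``volcano_p_max``); ``top10`` marks the
    ten largest effects among significant features.

    Set ``cfg`` with a BH-adjusted column by passing a config whose
    ``volcano_p_max`` should apply to adjusted p-values via
    :func:`statsmodels.stats.multitest.multipletests`; adjustment is
    reported in the ``p_adj`` column but the default flag uses raw p.
    """
    cfg = cfg or AnalysisConfig()
    g = _check_samples(z, group_ids, "group")
    h = _check_samples(z, hc_ids, "HC")
    if len(g) < 2 or len(h) < 2:
        raise ValidationError("both groups need >= 2 subjects")
    ga = z[g].to_numpy(dtype=float)
    ha = z[h].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance features
        tstat, p = stats.ttest_ind(ga, ha, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    effect = ga.mean(axis=1)
    out = pd.DataFrame(
        {"effect": effect, "p": p, "p_adj": multipletests(p, method="fdr_bh")[1]},
        index=z.index,
    )
    out["significant"] = (out["effect"] > cfg.volcano_z_min) & (out["p"] < cfg.volcano_p_max)
    sig = out[out["significant"]].nlargest(10, "effect")
    out["top10"] = out.index.isin(sig.index)
    return out


def group_overlap_set(
    z: pd.DataFrame, group_ids, cfg: AnalysisConfig | None = None
) -> tuple[str, ...]:
    """Antigens reactive (Z > z_reactive) in >= prevalence_min of the group."""
    cfg = cfg or AnalysisConfig()
    ids = _check_samples(z, group_ids, "group")
    if not ids:
        raise ValidationError("group is empty")
    frac = (z[ids] > cfg.z_reactive).mean(axis=1)
    return tuple(z.index[frac >= cfg.prevalence_min])


def subject_overlap_fraction(
    z_row: pd.Series, overlap_set, cfg: AnalysisConfig | None = None
) -> float:
    """Fraction of the group overlap set on which a subject is reactive.

    Defined as 0 (with a warning) when the overlap set is empty.
    """
    cfg = cfg or AnalysisConfig()
    overlap_set = tuple(overlap_set)
    if not overlap_set:
        warnings.warn("empty overlap set; overlap fraction defined as 0", UserWarning,
                      stacklevel=2)
        return 0.0
    reactive = set(z_row.index[z_row > cfg.z_reactive])
    return len(reactive.intersection(overlap_set)) / len(overlap_set)


def overlap_summary(
    z: pd.DataFrame, metadata: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-subject overlap fractions against their own group's overlap set."""
    cfg = cfg or AnalysisConfig()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for g, members in metadata.groupby("group").groups.items():
            members = [m for m in members if m in z.columns]
            oset = group_overlap_set(z, members, cfg)
            for s in members:
                rows.append(
                    {
                        "sample_id": s,
                        "group": g,
                        "overlap_size": len(oset),
                        "overlap_fraction": subject_overlap_fraction(z[s], oset, cfg),
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def top_variance_heatmap_input(
    z: pd.DataFrame, n: int = 100
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Slice of the ``n`` highest-variance features with clustered orderings.

    Features are ranked by variance across all subjects; hierarchical
    clustering (Euclidean distance, Ward linkage) of the slice yields the
    row (feature) and column (subject) leaf orders.  Returns
    ``(slice in original order, feature_order, sample_order)``.
    """
    if n > z.shape[0]:
        raise ValidationError(f"requested {n} features but matrix has {z.shape[0]}")
    variances = z.var(axis=1)
    top = variances.nlargest(n).index
    block = z.loc[top]

    def _leaf_order(mat: np.ndarray, labels) -> list[str]:
        if mat.shape[0] < 2:
            return list(labels)
        lk = linkage(mat, method="ward", metric="euclidean")
        order = dendrogram(lk, no_plot=True)["leaves"]
        return [labels[i] for i in order]

    feature_order = _leaf_order(block.to_numpy(), list(block.index))
    sample_order = _leaf_order(block.to_numpy().T, list(block.columns))
    return block, feature_order, sample_order


def hot_cold_split(
    z: pd.DataFrame, sle_ids, cfg: AnalysisConfig | None = None
) -> pd.Series:
    """Two-way stratification of the SLE group into 'hot' and 'cold'.

    SLE subjects are clustered (Ward, Euclidean, 2 clusters) on the
    top-variance feature slice; the cluster with the higher mean Z over
    the SLE overlap set is labeled 'hot'.  Degenerate inputs (all
    subjects identical) yield a single cluster labeled 'cold'.
    """
    cfg = cfg or AnalysisConfig()
    ids = _check_samples(z, sle_ids, "SLE")
    if len(ids) < 4:
        raise ValidationError(f"need >= 4 SLE subjects, got {len(ids)}")
    n_feat = min(cfg.n_top_variance, z.shape[0])
    block, _, _ = top_variance_heatmap_input(z, n_feat)
    x = block[ids].to_numpy().T  # subjects x features

    if np.allclose(x, x[0]):
        warnings.warn("all SLE subjects identical; labeling all 'cold'", UserWarning,
                      stacklevel=2)
        return pd.Series("cold", index=pd.Index(ids, name="sample_id"), name="label")

    labels = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(x)
    oset = group_overlap_set(z, ids, cfg)
    if oset:
        score_block = z.loc[list(oset), ids]
    else:
        score_block = z[ids]
    cluster_mean = [
        score_block.loc[:, np.asarray(ids)[labels == c]].to_numpy().mean()
        for c in (0, 1)
    ]
    hot_cluster = int(np.argmax(cluster_mean))
    out = ["hot" if l == hot_cluster else "cold" for l in labels]
    return pd.Series(out, index=pd.Index(ids, name="sample_id"), name="label")


def pca_embedding(z: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of subjects on the Z matrix.

    Returns per-subject coordinates for the first components and the
    explained-variance fractions.  Component signs are an arbitrary
    convention.
    """
    if z.shape[1] < 3:
        raise ValidationError("need >= 3 subjects for a PCA embedding")
    n_components = min(n_components, z.shape[1] - 1, z.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(z.to_numpy().T)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=z.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
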