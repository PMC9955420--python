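"""Reactivity statistics: counts, medians, curves, volcano, overlap,
heatmap input, hot/cold stratification, PCA."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autorep.containers import AnalysisConfig, ValidationError
from autorep.reactivity import (
    count_reactivities,
    group_overlap_set,
    hot_cold_split,
    pca_embedding,
    ranked_reactivity_curve,
    subject_median_z,
    subject_overlap_fraction,
    top_variance_heatmap_input,
    volcano_vs_hc,
)


def _z(arr, samples=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return pd.DataFrame(
        arr,
        index=[f"F{i}" for i in range(arr.shape[0])],
        columns=samples or [f"S{i}" for i in range(arr.shape[1])],
    )


class TestCountReactivities:
    def test_null_and_single_feature(self):
        z = _z(np.zeros((5, 1)))
        assert (count_reactivities(z, range(1, 11)).to_numpy() == 0).all()
        z2 = _z([[7.0], [0.0]])
        counts = count_reactivities(z2, range(1, 11)).iloc[0]
        assert all(counts[t] == (1 if t < 7 else 0) for t in range(1, 11))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, seed):
        z = _z(np.random.default_rng(seed).normal(0, 3, (40, 5)))
        counts = count_reactivities(z, range(1, 11))
        assert (counts.to_numpy()[:, 1:] <= counts.to_numpy()[:, :-1]).all()

    def test_breadth_ordering_on_cohort(self, array_arm):
        """SLE plants many moderate reactivities; APECED plants few, strong."""
        counts = count_reactivities(array_arm.z, [5])[5]
        groups = array_arm.metadata["group"]
        sle_med = counts[groups == "SLE"].median()
        ap_med = counts[groups == "APECED"].median()
        hc_med = counts[groups == "HC"].median()
        assert sle_med > ap_med / 4  # SLE breadth comparable despite weak shifts
        assert min(sle_med, ap_med) > hc_med


class TestSubjectMedianZ:
    def test_symmetric_null_near_zero(self):
        z = _z(np.random.default_rng(0).normal(0, 1, (501, 1)))
        assert abs(subject_median_z(z).iloc[0]) < 0.2

    def test_restricted_median(self):
        z = _z([[6.0], [8.0], [10.0], [0.0]])
        assert subject_median_z(z, restrict_above=5).iloc[0] == 8.0

    def test_no_qualifying_feature_is_nan(self):
        z = _z([[1.0], [2.0]])
        assert np.isnan(subject_median_z(z, restrict_above=5).iloc[0])

    def test_focused_group_has_higher_reactive_median(self, array_arm):
        med = subject_median_z(array_arm.z, restrict_above=5)
        groups = array_arm.metadata["group"]
        assert med[groups == "APECED"].median() > med[groups == "SLE"].median()


class TestRankedCurve:
    def test_sorted_descending_and_null(self):
        z = _z(np.random.default_rng(1).normal(0, 1, (50, 4)))
        curve = ranked_reactivity_curve(z, z.columns, n_top=30)
        assert (np.diff(curve) <= 0).all()
        assert abs(curve).max() < 3

    def test_focused_vs_broad_crossing(self, array_arm):
        """APECED's curve starts higher (strong targets) but falls below
        SLE's at high rank (fewer targets overall)."""
        groups = array_arm.metadata["group"]
        ap = ranked_reactivity_curve(array_arm.z, groups.index[groups == "APECED"], 500)
        sle = ranked_reactivity_curve(array_arm.z, groups.index[groups == "SLE"], 500)
        assert ap[0] > sle[0]
        assert ap[200] < sle[200]


class TestVolcano:
    def test_null_size_close_to_nominal(self):
        rng = np.random.default_rng(2)
        z = _z(rng.normal(0, 1, (2000, 40)))
        out = volcano_vs_hc(z, z.columns[:20], z.columns[20:])
        frac = (out["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_planted_feature_reaches_top10(self):
        rng = np.random.default_rng(3)
        z = _z(rng.normal(0, 1, (100, 12)))
        z.iloc[7, :6] += 10.0
        out = volcano_vs_hc(z, z.columns[:6], z.columns[6:])
        assert out["top10"].iloc[7]
        assert out["significant"].iloc[7]

    def test_group_size_validation(self):
        z = _z(np.zeros((3, 4)))
        with pytest.raises(ValidationError, match=">= 2"):
            volcano_vs_hc(z, z.columns[:1], z.columns[1:])


class TestOverlap:
    def test_planted_sjs_targets_recovered_exactly(self, array_arm):
        groups = array_arm.metadata["group"]
        oset = group_overlap_set(array_arm.z, groups.index[groups == "SjS"])
        assert set(oset) == set(array_arm.truth.group_targets["SjS"])

    def test_null_hc_overlap_empty(self, array_arm):
        groups = array_arm.metadata["group"]
        oset = group_overlap_set(array_arm.z, groups.index[groups == "HC"])
        assert oset == ()

    def test_full_prevalence_is_subset_of_each_subject(self):
        rng = np.random.default_rng(4)
        z = _z(rng.normal(0, 3, (50, 6)))
        cfg = AnalysisConfig(prevalence_min=1.0)
        oset = group_overlap_set(z, z.columns, cfg)
        for s in z.columns:
            reactive = set(z.index[z[s] > cfg.z_reactive])
            assert set(oset) <= reactive

    def test_shrinks_with_stricter_thresholds(self):
        rng = np.random.default_rng(5)
        z = _z(rng.normal(2, 3, (200, 10)))
        base = set(group_overlap_set(z, z.columns, AnalysisConfig(z_reactive=4,
                                                                  prevalence_min=0.2)))
        tighter_z = set(group_overlap_set(z, z.columns, AnalysisConfig(z_reactive=6,
                                                                       prevalence_min=0.2)))
        tighter_p = set(group_overlap_set(z, z.columns, AnalysisConfig(z_reactive=4,
                                                                       prevalence_min=0.5)))
        assert tighter_z <= base and tighter_p <= base

    @pytest.mark.parametrize(
        "reactive_n,total,expected", [(44, 44, 1.0), (0, 44, 0.0), (22, 44, 0.5)]
    )
    def test_overlap_fraction_arithmetic(self, reactive_n, total, expected):
        oset = [f"F{i}" for i in range(total)]
        row = pd.Series(
            [10.0] * reactive_n + [0.0] * (total - reactive_n), index=oset
        )
        assert subject_overlap_fraction(row, oset) == expected

    def test_empty_overlap_set_warns_and_returns_zero(self):
        row = pd.Series([10.0], index=["F0"])
        with pytest.warns(UserWarning, match="empty overlap"):
            assert subject_overlap_fraction(row, []) == 0.0


class TestHeatmapInput:
    def test_constant_features_never_selected(self):
        rng = np.random.default_rng(6)
        z = _z(np.vstack([np.zeros((5, 8)), rng.normal(0, 1, (20, 8))]))
        block, feat_order, sample_order = top_variance_heatmap_input(z, 10)
        assert not any(f in block.index for f in [f"F{i}" for i in range(5)])
        assert sorted(feat_order) == sorted(block.index)
        assert sorted(sample_order) == sorted(z.columns)

    def test_planted_targets_dominate_selection(self, array_arm):
        block, _, _ = top_variance_heatmap_input(array_arm.z, 100)
        planted = set().union(*array_arm.truth.group_targets.values())
        assert len(set(block.index) & planted) >= 80


class TestHotColdSplit:
    def test_planted_labels_recovered(self, array_arm):
        groups = array_arm.metadata["group"]
        sle = groups.index[groups == "SLE"].tolist()
        labels = hot_cold_split(array_arm.z, sle)
        agree = np.mean(
            [(labels[s] == "hot") == bool(array_arm.truth.hot[s]) for s in sle]
        )
        assert agree >= 0.9

    def test_identical_subjects_all_cold(self):
        z = _z(np.ones((30, 6)))
        with pytest.warns(UserWarning, match="identical"):
            labels = hot_cold_split(z, z.columns)
        assert (labels == "cold").all()

    def test_too_few_subjects_rejected(self):
        z = _z(np.random.default_rng(7).normal(0, 1, (30, 3)))
        with pytest.raises(ValidationError, match=">= 4"):
            hot_cold_split(z, z.columns)


class TestPCA:
    def test_explained_variance_fractions(self, array_arm):
        coords, evr = pca_embedding(array_arm.z)
        assert evr.sum() <= 1.0 + 1e-9
        assert coords.shape == (array_arm.z.shape[1], 2)

    def test_disease_groups_separate_from_hc(self, array_arm):
        coords, _ = pca_embedding(array_arm.z)
        groups = array_arm.metadata["group"]
        hc = coords.loc[groups.index[groups == "HC"]]
        spread = np.linalg.norm(hc.to_numpy() - hc.to_numpy().mean(0), axis=1).mean()
        for g in ("APECED", "SLE"):
            centroid = coords.loc[groups.index[groups == g]].mean()
            assert np.linalg.norm(centroid - hc.mean()) > spread

    def test_embedding_defined_up_to_sign(self):
        rng = np.random.default_rng(8)
        z = _z(rng.normal(0, 1, (30, 10)))
        c1, _ = pca_embedding(z)
        c2, _ = pca_embedding(z.iloc[::-1])  # row order must not matter
        for col in c1.columns:
            assert np.allclose(c1[col], c2[col], atol=1e-8) or np.allclose(
                c1[col], -c2[col], atol=1e-8
            )
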