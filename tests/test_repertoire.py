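"""Clonotype collapsing, Gini/R20 clonality, VH usage, CDR3, SHM, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autorep.containers import ValidationError
from autorep.repertoire import (
    cdr3_length_stats,
    cohort_vh_usage,
    collapse_clonotypes,
    gini_index,
    group_compare,
    r20,
    rank_fraction_curve,
    shm_rate,
    strip_allele,
    vh_usage,
)


def gini_oracle(freqs):
    """Direct double sum over all pairs."""
    x = np.asarray(freqs, dtype=float)
    n = x.size
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * x.sum()))


def r20_oracle(freqs, target=0.2):
    """Cumulative scan over descending frequencies."""
    shares = np.sort(np.asarray(freqs, dtype=float))[::-1]
    shares = shares / shares.sum()
    cum = 0.0
    for m, s in enumerate(shares, start=1):
        cum += s
        if cum >= target - 1e-12:
            return m / shares.size
    return 1.0


def mwu_oracle(x, y):
    """U = count of x>y pairs plus half the ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


def _airr(rows):
    return pd.DataFrame(rows)


class TestCollapse:
    def test_same_key_counts_summed(self):
        t = collapse_clonotypes(
            _airr(
                [
                    {"sequence_id": "a", "v_call": "IGHV1-2*01", "junction_aa": "CARW",
                     "duplicate_count": 3},
                    {"sequence_id": "b", "v_call": "IGHV1-2*02", "junction_aa": "CARW",
                     "duplicate_count": 2},
                    {"sequence_id": "c", "v_call": "IGHV3-7*01", "junction_aa": "CASSW",
                     "duplicate_count": 5},
                ]
            )
        )
        assert len(t) == 2
        row = t[t["v_gene"] == "IGHV1-2"].iloc[0]
        assert row["umi_count"] == 5  # allele suffixes collapse together
        assert t["frequency"].sum() == pytest.approx(1.0)

    def test_missing_column_named(self):
        with pytest.raises(ValidationError, match="junction_aa"):
            collapse_clonotypes(
                _airr([{"sequence_id": "a", "v_call": "x", "duplicate_count": 1}])
            )

    def test_zero_total_umis_rejected(self):
        with pytest.raises(ValidationError, match="zero total"):
            collapse_clonotypes(
                _airr([{"sequence_id": "a", "v_call": "IGHV1-2*01",
                        "junction_aa": "CARW", "duplicate_count": 0}])
            )

    def test_strip_allele(self):
        assert strip_allele("IGHV4-34*03") == "IGHV4-34"
        assert strip_allele("IGHV4-34") == "IGHV4-34"


class TestRankFractionCurve:
    def test_uniform_then_zero_padding(self):
        t = pd.DataFrame({"frequency": [0.1] * 10})
        curve = rank_fraction_curve(t, n_top=15)
        assert np.allclose(curve[:10], 0.1)
        assert (curve[10:] == 0).all()

    def test_single_clone(self):
        curve = rank_fraction_curve(pd.DataFrame({"frequency": [1.0]}), n_top=5)
        assert curve[0] == 1.0 and (curve[1:] == 0).all()

    def test_expanded_group_dominates_rank_one(self, bcr_arm):
        groups = bcr_arm.truth.group
        top1 = {
            s: rank_fraction_curve(collapse_clonotypes(t), 1)[0]
            for s, t in bcr_arm.tables.items()
        }
        top1 = pd.Series(top1)
        assert top1[groups == "APECED"].median() > top1[groups == "SLE"].median()


class TestGini:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([0.25] * 4, 0.0), ([1.0], 0.0), ([0.7, 0.1, 0.1, 0.1], 0.45)],
    )
    def test_closed_form_values(self, freqs, expected):
        assert gini_index(freqs) == pytest.approx(expected, abs=1e-12)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.dirichlet(np.full(int(rng.integers(2, 60)), rng.uniform(0.1, 5)))
            assert gini_index(x) == pytest.approx(gini_oracle(x), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            gini_index([0.0, 0.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_invariant_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.dirichlet(np.full(20, 0.5))
        g = gini_index(x)
        assert 0 <= g < 1
        assert gini_index(rng.permutation(x)) == pytest.approx(g, abs=1e-12)

    def test_moving_mass_to_major_clone_increases_gini(self):
        x = np.array([0.4, 0.3, 0.2, 0.1])
        moved = np.array([0.45, 0.3, 0.2, 0.05])
        assert gini_index(moved) > gini_index(x)
        assert r20(moved) <= r20(x)


class TestR20:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([0.1] * 10, 0.2), ([0.9] + [0.1 / 9] * 9, 0.1), ([1.0], 1.0)],
    )
    def test_closed_form_values(self, freqs, expected):
        assert r20(freqs) == pytest.approx(expected)

    def test_matches_cumulative_scan_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            x = rng.dirichlet(np.full(int(rng.integers(1, 80)), rng.uniform(0.05, 5)))
            assert r20(x) == pytest.approx(r20_oracle(x))

    def test_target_fraction_validation(self):
        with pytest.raises(ValidationError):
            r20([0.5, 0.5], target_fraction=0.0)


class TestVhUsage:
    def test_single_gene_usage_is_one(self):
        t = pd.DataFrame({"v_gene": ["IGHV1-2"] * 4, "umi_count": [1, 2, 3, 4]})
        assert vh_usage(t)["IGHV1-2"] == 1.0
        assert vh_usage(t, weighting="umi")["IGHV1-2"] == 1.0

    def test_top_truncation_sums_below_one(self, bcr_arm):
        tables = {s: collapse_clonotypes(t) for s, t in bcr_arm.tables.items()}
        usage = cohort_vh_usage(tables, bcr_arm.truth.group, n_top=30)
        assert usage.shape[0] == 30
        assert (usage.sum(axis=0) <= 1.0 + 1e-9).all()

    def test_planted_multinomial_recovered(self):
        """Long-tailed planted usage is recovered within sampling error."""
        from autorep.simulate import VH_GENES

        planted = 1.0 / (np.arange(len(VH_GENES)) + 2.0)
        planted /= planted.sum()
        rng = np.random.default_rng(2)
        draws = rng.choice(len(VH_GENES), 10_000, p=planted)
        t = pd.DataFrame(
            {"v_gene": [VH_GENES[i] for i in draws], "umi_count": np.ones(10_000)}
        )
        usage = vh_usage(t)
        for k in range(5):
            assert usage[VH_GENES[k]] == pytest.approx(planted[k], abs=0.02)


class TestCdr3:
    def test_anchor_convention(self):
        t = pd.DataFrame({"junction_aa": ["C" + "A" * 13 + "W"]})
        hist, mean = cdr3_length_stats(t)
        assert mean == 13.0
        assert hist.loc[13] == 1

    def test_short_junctions_skipped(self):
        t = pd.DataFrame({"junction_aa": ["CW", "CARW"]})
        hist, mean = cdr3_length_stats(t)
        assert mean == 2.0 and hist.sum() == 1

    def test_planted_gaussian_mean_recovered(self, bcr_arm):
        means = []
        for t in list(bcr_arm.tables.values())[:20]:
            _, m = cdr3_length_stats(t)
            means.append(m)
        assert np.mean(means) == pytest.approx(15.0, abs=0.2)


class TestShm:
    def test_all_zero_counts(self):
        t = pd.DataFrame(
            {"umi_count": [1, 2], **{f"mu_count_{r}": [0, 0]
                                     for r in ("fr1", "cdr1", "fr2", "cdr2", "fr3")}}
        )
        assert shm_rate(t)["overall"] == 0.0

    def test_region_sums_equal_overall(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(
            {
                "umi_count": rng.integers(1, 10, 50),
                **{f"mu_count_{r}": rng.poisson(3, 50)
                   for r in ("fr1", "cdr1", "fr2", "cdr2", "fr3")},
            }
        )
        rates = shm_rate(t)
        regions = [k for k in rates.index if k != "overall"]
        assert rates["overall"] == pytest.approx(rates[regions].sum())

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError, match="mutation-count"):
            shm_rate(pd.DataFrame({"umi_count": [1]}))

    def test_planted_poisson_means_recovered(self, bcr_arm, design):
        from autorep.simulate import REGION_WEIGHTS

        summary = bcr_arm.summary
        for g, params in design.repertoire_params.items():
            grp = summary[summary["group"] == g]
            for region, w in REGION_WEIGHTS.items():
                est = grp[f"shm_{region}"].mean()
                assert est == pytest.approx(params.mutation_mean * w, rel=0.05)


class TestGroupCompare:
    def test_u_statistic_matches_pair_counting(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            nx, ny = rng.integers(2, 10, 2)
            x = rng.integers(0, 6, nx).astype(float)  # integers force ties
            y = rng.integers(0, 6, ny).astype(float)
            values = pd.Series(np.concatenate([x, y]),
                               index=[f"s{i}" for i in range(nx + ny)])
            groups = pd.Series(["A"] * nx + ["HC"] * ny, index=values.index)
            out = group_compare(values, groups)
            assert out.iloc[0]["U"] == pytest.approx(mwu_oracle(x, y))

    def test_identical_samples_not_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["A"] * 3 + ["HC"] * 3, index=values.index)
        out = group_compare(values, groups)
        assert out.iloc[0]["p"] > 0.5

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(5)
        values = pd.Series(rng.normal(0, 1, 40), index=[f"s{i}" for i in range(40)])
        groups = pd.Series(
            ["A"] * 10 + ["B"] * 10 + ["C"] * 10 + ["HC"] * 10, index=values.index
        )
        out = group_compare(values, groups).sort_values("p")
        assert (out["fdr"] >= out["p"] - 1e-12).all()
        assert (np.diff(out["fdr"]) >= -1e-12).all()


class TestPlantedClonality:
    def test_group_ordering_matches_design(self, bcr_arm):
        """Expanded APECED repertoires: higher Gini, lower R20 than HC;
        high-evenness SLE at or below the HC median Gini."""
        med = bcr_arm.summary.groupby("group")[["gini", "r20"]].median()
        assert med.loc["APECED", "gini"] > med.loc["HC", "gini"]
        assert med.loc["APECED", "r20"] < med.loc["HC", "r20"]
        assert med.loc["SLE", "gini"] <= med.loc["HC", "gini"]

    def test_autoimmune_shm_below_hc(self, bcr_arm):
        med = bcr_arm.summary.groupby("group")["shm_overall"].median()
        for g in ("APECED", "SjS", "SLE"):
            assert med[g] < med["HC"]
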