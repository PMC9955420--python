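"""Clonotype collapsing and repertoire clonality statistics.

A *clonotype* here is a (V gene stripped of allele, junction amino-acid
sequence) class; UMI counts are summed within it.  Clonality is summarized
by the Gini index of the clone-frequency distribution (0 = perfectly even)
and R20, the fraction of unique clones needed to account for 20% of the
sequenced repertoire mass (lower = more clonally dominated).  VH usage,
CDR3 length and per-region mutation loads round out the per-subject
summary; group comparisons use the two-sided Mann-Whitney U test with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError
from .simulate import V_REGIONS

__all__ = [
    "collapse_clonotypes",
    "rank_fraction_curve",
    "gini_index",
    "r20",
    "vh_usage",
    "cdr3_length_stats",
    "shm_rate",
    "group_compare",
    "repertoire_summary",
]

logger = logging.getLogger(__name__)

REQUIRED_AIRR_COLUMNS = ("sequence_id", "v_call", "junction_aa", "duplicate_count")
MUTATION_COLUMNS = tuple(f"mu_count_{r}" for r in V_REGIONS)


def strip_allele(v_call: str) -> str:
    """Drop the allele suffix from an IMGT-style gene call (IGHV1-2*01 -> IGHV1-2)."""
    return v_call.split("*", 1)[0]


def collapse_clonotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse AIRR rearrangement records into a clonotype table.

    Records are grouped by (allele-stripped V gene, junction_aa); UMI
    (``duplicate_count``) values are summed and frequencies computed over
    the subject total.  Per-region mutation-count columns, when present,
    are carried through as UMI-weighted means within the clonotype.
    """
    missing = [c for c in REQUIRED_AIRR_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"missing required AIRR columns: {missing}")
    if len(records) == 0:
        raise ValidationError("empty rearrangement table")
    counts = pd.to_numeric(records["duplicate_count"], errors="raise")
    if (counts < 0).any():
        raise ValidationError("negative duplicate_count")
    total = counts.sum()
    if total == 0:
        raise ValidationError("zero total UMIs")

    df = records.copy()
    df["duplicate_count"] = counts
    df["v_gene"] = df["v_call"].map(strip_allele)
    mut_cols = [c for c in MUTATION_COLUMNS if c in df.columns]

    agg = {"duplicate_count": "sum"}
    grouped = df.groupby(["v_gene", "junction_aa"], sort=True)
    out = grouped.agg(agg).reset_index()
    if mut_cols:
        # UMI-weighted mean mutation load per clonotype
        weighted = df[mut_cols].multiply(df["duplicate_count"], axis=0)
        wsum = weighted.groupby([df["v_gene"], df["junction_aa"]], sort=True).sum()
        denom = out.set_index(["v_gene", "junction_aa"])["duplicate_count"]
        out[mut_cols] = wsum.div(denom, axis=0).reset_index(drop=True)
    out = out.rename(columns={"duplicate_count": "umi_count"})
    out["frequency"] = out["umi_count"] / total
    return out.sort_values("umi_count", ascending=False, kind="stable").reset_index(
        drop=True
    )


def _check_freqs(freqs) -> np.ndarray:
    x = np.asarray(freqs, dtype=float)
    if x.size == 0:
        raise ValidationError("empty frequency vector")
    if (x < 0).any():
        raise ValidationError("negative frequencies")
    if x.sum() == 0:
        raise ValidationError("all-zero frequency vector")
    return x


def rank_fraction_curve(table: pd.DataFrame, n_top: int = 4000) -> np.ndarray:
    """Clone frequencies in descending rank order, zero-padded to ``n_top``."""
    freqs = np.sort(table["frequency"].to_numpy())[::-1]
    if freqs.size >= n_top:
        return freqs[:n_top]
    return np.pad(freqs, (0, n_top - freqs.size))


def gini_index(freqs) -> float:
    """Gini index of a clone-frequency vector.

    Population mean-absolute-difference form
    ``G = sum_ij |x_i - x_j| / (2 n sum_k x_k)``; 0 for a perfectly even
    repertoire (and for a single clone), approaching 1 for complete
    dominance.
    """
    x = _check_freqs(freqs)
    n = x.size
    if n == 1:
        return 0.0
    # sorted form of the pairwise sum: O(n log n)
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    g = ((2 * i - n - 1) * xs).sum() / (n * xs.sum())
    return float(max(0.0, g))  # exact-equality case can round to -1e-17


def r20(freqs, target_fraction: float = 0.2) -> float:
    """Fraction of unique clones accounting for ``target_fraction`` of the mass.

    Clones are taken in stable descending-frequency order; the smallest
    prefix whose cumulative share reaches the target counts fully (no
    fractional interpolation).
    """
    if not (0 < target_fraction <= 1):
        raise ValidationError("target_fraction must lie in (0, 1]")
    x = _check_freqs(freqs)
    shares = np.sort(x)[::-1] / x.sum()
    cum = np.cumsum(shares)
    m = int(np.searchsorted(cum, target_fraction - 1e-12) + 1)
    return m / x.size


def vh_usage(table: pd.DataFrame, weighting: str = "clone") -> pd.Series:
    """Relative VH gene frequency for one subject's clonotype table.

    ``weighting="clone"`` counts each clonotype once; ``"umi"`` weights by
    UMI count.
    """
    if weighting not in ("clone", "umi"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    if "v_gene" in table.columns:
        genes = table["v_gene"]
    else:
        genes = table["v_call"].map(strip_allele)
    if weighting == "clone":
        counts = genes.value_counts()
    else:
        counts = table.groupby(genes)["umi_count"].sum().sort_values(ascending=False)
    return counts / counts.sum()


def cohort_vh_usage(
    tables: dict[str, pd.DataFrame],
    groups: pd.Series,
    n_top: int = 30,
    weighting: str = "clone",
) -> pd.DataFrame:
    """Group-mean VH usage restricted to the cohort-wide top ``n_top`` genes.

    Per subject, usage frequencies are computed with :func:`vh_usage`;
    genes are ranked by the cohort-wide mean frequency and the top
    ``n_top`` kept; returned as genes x groups means.
    """
    per_subject = pd.DataFrame(
        {s: vh_usage(t, weighting=weighting) for s, t in tables.items()}
    ).fillna(0.0)
    top = per_subject.mean(axis=1).nlargest(n_top).index
    block = per_subject.loc[top]
    return block.T.groupby(groups.reindex(block.columns)).mean().T


def cdr3_length_stats(table: pd.DataFrame) -> tuple[pd.Series, float]:
    """CDR3 length histogram and mean for one subject.

    CDR3 length = len(junction_aa) - 2 (the conserved anchor residues are
    excluded).  Junctions shorter than 3 residues are skipped (logged).
    Returns ``(length counts indexed by length, mean length)``.
    """
    if "junction_aa" not in table.columns:
        raise ValidationError("junction_aa column missing")
    lengths = table["junction_aa"].astype(str).str.len() - 2
    bad = int((lengths < 1).sum())
    if bad:
        logger.info("skipped %d records with junctions shorter than 3 aa", bad)
    lengths = lengths[lengths >= 1]
    hist = lengths.value_counts().sort_index()
    return hist, float(lengths.mean())


def shm_rate(table: pd.DataFrame, umi_weighted: bool = False) -> pd.Series:
    """Mean mutations per V gene, overall and per region, for one subject.

    Requires the per-region mutation-count columns; when absent, returns
    an overall-only series if a total column exists, else raises.
    """
    mut_cols = [c for c in MUTATION_COLUMNS if c in table.columns]
    if not mut_cols:
        raise ValidationError("no per-region mutation-count columns present")
    if len(mut_cols) < len(MUTATION_COLUMNS):
        logger.warning(
            "only %d of %d region columns present", len(mut_cols), len(MUTATION_COLUMNS)
        )
    block = table[mut_cols].astype(float)
    if umi_weighted:
        w = table["umi_count"].to_numpy(dtype=float)
        means = block.multiply(w, axis=0).sum() / w.sum()
    else:
        means = block.mean()
    out = {c.removeprefix("mu_count_"): float(means[c]) for c in mut_cols}
    out["overall"] = float(sum(out.values()))
    return pd.Series(out, name="shm_rate")


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    reference: str = "HC",
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of each group versus the reference, BH-adjusted.

    ``values`` is a per-subject statistic; ``groups`` maps the same
    subjects to group labels.  Ties use the midrank convention (scipy
    default).  Returns one row per non-reference group with U, p and FDR.
    """
    groups = groups.reindex(values.index)
    ref_vals = values[groups == reference].to_numpy()
    if ref_vals.size < 2:
        raise ValidationError(f"reference group {reference!r} needs >= 2 subjects")
    rows = []
    for g in sorted(set(groups.dropna()) - {reference}):
        gv = values[groups == g].to_numpy()
        if gv.size < 2:
            raise ValidationError(f"group {g!r} needs >= 2 subjects")
        u, p = stats.mannwhitneyu(gv, ref_vals, alternative="two-sided")
        rows.append({"group": g, "reference": reference, "U": float(u), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def repertoire_summary(
    tables: dict[str, pd.DataFrame],
    target_fraction: float = 0.2,
) -> pd.DataFrame:
    """One row per subject: Gini, R20, clone count, mean CDR3, SHM rates."""
    rows = []
    for s, raw in tables.items():
        t = collapse_clonotypes(raw)
        freqs = t["frequency"].to_numpy()
        _, mean_len = cdr3_length_stats(t)
        row = {
            "sample_id": s,
            "n_clonotypes": len(t),
            "gini": gini_index(freqs),
            "r20": r20(freqs, target_fraction),
            "mean_cdr3_len": mean_len,
        }
        try:
            shm = shm_rate(t)
            row.update({f"shm_{k}": v for k, v in shm.items()})
        except ValidationError:
            logger.warning("subject %s lacks mutation columns; SHM skipped", s)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
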