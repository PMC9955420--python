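"""Interferon gene-signature scoring and simplified differential expression.

The IFN gene signature (GS) score standardizes each panel gene against the
healthy-control mean/SD and averages over the panel; a subject is
classified IFN-hi when its score exceeds the HC score mean by more than
``hi_sd_mult`` HC-score SDs (default 2).  Differential expression between
two groups uses the per-gene standardized mean difference with a Welch t
test, flagged at the |Z| > 0.7 / p < 0.01 volcano cutoffs.  Gene-set
over-representation of a flagged list is a one-sided hypergeometric test
with Benjamini-Hochberg FDR across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError

__all__ = [
    "ifn_gs_score",
    "differential_expression",
    "gene_set_overrepresentation",
    "read_gmt",
]


def ifn_gs_score(
    expr: pd.DataFrame,
    panel,
    hc_ids,
    hi_sd_mult: float = 2.0,
    sd_floor: float = 1e-8,
) -> pd.DataFrame:
    """IFN GS score and IFN-hi/lo classification per subject.

    Parameters
    ----------
    expr : DataFrame
        Log-expression, genes x samples.
    panel : iterable of str
        Signature genes (>= 2), all present in ``expr``.
    hc_ids : iterable of str
        Healthy-control sample IDs (the standardization reference).
    hi_sd_mult : float
        Classification cutoff: IFN-hi iff score > mean(HC scores) +
        ``hi_sd_mult`` * SD(HC scores).

    Returns
    -------
    DataFrame indexed by sample with columns ``score`` and
    ``classification`` ("IFN-hi" / "IFN-lo").
    """
    panel = list(panel)
    if len(panel) < 2:
        raise ValidationError("signature panel needs >= 2 genes")
    missing = [g for g in panel if g not in expr.index]
    if missing:
        raise ValidationError(f"panel genes absent from matrix: {missing}")
    hc_ids = list(hc_ids)
    if not hc_ids:
        raise ValidationError("HC sample set is empty")
    absent = [s for s in hc_ids if s not in expr.columns]
    if absent:
        raise ValidationError(f"HC ids absent from matrix: {absent[:5]}")

    block = expr.loc[panel]
    hc = block[hc_ids]
    mu = hc.mean(axis=1)
    sd = hc.std(axis=1, ddof=1).clip(lower=sd_floor)
    zs = block.sub(mu, axis=0).div(sd, axis=0)
    score = zs.mean(axis=0)

    hc_scores = score[hc_ids]
    cut = hc_scores.mean() + hi_sd_mult * hc_scores.std(ddof=1)
    out = pd.DataFrame({"score": score})
    out["classification"] = np.where(out["score"] > cut, "IFN-hi", "IFN-lo")
    out.index.name = "sample_id"
    return out


def differential_expression(
    expr: pd.DataFrame,
    group_a,
    group_b,
    z_cut: float = 0.7,
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Per-gene standardized effect and Welch-t p of group A versus group B.

    effect = (mean_A - mean_B) / pooled SD (per gene); ``flag`` marks
    genes with |effect| > ``z_cut`` and p < ``p_cut``.
    """
    a = [s for s in group_a]
    b = [s for s in group_b]
    for ids, name in ((a, "group_a"), (b, "group_b")):
        if len(ids) < 2:
            raise ValidationError(f"{name} needs >= 2 subjects")
        missing = [s for s in ids if s not in expr.columns]
        if missing:
            raise ValidationError(f"{name} ids absent from matrix: {missing[:5]}")
    xa = expr[a].to_numpy(dtype=float)
    xb = expr[b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    pooled = np.where(pooled <= 0, np.nan, pooled)
    effect = (xa.mean(axis=1) - xb.mean(axis=1)) / pooled
    effect = np.where(np.isnan(effect), 0.0, effect)
    tstat, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame({"effect": effect, "p": p}, index=expr.index)
    out["flag"] = (np.abs(out["effect"]) > z_cut) & (out["p"] < p_cut)
    return out


def gene_set_overrepresentation(
    flagged,
    universe,
    sets: dict[str, set[str]],
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH-FDR across sets.

    Parameters
    ----------
    flagged : iterable of str
        Genes of interest (must be a subset of ``universe``).
    universe : iterable of str
        Background gene list.
    sets : dict
        Named gene sets; each is intersected with the universe before
        testing.
    directions : dict, optional
        Optional per-set direction annotation (e.g. "up"/"down") echoed in
        the output.

    Returns
    -------
    DataFrame ranked by p with columns term, n_genes, overlap, direction,
    p, fdr.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    flagged = set(flagged)
    stray = flagged - universe
    if stray:
        raise ValidationError(f"flagged genes outside universe: {sorted(stray)[:5]}")

    big_m = len(universe)
    n_draw = len(flagged)
    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        k = len(members & flagged)
        # upper-tail probability of seeing >= k set members among the draws
        p = stats.hypergeom.sf(k - 1, big_m, len(members), n_draw) if members else 1.0
        rows.append(
            {
                "term": name,
                "n_genes": len(members),
                "overlap": k,
                "direction": (directions or {}).get(name, ""),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT-style gene-set file (name, description, members per line)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")
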