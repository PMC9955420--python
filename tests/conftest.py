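"""Shared fixtures: the default synthetic cohort, run once per session.

The array arm (simulate -> background-subtract -> log2 -> cyclic loess ->
trimmed baseline -> Z-scores) is the expensive piece (~1 min); everything
that needs Z-scores shares the session-scoped result.
"""

from types import SimpleNamespace

import pytest

from autorep.baseline import compute_zscores, fit_baseline
from autorep.normalize import cyclic_loess_normalize, log_transform, subtract_background
from autorep.repertoire import repertoire_summary
from autorep.simulate import (
    CohortDesign,
    generate_array_cohort,
    generate_bcr_repertoires,
    generate_expression,
)

COHORT_SEED = 1


@pytest.fixture(scope="session")
def design() -> CohortDesign:
    return CohortDesign(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def array_arm(design):
    fg, bg, metadata, truth = generate_array_cohort(design)
    norm = cyclic_loess_normalize(log_transform(subtract_background(fg, bg)))
    hc_ids = metadata.index[metadata["group"] == "HC"].tolist()
    baseline = fit_baseline(norm, hc_ids)
    z = compute_zscores(norm, baseline)
    return SimpleNamespace(
        fg=fg,
        bg=bg,
        metadata=metadata,
        truth=truth,
        norm=norm,
        baseline=baseline,
        z=z,
        hc_ids=hc_ids,
    )


@pytest.fixture(scope="session")
def bcr_arm(design):
    tables, truth = generate_bcr_repertoires(design)
    summary = repertoire_summary(tables)
    summary["group"] = truth.group.reindex(summary.index)
    return SimpleNamespace(tables=tables, truth=truth, summary=summary)


@pytest.fixture(scope="session")
def expression_arm(design):
    expr, truth = generate_expression(design)
    return SimpleNamespace(expr=expr, truth=truth, panel=list(design.ifn_panel))
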