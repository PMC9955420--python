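"""Synthetic cohort generator with planted archetype structure.

Emulates the four study groups so every downstream stage can be tested
against known truth:

* **HC** — null reactivity, with a small number of planted outlier
  subjects carrying broad moderate shifts (these exercise the baseline
  trimming).
* **APECED** — few shared target antigens with very high Z shifts,
  biased toward extracellular localization; highly expanded B-cell
  clone distributions (low Dirichlet concentration).
* **SLE** — many weak-to-moderate reactivities biased to nuclear and
  cytosolic antigens, split into planted 'hot' (broad, strong, IFN-hi)
  and 'cold' (sparse, weak) subjects; broad but unexpanded repertoires.
* **SjS** — exactly two dominant target antigens (the Ro52/La pattern);
  otherwise quiet.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` children, so each data arm regenerates
independently and byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, ValidationError

__all__ = [
    "ArchetypeParams",
    "RepertoireParams",
    "CohortDesign",
    "TruthLabels",
    "generate_array_cohort",
    "generate_bcr_repertoires",
    "generate_expression",
]

GROUPS = ("HC", "APECED", "SjS", "SLE")
LOCALIZATION_CATEGORIES = ("extracellular", "nuclear", "cytosolic", "membrane", "other")
V_REGIONS = ("fr1", "cdr1", "fr2", "cdr2", "fr3")

# region shares of the total V-gene mutation load, roughly proportional to
# the amino-acid lengths of the IMGT regions
REGION_WEIGHTS = {"fr1": 0.25, "cdr1": 0.10, "fr2": 0.15, "cdr2": 0.12, "fr3": 0.38}

#: fixed VH gene pool (allele suffixes are attached at draw time)
VH_GENES = tuple(
    f"IGHV{fam}-{gene}"
    for fam, genes in {
        1: (2, 3, 8, 18, 24, 46, 58, 69),
        2: (5, 26, 70),
        3: (7, 9, 11, 13, 15, 21, 23, 30, 33, 43, 48, 53, 64, 66, 72, 74),
        4: (4, 28, 30, 31, 34, 39, 59, 61),
        5: (10, 51),
        6: (1,),
    }.items()
    for gene in genes
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: interferon-stimulated genes used as the default signature panel
DEFAULT_IFN_PANEL = (
    "IFI27",
    "IFI44L",
    "IFIT1",
    "ISG15",
    "MX1",
    "OAS1",
    "RSAD2",
    "SIGLEC1",
    "USP18",
)


@dataclass(frozen=True)
class ArchetypeParams:
    """Per-group array reactivity specification.

    n_targets
        Number of planted target antigens for the group.
    shift_mean, shift_sd
        Mean/SD of the planted Z shift, in baseline-SD units.
    prevalence
        Probability each subject of the group reacts to each target.
    """

    n_targets: int
    shift_mean: float
    shift_sd: float
    prevalence: float

    def __post_init__(self) -> None:
        if self.n_targets < 0:
            raise ValidationError("n_targets must be >= 0")
        if not (0 <= self.prevalence <= 1):
            raise ValidationError("prevalence must lie in [0, 1]")
        if self.shift_sd < 0:
            raise ValidationError("shift_sd must be >= 0")


@dataclass(frozen=True)
class RepertoireParams:
    """Per-group clone-frequency specification.

    n_clones
        Clones per subject.
    concentration
        Symmetric Dirichlet concentration of the clone-frequency vector;
        low values give expanded (clonally dominated) repertoires, high
        values give even ones.
    depth
        Total UMIs sampled per subject (multinomial).
    mutation_mean
        Mean total mutations per V gene (split over regions by
        ``REGION_WEIGHTS``).
    """

    n_clones: int
    concentration: float
    depth: int
    mutation_mean: float

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValidationError("n_clones must be >= 1")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        if self.depth < self.n_clones:
            raise ValidationError(
                f"UMI depth {self.depth} below clone count {self.n_clones}"
            )
        if self.mutation_mean < 0:
            raise ValidationError("mutation_mean must be >= 0")


def _default_archetypes() -> dict[str, ArchetypeParams]:
    return {
        "HC": ArchetypeParams(0, 0.0, 0.0, 0.0),
        "APECED": ArchetypeParams(40, 12.0, 2.0, 0.85),
        "SjS": ArchetypeParams(2, 10.0, 1.5, 1.0),
        # the SLE entry describes the 'hot' phenotype; cold subjects use the
        # attenuated sle_cold_* settings on the same target set
        "SLE": ArchetypeParams(150, 8.0, 2.0, 0.9),
    }


def _default_repertoires() -> dict[str, RepertoireParams]:
    return {
        "HC": RepertoireParams(500, 1.0, 20_000, 20.0),
        "APECED": RepertoireParams(500, 0.2, 20_000, 13.0),
        "SjS": RepertoireParams(500, 2.0, 20_000, 14.0),
        "SLE": RepertoireParams(500, 5.0, 20_000, 14.0),
    }


@dataclass(frozen=True)
class CohortDesign:
    """Full parameterization of the synthetic cohort.

    Defaults mirror the study group sizes (HC 18, APECED 20, SjS 26,
    SLE 43) with a 2,000-antigen array for desk-scale runtime.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 18, "APECED": 20, "SjS": 26, "SLE": 43}
    )
    n_features: int = 2000
    archetype_params: dict[str, ArchetypeParams] = field(default_factory=_default_archetypes)
    hc_outlier_rate: float = 0.1
    hc_outlier_shift: float = 9.0
    hc_outlier_feature_frac: float = 0.03
    sle_hot_fraction: float = 0.5
    sle_cold_shift_mean: float = 3.0
    sle_cold_prevalence: float = 0.3
    repertoire_params: dict[str, RepertoireParams] = field(default_factory=_default_repertoires)
    n_genes: int = 500
    ifn_panel: tuple[str, ...] = DEFAULT_IFN_PANEL
    ifn_shift: float = 5.0
    cold_ifn_hi_rate: float = 0.5
    sjs_ifn_hi_rate: float = 0.2
    sample_scale_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group label {g!r}")
            if n < 1:
                raise ValidationError(f"group size for {g} must be >= 1, got {n}")
        if self.n_features < 1 or self.n_genes < 1:
            raise ValidationError("feature/gene counts must be positive")
        for p in (
            self.hc_outlier_rate,
            self.hc_outlier_feature_frac,
            self.sle_hot_fraction,
            self.sle_cold_prevalence,
            self.cold_ifn_hi_rate,
            self.sjs_ifn_hi_rate,
        ):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must lie in [0, 1]")
        n_targets = sum(a.n_targets for a in self.archetype_params.values())
        if n_targets > self.n_features:
            raise ValidationError("planted targets exceed feature count")
        if len(self.ifn_panel) > self.n_genes:
            raise ValidationError("IFN panel larger than gene count")
        if len(self.ifn_panel) < 2:
            raise ValidationError("IFN panel needs >= 2 genes")

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for g in GROUPS:
            if g in self.group_sizes:
                out.extend(f"{g}_{i + 1:02d}" for i in range(self.group_sizes[g]))
        return out


@dataclass(frozen=True)
class TruthLabels:
    """Planted ground truth for one design+seed."""

    group: pd.Series  # sample_id -> group label
    hot: pd.Series  # sample_id -> bool (SLE 'hot'; False elsewhere)
    ifn_hi: pd.Series  # sample_id -> bool
    group_targets: dict[str, tuple[str, ...]]
    localization: dict[str, tuple[str, ...]]
    hc_outliers: dict[str, tuple[str, ...]]  # HC outlier subject -> shifted features
    concentration: pd.Series  # sample_id -> Dirichlet concentration

    def __post_init__(self) -> None:
        all_feats = set(self.localization)
        for g, targets in self.group_targets.items():
            missing = set(targets) - all_feats
            if missing:
                raise ValidationError(f"{g} targets missing from feature list: {missing}")


def _streams(design: CohortDesign) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(design.seed).spawn(4)
    names = ("truth", "array", "bcr", "expression")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _feature_ids(design: CohortDesign) -> list[str]:
    return [f"AG{i:04d}" for i in range(design.n_features)]


def _draw_localization(
    rng: np.random.Generator, is_target_of: str | None
) -> tuple[str, ...]:
    # category inclusion probabilities depend on which group (if any) the
    # antigen is a planted target of
    if is_target_of == "APECED":
        probs = {"extracellular": 0.8, "nuclear": 0.2, "cytosolic": 0.2, "membrane": 0.3}
    elif is_target_of in ("SLE", "SjS"):
        probs = {"extracellular": 0.15, "nuclear": 0.7, "cytosolic": 0.6, "membrane": 0.1}
    else:
        probs = {"extracellular": 0.2, "nuclear": 0.2, "cytosolic": 0.2, "membrane": 0.2}
    cats = tuple(c for c, p in probs.items() if rng.random() < p)
    return cats if cats else ("other",)


def plant_truth(design: CohortDesign) -> TruthLabels:
    """Draw all planted labels for the design (deterministic in the seed)."""
    rng = _streams(design)["truth"]
    features = _feature_ids(design)
    samples = design.sample_ids
    group = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in samples}, name="group"
    ).reindex(samples)

    # disjoint target sets per group, drawn from the feature pool
    pool = rng.permutation(design.n_features)
    cursor = 0
    group_targets: dict[str, tuple[str, ...]] = {}
    target_of: dict[str, str] = {}
    for g in GROUPS:
        arch = design.archetype_params.get(g)
        k = arch.n_targets if arch else 0
        idx = pool[cursor : cursor + k]
        cursor += k
        targets = tuple(features[i] for i in sorted(idx))
        group_targets[g] = targets
        for t in targets:
            target_of[t] = g

    localization = {
        f: _draw_localization(rng, target_of.get(f)) for f in features
    }

    # hot/cold split of the SLE group: first ceil(fraction * n) after a
    # seeded shuffle are hot
    sle = [s for s in samples if group[s] == "SLE"]
    n_hot = int(round(design.sle_hot_fraction * len(sle)))
    shuffled = list(rng.permutation(sle))
    hot_set = set(shuffled[:n_hot])
    hot = pd.Series({s: s in hot_set for s in samples}, name="hot").reindex(samples)

    # planted IFN-hi: every hot SLE subject, cold SLE at cold_ifn_hi_rate,
    # SjS at sjs_ifn_hi_rate, HC and APECED never
    ifn_hi = {}
    for s in samples:
        g = group[s]
        if g == "SLE":
            ifn_hi[s] = bool(hot[s]) or rng.random() < design.cold_ifn_hi_rate
        elif g == "SjS":
            ifn_hi[s] = rng.random() < design.sjs_ifn_hi_rate
        else:
            ifn_hi[s] = False
    ifn_hi = pd.Series(ifn_hi, name="ifn_hi").reindex(samples)

    # planted HC outlier subjects: a fixed count (round(rate * n)), each with
    # its own random feature subset
    hcs = [s for s in samples if group[s] == "HC"]
    n_out = int(round(design.hc_outlier_rate * len(hcs)))
    outlier_subjects = list(rng.permutation(hcs))[:n_out]
    n_shift = int(round(design.hc_outlier_feature_frac * design.n_features))
    hc_outliers = {
        s: tuple(
            features[i] for i in sorted(rng.choice(design.n_features, n_shift, replace=False))
        )
        for s in sorted(outlier_subjects)
    }

    concentration = pd.Series(
        {s: design.repertoire_params[group[s]].concentration for s in samples},
        name="concentration",
    ).reindex(samples)

    return TruthLabels(
        group=group,
        hot=hot,
        ifn_hi=ifn_hi,
        group_targets=group_targets,
        localization=localization,
        hc_outliers=hc_outliers,
        concentration=concentration,
    )


def generate_array_cohort(
    design: CohortDesign,
) -> tuple[IntensityMatrix, IntensityMatrix, pd.DataFrame, TruthLabels]:
    """Simulate the protein-array arm.

    Returns ``(foreground, background, sample_metadata, truth)``.  Signal
    is built on the log2 scale -- per-feature lognormal baseline, planted
    shifts in baseline-SD units, per-sample scale jitter -- then written
    to the raw scale with an additive background channel, so that the
    normalization stages (background subtraction, log2, cyclic loess) can
    recover it.
    """
    truth = plant_truth(design)
    rng = _streams(design)["array"]
    features = _feature_ids(design)
    samples = design.sample_ids
    n_f, n_s = design.n_features, len(samples)

    feat_mean = rng.normal(8.0, 1.0, n_f)
    feat_sd = rng.uniform(0.15, 0.35, n_f)
    sample_offset = rng.normal(0.0, design.sample_scale_sd, n_s)

    log_signal = (
        feat_mean[:, None]
        + feat_sd[:, None] * rng.standard_normal((n_f, n_s))
        + sample_offset[None, :]
    )

    feat_pos = {f: i for i, f in enumerate(features)}
    for c, s in enumerate(samples):
        g = truth.group[s]
        arch = design.archetype_params.get(g)
        if g == "SLE":
            if truth.hot[s]:
                prevalence, shift_mean, shift_sd = (
                    arch.prevalence,
                    arch.shift_mean,
                    arch.shift_sd,
                )
            else:
                prevalence, shift_mean, shift_sd = (
                    design.sle_cold_prevalence,
                    design.sle_cold_shift_mean,
                    1.0,
                )
            targets = truth.group_targets["SLE"]
        elif arch and arch.n_targets:
            prevalence, shift_mean, shift_sd = (
                arch.prevalence,
                arch.shift_mean,
                arch.shift_sd,
            )
            targets = truth.group_targets[g]
        else:
            targets = ()
            prevalence = 0.0
        for t in targets:
            if rng.random() < prevalence:
                i = feat_pos[t]
                log_signal[i, c] += max(0.0, rng.normal(shift_mean, shift_sd)) * feat_sd[i]
        if s in truth.hc_outliers:
            for t in truth.hc_outliers[s]:
                i = feat_pos[t]
                log_signal[i, c] += max(0.0, rng.normal(design.hc_outlier_shift, 1.0)) * feat_sd[i]

    background = 2.0 ** rng.normal(4.0, 0.3, (n_f, n_s))
    foreground = 2.0 ** log_signal + background

    fg = IntensityMatrix(
        pd.DataFrame(foreground, index=features, columns=samples),
        channel="foreground",
        scale="raw",
    )
    bg = IntensityMatrix(
        pd.DataFrame(background, index=features, columns=samples),
        channel="background",
        scale="raw",
    )
    metadata = pd.DataFrame(
        {"sample_id": samples, "group": [truth.group[s] for s in samples]}
    ).set_index("sample_id")
    return fg, bg, metadata, truth


def _random_junction(rng: np.random.Generator) -> str:
    # junction = conserved C ... W anchors around a CDR3 of Gaussian length
    length = int(np.clip(np.rint(rng.normal(17.0, 2.0)), 8, 30))
    middle = "".join(rng.choice(list(AA_ALPHABET), length - 2))
    return f"C{middle}W"


def generate_bcr_repertoires(
    design: CohortDesign,
) -> tuple[dict[str, pd.DataFrame], TruthLabels]:
    """Simulate the BCR repertoire arm as AIRR rearrangement tables.

    Per subject: clone frequencies from a symmetric Dirichlet with the
    group's concentration, UMI counts multinomial at the group depth,
    VH genes from a fixed long-tailed multinomial over the
    :data:`VH_GENES` pool (with random allele suffixes), junction amino
    acids with Gaussian CDR3 lengths, and per-region Poisson mutation
    counts.  Expanded clones may be emitted as several records sharing
    the (V gene, junction) key, to exercise clonotype collapsing.
    """
    truth = plant_truth(design)
    rng = _streams(design)["bcr"]

    # fixed long-tailed usage over the VH pool, shared by all subjects
    usage = 1.0 / (np.arange(len(VH_GENES)) + 2.0)
    usage /= usage.sum()

    tables: dict[str, pd.DataFrame] = {}
    for s in design.sample_ids:
        params = design.repertoire_params[truth.group[s]]
        n = params.n_clones
        freqs = (
            rng.dirichlet(np.full(n, params.concentration))
            if n > 1
            else np.ones(1)
        )
        counts = rng.multinomial(params.depth, freqs)
        v_idx = rng.choice(len(VH_GENES), n, p=usage)
        region_means = {
            r: params.mutation_mean * w for r, w in REGION_WEIGHTS.items()
        }
        rows = []
        seq = 0
        for k in range(n):
            if counts[k] == 0:
                continue
            v_call = f"{VH_GENES[v_idx[k]]}*{rng.integers(1, 4):02d}"
            junction = _random_junction(rng)
            # occasionally split a clone across records (same V+junction)
            n_records = int(rng.integers(1, 3)) if counts[k] >= 2 else 1
            split = (
                rng.multinomial(counts[k] - n_records, np.full(n_records, 1 / n_records))
                + 1
                if n_records > 1
                else np.array([counts[k]])
            )
            for c in split:
                rows.append(
                    {
                        "sequence_id": f"{s}_seq{seq:05d}",
                        "v_call": v_call,
                        "junction_aa": junction,
                        "duplicate_count": int(c),
                        **{
                            f"mu_count_{r}": int(rng.poisson(region_means[r]))
                            for r in V_REGIONS
                        },
                    }
                )
                seq += 1
        tables[s] = pd.DataFrame(rows)
    return tables, truth


def generate_expression(design: CohortDesign) -> tuple[pd.DataFrame, TruthLabels]:
    """Simulate the log-expression arm (genes x samples).

    Gaussian log-expression with unit per-gene SD; the IFN panel genes are
    shifted upward by ``ifn_shift`` SD in planted IFN-hi subjects.
    """
    truth = plant_truth(design)
    rng = _streams(design)["expression"]
    samples = design.sample_ids

    other = [f"G{i:04d}" for i in range(design.n_genes - len(design.ifn_panel))]
    genes = list(design.ifn_panel) + other
    gene_mean = rng.normal(5.0, 1.5, len(genes))
    expr = gene_mean[:, None] + rng.standard_normal((len(genes), len(samples)))
    panel_rows = np.arange(len(design.ifn_panel))
    for c, s in enumerate(samples):
        if truth.ifn_hi[s]:
            expr[panel_rows, c] += design.ifn_shift
    return pd.DataFrame(expr, index=genes, columns=samples), truth
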