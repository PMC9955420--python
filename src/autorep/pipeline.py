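"""End-to-end pipeline: simulate -> normalize -> Z-score -> reactivity
(-> localization) -> expression -> repertoire -> manifest.

Driven by a nested configuration mapping (typically loaded from YAML);
every stage logs its parameters and row counts, writes deterministic TSV
outputs into the run directory, and the whole run is summarized in a JSON
manifest whose file digests are byte-identical across reruns with the same
configuration and seed.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .baseline import compute_zscores, fit_baseline
from .containers import AnalysisConfig, ValidationError
from .expression import differential_expression, ifn_gs_score
from .io import (
    file_digest,
    read_airr,
    read_matrix,
    read_metadata,
    write_airr,
    write_json,
    write_matrix,
    write_metadata,
)
from .localization import LocalizationAnnotation, localization_breakdown
from .normalize import cyclic_loess_normalize, log_transform, subtract_background
from .containers import IntensityMatrix
from .reactivity import (
    count_reactivities,
    hot_cold_split,
    overlap_summary,
    pca_embedding,
    ranked_reactivity_curve,
    subject_median_z,
    top_variance_heatmap_input,
    volcano_vs_hc,
)
from .repertoire import cohort_vh_usage, group_compare, repertoire_summary
from .simulate import (
    ArchetypeParams,
    CohortDesign,
    RepertoireParams,
    generate_array_cohort,
    generate_bcr_repertoires,
    generate_expression,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"enabled": True},
    "normalize": {"span": 0.4, "iterations": 2, "floor": 1.0},
    "zscore": {"k_max": 3, "alpha": 0.01, "sd_floor": 0.1},
    "reactivity": {
        "z_reactive": 5.0,
        "prevalence_min": 0.30,
        "n_top_variance": 100,
        "n_top_rank": 4000,
        "volcano_z_min": 1.0,
        "volcano_p_max": 0.05,
    },
    "expression": {"enabled": True, "hi_sd_mult": 2.0, "de_z_cut": 0.7, "de_p_cut": 0.01},
    "bcr": {"enabled": True, "target_fraction": 0.2, "n_top_rank": 4000, "n_top_vh": 30},
}


def _merged(config: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def design_from_config(config: dict) -> CohortDesign:
    sim = config.get("simulate", {})
    kwargs: dict = {"seed": int(config.get("seed", 0))}
    for key in (
        "group_sizes",
        "n_features",
        "hc_outlier_rate",
        "hc_outlier_shift",
        "hc_outlier_feature_frac",
        "sle_hot_fraction",
        "sle_cold_shift_mean",
        "sle_cold_prevalence",
        "n_genes",
        "ifn_shift",
        "cold_ifn_hi_rate",
        "sjs_ifn_hi_rate",
        "sample_scale_sd",
    ):
        if key in sim:
            kwargs[key] = sim[key]
    if "archetype_params" in sim:
        kwargs["archetype_params"] = {
            g: ArchetypeParams(**p) for g, p in sim["archetype_params"].items()
        }
    if "repertoire_params" in sim:
        kwargs["repertoire_params"] = {
            g: RepertoireParams(**p) for g, p in sim["repertoire_params"].items()
        }
    if "ifn_panel" in sim:
        kwargs["ifn_panel"] = tuple(sim["ifn_panel"])
    return CohortDesign(**kwargs)


class PipelineRun:
    """Executes the configured stages and accumulates the run manifest."""

    def __init__(self, config: dict | None, outdir) -> None:
        self.config = _merged(config)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": int(self.config.get("seed", 0)),
            "config": self.config,
            "stages": {},
        }

    def _record(self, stage: str, name: str, path: Path, n_rows: int) -> None:
        self.manifest["stages"].setdefault(stage, {})[name] = {
            "file": path.name,
            "n_rows": int(n_rows),
            "sha256": file_digest(path),
        }

    def _write(self, stage: str, name: str, df: pd.DataFrame, index_label: str) -> None:
        path = self.outdir / f"{name}.tsv"
        write_matrix(df, path, index_label=index_label)
        self._record(stage, name, path, len(df))

    def run(self) -> dict:
        cfg = self.config
        try:
            fg, bg, metadata, truth, expr, airr_tables, ann = self._stage_inputs()
            z, baseline = self._stage_array(fg, bg, metadata)
            self._stage_reactivity(z, metadata, ann)
            if cfg["expression"].get("enabled", True) and expr is not None:
                self._stage_expression(expr, metadata)
            if cfg["bcr"].get("enabled", True) and airr_tables is not None:
                self._stage_bcr(airr_tables, metadata)
        except Exception as exc:
            stage = self.manifest.get("_current_stage", "setup")
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        manifest_path = self.outdir / "manifest.json"
        self.manifest.pop("_current_stage", None)
        write_json(self.manifest, manifest_path)
        return self.manifest

    # stages -----------------------------------------------------------

    def _stage_inputs(self):
        self.manifest["_current_stage"] = "inputs"
        cfg = self.config
        sim = cfg.get("simulate", {})
        if sim.get("enabled", True):
            design = design_from_config(cfg)
            logger.info("simulating cohort: %s", design.group_sizes)
            fg, bg, metadata, truth = generate_array_cohort(design)
            expr, _ = generate_expression(design)
            airr_tables, _ = generate_bcr_repertoires(design)
            ann = LocalizationAnnotation(dict(truth.localization))

            stage = "simulate"
            for name, m in (("intensity_fg", fg.values), ("intensity_bg", bg.values)):
                self._write(stage, name, m, "feature_id")
            meta_path = self.outdir / "metadata.tsv"
            write_metadata(metadata, meta_path)
            self._record(stage, "metadata", meta_path, len(metadata))
            self._write(stage, "expression", expr, "gene_id")
            ann_path = self.outdir / "localization.tsv"
            ann.to_frame().to_csv(ann_path, sep="\t", index=False)
            self._record(stage, "localization", ann_path, len(ann))
            airr_dir = self.outdir / "airr"
            airr_dir.mkdir(exist_ok=True)
            for s, t in airr_tables.items():
                p = airr_dir / f"{s}.tsv"
                write_airr(t, p)
                self._record(stage, f"airr_{s}", p, len(t))
            truth_obj = {
                "group": truth.group.to_dict(),
                "hot": {k: bool(v) for k, v in truth.hot.items()},
                "ifn_hi": {k: bool(v) for k, v in truth.ifn_hi.items()},
                "group_targets": {g: list(t) for g, t in truth.group_targets.items()},
                "hc_outliers": {s: list(f) for s, f in truth.hc_outliers.items()},
            }
            truth_path = self.outdir / "truth.json"
            write_json(truth_obj, truth_path)
            self._record("simulate", "truth", truth_path, len(truth.group))
            self._truth = truth
            self._ifn_panel = list(design.ifn_panel)
            return fg, bg, metadata, truth, expr, airr_tables, ann

        inputs = cfg.get("inputs", {})
        for key in ("fg", "bg", "metadata"):
            if key not in inputs:
                raise ValidationError(f"inputs.{key} required when simulation is disabled")
            if not Path(inputs[key]).exists():
                raise ValidationError(f"input file not found: {inputs[key]}")
        fg = IntensityMatrix(read_matrix(inputs["fg"]), scale="raw")
        bg = IntensityMatrix(read_matrix(inputs["bg"]), channel="background", scale="raw")
        metadata = read_metadata(inputs["metadata"])
        expr = read_matrix(inputs["expression"]) if "expression" in inputs else None
        airr_tables = None
        if "airr_dir" in inputs:
            airr_tables = {
                p.stem: read_airr(p) for p in sorted(Path(inputs["airr_dir"]).glob("*.tsv"))
            }
        ann = None
        if "localization" in inputs:
            ann = LocalizationAnnotation.from_frame(
                pd.read_csv(inputs["localization"], sep="\t", dtype=str)
            )
        self._truth = None
        self._ifn_panel = list(inputs.get("ifn_panel", []))
        return fg, bg, metadata, None, expr, airr_tables, ann

    def _stage_array(self, fg, bg, metadata):
        self.manifest["_current_stage"] = "normalize"
        ncfg = self.config["normalize"]
        corrected = subtract_background(fg, bg, floor=float(ncfg.get("floor", 1.0)))
        logm = log_transform(corrected)
        norm = cyclic_loess_normalize(
            logm, span=float(ncfg.get("span", 0.4)), iterations=int(ncfg.get("iterations", 2))
        )
        self._write("normalize", "normalized", norm.values, "feature_id")

        self.manifest["_current_stage"] = "zscore"
        zcfg = self.config["zscore"]
        hc_ids = metadata.index[metadata["group"] == "HC"].tolist()
        baseline = fit_baseline(
            norm,
            hc_ids,
            k_max=int(zcfg.get("k_max", 3)),
            alpha=float(zcfg.get("alpha", 0.01)),
            sd_floor=float(zcfg.get("sd_floor", 0.1)),
        )
        z = compute_zscores(norm, baseline)
        self._write("zscore", "zmatrix", z, "feature_id")
        self._write("zscore", "baseline", baseline.to_frame(), "feature_id")
        return z, baseline

    def _stage_reactivity(self, z, metadata, ann):
        self.manifest["_current_stage"] = "reactivity"
        rcfg = self.config["reactivity"]
        acfg = AnalysisConfig(
            z_reactive=float(rcfg.get("z_reactive", 5.0)),
            prevalence_min=float(rcfg.get("prevalence_min", 0.30)),
            n_top_variance=int(rcfg.get("n_top_variance", 100)),
            n_top_rank=int(rcfg.get("n_top_rank", 4000)),
            volcano_z_min=float(rcfg.get("volcano_z_min", 1.0)),
            volcano_p_max=float(rcfg.get("volcano_p_max", 0.05)),
        )
        groups = metadata["group"]
        hc_ids = groups.index[groups == "HC"].tolist()

        self._write("reactivity", "counts", count_reactivities(z, acfg.threshold_grid),
                    "sample_id")
        medians = pd.DataFrame(
            {
                "median_z": subject_median_z(z),
                "median_z_reactive": subject_median_z(z, restrict_above=acfg.z_reactive),
            }
        )
        self._write("reactivity", "medians", medians, "sample_id")

        curves = {}
        for g in sorted(groups.unique()):
            ids = groups.index[groups == g].tolist()
            curve = ranked_reactivity_curve(z, ids, n_top=acfg.n_top_rank)
            curves[g] = pd.Series(curve)
        self._write("reactivity", "rank_curves", pd.DataFrame(curves), "rank")

        self._write("reactivity", "overlap", overlap_summary(z, metadata, acfg), "sample_id")

        for g in sorted(set(groups.unique()) - {"HC"}):
            ids = groups.index[groups == g].tolist()
            if len(ids) >= 2 and len(hc_ids) >= 2:
                self._write("reactivity", f"volcano_{g}", volcano_vs_hc(z, ids, hc_ids, acfg),
                            "feature_id")

        n_var = min(acfg.n_top_variance, z.shape[0])
        block, feat_order, sample_order = top_variance_heatmap_input(z, n_var)
        self._write("reactivity", "heatmap_input", block.loc[feat_order, sample_order],
                    "feature_id")

        sle_ids = groups.index[groups == "SLE"].tolist()
        if len(sle_ids) >= 4:
            labels = hot_cold_split(z, sle_ids, acfg)
            self._write("reactivity", "hotcold", labels.to_frame(), "sample_id")

        coords, evr = pca_embedding(z)
        coords["group"] = groups.reindex(coords.index)
        self._write("reactivity", "pca", coords, "sample_id")
        self.manifest["stages"]["reactivity"]["pca_explained_variance"] = [
            round(float(v), 6) for v in evr
        ]

        if ann is not None:
            self.manifest["_current_stage"] = "localization"
            rows = {}
            from .reactivity import group_overlap_set

            for g in sorted(set(groups.unique()) - {"HC"}):
                ids = groups.index[groups == g].tolist()
                oset = group_overlap_set(z, ids, acfg)
                if oset:
                    rows[g] = localization_breakdown(oset, ann)
                else:
                    logger.warning("group %s has an empty overlap set; no breakdown", g)
            if rows:
                self._write("localization", "localization_breakdown", pd.DataFrame(rows),
                            "category")

    def _stage_expression(self, expr, metadata):
        self.manifest["_current_stage"] = "expression"
        ecfg = self.config["expression"]
        groups = metadata["group"]
        hc_ids = [s for s in groups.index[groups == "HC"] if s in expr.columns]
        panel = self._ifn_panel or [g for g in expr.index[:9]]
        scores = ifn_gs_score(expr, panel, hc_ids,
                              hi_sd_mult=float(ecfg.get("hi_sd_mult", 2.0)))
        scores["group"] = groups.reindex(scores.index)
        self._write("expression", "ifn_scores", scores, "sample_id")

        sle = [s for s in groups.index[groups == "SLE"] if s in expr.columns]
        if len(sle) >= 2 and len(hc_ids) >= 2:
            de = differential_expression(
                expr, sle, hc_ids,
                z_cut=float(ecfg.get("de_z_cut", 0.7)),
                p_cut=float(ecfg.get("de_p_cut", 0.01)),
            )
            self._write("expression", "de_SLE_vs_HC", de, "gene_id")

    def _stage_bcr(self, airr_tables, metadata):
        self.manifest["_current_stage"] = "bcr"
        bcfg = self.config["bcr"]
        groups = metadata["group"]
        summary = repertoire_summary(
            airr_tables, target_fraction=float(bcfg.get("target_fraction", 0.2))
        )
        summary["group"] = groups.reindex(summary.index)
        self._write("bcr", "repertoire_summary", summary, "sample_id")

        from .repertoire import collapse_clonotypes, rank_fraction_curve

        n_top = int(bcfg.get("n_top_rank", 4000))
        curves = {
            s: pd.Series(rank_fraction_curve(collapse_clonotypes(t), n_top))
            for s, t in airr_tables.items()
        }
        self._write("bcr", "clone_rank_curves", pd.DataFrame(curves), "rank")

        usage = cohort_vh_usage(
            {s: collapse_clonotypes(t) for s, t in airr_tables.items()},
            groups,
            n_top=int(bcfg.get("n_top_vh", 30)),
        )
        self._write("bcr", "vh_usage", usage, "v_gene")

        tests = {}
        for metric in ("gini", "r20", "mean_cdr3_len", "shm_overall"):
            if metric in summary.columns:
                tests[metric] = group_compare(summary[metric], groups).set_index("group")
        if tests:
            combined = pd.concat(tests, names=["metric", "group"])
            self._write("bcr", "group_tests", combined.reset_index().set_index("metric"),
                        "metric")


def run_pipeline(config: dict | None, outdir) -> dict:
    """Run the configured pipeline into ``outdir`` and return the manifest."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return PipelineRun(config, outdir).run()
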