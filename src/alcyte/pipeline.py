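"""End-to-end pipeline: AL scoring → QC → deconvolution → association → direction → enrichment.

Stages run in order on in-memory tables; :func:`run_pipeline` wires them to
files named in a :class:`~alcyte.config.PipelineConfig` and writes one TSV per
stage output into a run directory, logging input/output dimensions and stage
timings. Any stage error aborts the run with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import al_score, assoc, deconvolution, direction, enrichment, io, preprocess
from .config import PipelineConfig
from .simulate import Cohort

logger = logging.getLogger("alcyte")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def load_cohort(config: PipelineConfig) -> Cohort:
    """Read the input bundle named in the config into a Cohort."""
    beta = io.read_matrix(config.beta_matrix)
    expression = io.read_matrix(config.expression_matrix)
    panel = io.read_table(config.biomarker_panel)
    thresholds = pd.read_csv(config.threshold_table, sep="\t")
    annotation = io.read_table(config.probe_annotation)
    annotation["blacklist"] = annotation["blacklist"].astype(str).str.lower().isin(
        ["true", "1", "yes"]
    )
    gene_map = io.read_table(config.gene_id_map).iloc[:, 0]
    signature = io.read_matrix(config.signature_matrix)
    return Cohort(
        beta=beta, expression=expression, panel=panel, thresholds=thresholds,
        annotation=annotation, gene_map=gene_map, signature=signature, truth=None,
    )


@_stage("al_score")
def _score_stage(cohort: Cohort, config: PipelineConfig):
    biomarkers = list(cohort.thresholds["biomarker"].unique())
    if config.al_method == "index":
        scores = al_score.compute_index_score(
            cohort.panel, cohort.thresholds, biomarkers,
            at_cutoff=config.dichotomize_at_cutoff,
        )
    else:
        scores = al_score.compute_zscore_al(cohort.panel, biomarkers)
    return al_score.assign_groups(scores, config.al_method, config.al_index_cutoff)


@_stage("qc")
def _qc_stage(cohort: Cohort, config: PipelineConfig):
    sex_info = preprocess.infer_sex(
        cohort.beta, cohort.annotation, config.female_x_window
    )
    reported = cohort.panel["sex"]
    keep = preprocess.drop_sex_mismatches(sex_info["predicted_sex"], reported)
    beta = preprocess.filter_probes(cohort.beta[keep], cohort.annotation)
    beta = preprocess.quantile_normalize_stratified(beta, cohort.annotation)
    expr = cohort.expression[keep]
    expr = preprocess.map_and_filter_genes(
        expr, cohort.gene_map, config.duplicate_gene_policy
    )
    return beta, expr, keep, sex_info


def run_pipeline_from_cohort(
    cohort: Cohort, config: PipelineConfig, out_dir: str | Path | None = None,
    gmt_collections: dict | None = None,
) -> dict:
    """Run every stage on an in-memory cohort; optionally write result tables.

    Returns a dict with all intermediate and final tables (scores, qc'd
    matrices, proportions, tensors, pairs per mode, combined pairs, direction
    calls, summary, enrichment).
    """
    results: dict = {}

    al = _score_stage(cohort, config)
    results["al"] = al
    groups = al.groups

    beta, expr, keep, sex_info = _qc_stage(cohort, config)
    groups = groups.loc[groups.index.intersection(keep)]
    results["beta_qc"], results["expr_qc"] = beta, expr
    results["sex_info"] = sex_info

    t0 = time.perf_counter()
    try:
        proportions = deconvolution.estimate_proportions(expr, cohort.signature)
        expr_tensor = deconvolution.purify_expression(expr, proportions)
        rf = deconvolution.refactor_components(
            beta, k=min(config.refactor_k, beta.shape[1] - 1),
            t=min(config.refactor_t, beta.shape[0]),
        )
        c1 = pd.DataFrame(index=beta.columns)
        panel = cohort.panel.loc[beta.columns]
        if "sex" in panel:
            c1["sex"] = (panel["sex"] == "male").astype(float)
        if "age" in panel:
            age = panel["age"].astype(float)
            c1["age"] = (age - age.mean()) / (age.std(ddof=0) or 1.0)
        if "smoking" in panel:
            c1["smoking"] = (panel["smoking"] == "yes").astype(float)
        c2 = panel[["center"]] if "center" in panel else None
        tca = deconvolution.fit_tca(beta, proportions.loc[beta.columns], c1=c1, c2=c2)
        meth_tensor = tca.tensor(beta)
    except Exception as exc:  # noqa: BLE001
        raise StageError("deconvolve", exc) from exc
    logger.info("stage deconvolve finished in %.2f s", time.perf_counter() - t0)
    results.update(
        proportions=proportions, refactor=rf, tca=tca,
        meth_tensor=meth_tensor, expr_tensor=expr_tensor,
    )

    t0 = time.perf_counter()
    try:
        per_ct = {}
        all_pairs = []
        min_subset = max(config.min_subset,
                         int(np.ceil(config.min_subset_frac * (groups == "high").sum())))
        for ct in meth_tensor.cell_types():
            states = assoc.compute_states(
                meth_tensor.values[ct], groups,
                config.dm_threshold, config.state_p_threshold,
            )
            mode_tables = {}
            for mode in assoc.MODES:
                mode_tables[mode] = assoc.run_mode(
                    meth_tensor.values[ct], expr_tensor.values[ct], groups,
                    cohort.annotation, mode, cell_type=ct, alpha=config.alpha,
                    dm_threshold=config.dm_threshold,
                    p_threshold=config.state_p_threshold,
                    min_subset=min_subset, states=states,
                )
            combined, summary = assoc.combine_modes(
                mode_tables["negative"], mode_tables["positive"]
            )
            per_ct[ct] = {"modes": mode_tables, "combined": combined, "summary": summary}
            if len(combined):
                all_pairs.append(combined)
        pairs = pd.concat(all_pairs, ignore_index=True) if all_pairs else pd.DataFrame(
            columns=assoc.PAIR_COLUMNS
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("associate", exc) from exc
    logger.info("stage associate finished in %.2f s", time.perf_counter() - t0)
    results["pairs_per_celltype"] = per_ct
    results["pairs"] = pairs

    t0 = time.perf_counter()
    try:
        calls = direction.call_directions(pairs)
        summary = direction.summarize(pairs, calls)
    except Exception as exc:  # noqa: BLE001
        raise StageError("direction", exc) from exc
    logger.info("stage direction finished in %.2f s", time.perf_counter() - t0)
    results["direction_calls"] = calls
    results["summary"] = summary

    if gmt_collections is None and config.gmt:
        gmt_collections = {"sets": io.read_gmt(config.gmt)}
    if gmt_collections:
        t0 = time.perf_counter()
        try:
            universe = list(expr.index)
            enr = enrichment.stratified_enrichment(
                calls, gmt_collections, universe,
                alpha=config.enrichment_alpha,
                min_set_size=config.min_set_size, max_set_size=config.max_set_size,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", exc) from exc
        logger.info("stage enrich finished in %.2f s", time.perf_counter() - t0)
        results["enrichment"] = enr

    if out_dir is not None:
        _write_results(results, Path(out_dir))
    return results


def _write_results(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    al = results["al"]
    al_table = pd.DataFrame({"score": al.scores})
    al_table["group"] = al.groups.reindex(al.scores.index)
    al_table["method"] = al.method
    al_table["cutoff_used"] = al.cutoff_used
    al_table.index.name = "sample"
    al_table.to_csv(out_dir / "al_scores.tsv", sep="\t", na_rep="NA")

    io.write_matrix(results["beta_qc"], out_dir / "beta_qc.tsv")
    io.write_matrix(results["expr_qc"], out_dir / "expression_qc.tsv")
    results["proportions"].rename_axis("sample").to_csv(
        out_dir / "proportions.tsv", sep="\t"
    )
    results["refactor"].rename_axis("sample").to_csv(
        out_dir / "refactor_components.tsv", sep="\t"
    )
    for modality, tensor in (("meth", results["meth_tensor"]),
                             ("expr", results["expr_tensor"])):
        for ct, frame in tensor.values.items():
            io.write_matrix(frame, out_dir / f"tensor_{modality}_{ct}.tsv")
    for ct, d in results["pairs_per_celltype"].items():
        for mode, table in d["modes"].items():
            table.to_csv(out_dir / f"pairs_{ct}_{mode}.tsv", sep="\t", index=False)
    results["pairs"].to_csv(out_dir / "pairs_combined.tsv", sep="\t", index=False)
    results["direction_calls"].to_csv(out_dir / "direction_calls.tsv", sep="\t", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(results["summary"], fh, indent=2, default=str)
    with open(out_dir / "report.txt", "w") as fh:
        fh.write(direction.render_report(results["summary"]))
    if "enrichment" in results:
        results["enrichment"].to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """File-based end-to-end run; returns the run directory."""
    cohort = load_cohort(config)
    out_dir = Path(config.out_dir)
    run_pipeline_from_cohort(cohort, config, out_dir=out_dir)
    return out_dir


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a synthetic cohort as a directory of pipeline-ready TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_matrix(cohort.beta, out / "beta.tsv")
    io.write_matrix(cohort.expression, out / "expression.tsv")
    cohort.panel.rename_axis("sample").to_csv(out / "panel.tsv", sep="\t", na_rep="NA")
    cohort.thresholds.to_csv(out / "thresholds.tsv", sep="\t", index=False)
    cohort.annotation.rename_axis("cpg").to_csv(out / "annotation.tsv", sep="\t")
    cohort.gene_map.rename("symbol").rename_axis("source_id").to_csv(
        out / "gene_map.tsv", sep="\t", na_rep="NA"
    )
    io.write_matrix(cohort.signature, out / "signature.tsv")
    if cohort.truth is not None:
        cohort.truth.proportions.rename_axis("sample").to_csv(
            out / "truth_proportions.tsv", sep="\t"
        )
        cohort.truth.planted.to_csv(out / "truth_planted.tsv", sep="\t", index=False)
        pd.DataFrame({
            "sex": cohort.truth.sexes,
            "al_score": cohort.truth.al_scores,
            "al_group": cohort.truth.al_groups,
        }).rename_axis("sample").to_csv(out / "truth_samples.tsv", sep="\t")
    return out


def config_for_cohort_dir(cohort_dir: str | Path, out_dir: str | Path,
                          **overrides) -> PipelineConfig:
    d = Path(cohort_dir)
    return PipelineConfig(
        biomarker_panel=str(d / "panel.tsv"),
        threshold_table=str(d / "thresholds.tsv"),
        beta_matrix=str(d / "beta.tsv"),
        probe_annotation=str(d / "annotation.tsv"),
        expression_matrix=str(d / "expression.tsv"),
        gene_id_map=str(d / "gene_map.tsv"),
        signature_matrix=str(d / "signature.tsv"),
        out_dir=str(out_dir),
        **overrides,
    )
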