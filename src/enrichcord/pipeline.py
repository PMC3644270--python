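"""Orchestration: simulate/load -> common genes -> statistics -> DEG lists ->
both enrichment engines -> DEG-count table and concordance outputs.

:func:`analyze_study` is the in-memory core used by tests and the
reproduction script; :func:`run_study` wraps it with configuration, output
files and a run manifest.  All randomness flows from one global seed,
expanded into fixed per-stage substreams, so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import concordance as cc
from .degs import (DEGCriterion, DEGList, GeneStatistics,
                   compute_gene_statistics, deg_count_table, select_degs)
from .exceptions import AnalysisError, ParameterError
from .gsea import run_gsea
from .io_formats import (ExpressionStudy, GeneSetCollection,
                         read_expression_matrix, read_gmt,
                         write_expression_study, write_gmt,
                         write_results_table)
from .lrpath import run_lrpath
from .synthetic import StudyDesign, common_genes, generate_study

logger = logging.getLogger(__name__)

#: per-criterion significance source fed to the regression engine
P_SOURCE_BY_METHOD = {"FC": "fc_rank", "SAM": "sam_p", "TTEST": "t_p"}

DEFAULT_CRITERIA = [DEGCriterion(m, c)
                    for m in ("FC", "SAM", "TTEST") for c in (0.01, 0.05)]


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0]) & 0x7FFFFFFF


@dataclass
class AnalysisResult:
    """Everything :func:`analyze_study` computes, keyed for the concordance plan."""

    common: list[str]
    stats: dict[tuple, GeneStatistics]          # (platform, site)
    deg_lists: dict[tuple, DEGList]             # (platform, site, method, cutoff)
    gsea_results: dict[tuple, list]             # (platform, site, method, cutoff)
    lrpath_results: dict[tuple, list]
    catalog: dict[tuple, object]                # (platform, site, method, cutoff, engine)
    failures: list[dict] = field(default_factory=list)

    @property
    def platforms(self) -> list[str]:
        return list(dict.fromkeys(p for p, _s in self.stats))

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(s for _p, s in self.stats))


def analyze_study(studies: Sequence[ExpressionStudy],
                  gene_sets: GeneSetCollection,
                  criteria: Sequence[DEGCriterion] = tuple(DEFAULT_CRITERIA),
                  *, seed: int = 0, fdr_cutoff: float = 0.25,
                  gsea_params: Mapping | None = None,
                  lrpath_params: Mapping | None = None,
                  engines: Sequence[str] = ("gsea", "lrpath")) -> AnalysisResult:
    """Run the full analysis in memory over per-platform studies.

    Statistics are always computed on the cross-platform common-gene
    intersection first, even for a single platform, so every downstream
    list lives on the same universe.
    """
    if not criteria:
        raise ParameterError("criteria grid must be non-empty")
    gsea_params = dict(gsea_params or {})
    lrpath_params = dict(lrpath_params or {})
    common = common_genes(studies)
    logger.info("analysis restricted to %d common genes", len(common))

    result = AnalysisResult(common, {}, {}, {}, {}, {})
    for qi, study in enumerate(studies):
        platform = study.platforms[0]
        for si, site in enumerate(study.sites):
            stats = compute_gene_statistics(
                study, site=site, genes=common,
                seed=_sub_seed(seed, 1, qi, si))
            result.stats[(platform, site)] = stats
            lr_cache: dict[str, list] = {}
            for ci, crit in enumerate(criteria):
                key = (platform, site, crit.method, crit.p_cutoff)
                deg = select_degs(stats, crit)
                result.deg_lists[key] = deg
                if "gsea" in engines:
                    try:
                        if not deg.genes:
                            raise AnalysisError("empty DEG list")
                        res = run_gsea(deg, stats, gene_sets,
                                       fdr_cutoff=fdr_cutoff,
                                       seed=_sub_seed(seed, 2, qi, si, ci),
                                       **gsea_params)
                        result.gsea_results[key] = res
                        result.catalog[key + ("gsea",)] = \
                            cc.rank_significant_terms(res, fdr_cutoff)
                    except AnalysisError as exc:
                        result.failures.append(
                            {"stage": "gsea", "key": key, "error": str(exc)})
                if "lrpath" in engines:
                    source = P_SOURCE_BY_METHOD[crit.method]
                    try:
                        if source not in lr_cache:
                            lr_cache[source] = run_lrpath(
                                stats, source, gene_sets,
                                fdr_cutoff=fdr_cutoff, **lrpath_params)
                        res = lr_cache[source]
                        result.lrpath_results[key] = res
                        result.catalog[key + ("lrpath",)] = \
                            cc.rank_significant_terms(res, fdr_cutoff)
                    except AnalysisError as exc:
                        result.failures.append(
                            {"stage": "lrpath", "key": key, "error": str(exc)})
    return result


# ---------------------------------------------------------------------------
# configuration + disk-writing front end
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One study: data source, criteria grid, engine params, output, seed."""

    out_dir: str
    seed: int = 0
    design: StudyDesign | None = None          # simulate mode
    matrix_paths: list[str] = field(default_factory=list)   # load mode
    design_paths: list[str] = field(default_factory=list)
    gmt_path: str | None = None
    criteria: list[DEGCriterion] = field(
        default_factory=lambda: list(DEFAULT_CRITERIA))
    fdr_cutoff: float = 0.25
    gsea_params: dict = field(default_factory=dict)
    lrpath_params: dict = field(default_factory=dict)
    engines: tuple[str, ...] = ("gsea", "lrpath")
    write_simulated_data: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ParameterError("criteria grid must be non-empty")
        if self.design is None:
            if not self.matrix_paths or self.gmt_path is None:
                raise ParameterError(
                    "load mode needs matrix_paths, design_paths and gmt_path")
            if len(self.matrix_paths) != len(self.design_paths):
                raise ParameterError("matrix_paths/design_paths length mismatch")
            for p in [*self.matrix_paths, *self.design_paths, self.gmt_path]:
                if not Path(p).exists():
                    raise ParameterError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "design" in raw and raw["design"] is not None:
            d = raw["design"]
            for k in ("platforms",):
                if k in d:
                    d[k] = tuple(d[k])
            for k in ("gene_sd_range", "set_size_range"):
                if k in d:
                    d[k] = tuple(d[k])
            raw["design"] = StudyDesign(**d)
        if "criteria" in raw:
            raw["criteria"] = [DEGCriterion(**c) for c in raw["criteria"]]
        if "engines" in raw:
            raw["engines"] = tuple(raw["engines"])
        return cls(**raw)


def run_study(config: PipelineConfig) -> dict:
    """Execute a full study and write all tables; returns the run manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "engines": list(config.engines),
                      "failures": [], "exclusions": [], "timings_s": {}}

    if config.design is not None:
        design = config.design
        if design.seed != config.seed:
            from dataclasses import replace
            design = replace(design, seed=config.seed)
        studies, gene_sets, truth = generate_study(design)
        manifest["mode"] = "simulate"
        if config.write_simulated_data:
            data_dir = out / "data"
            data_dir.mkdir(exist_ok=True)
            for st in studies:
                p = st.platforms[0]
                write_expression_study(st, data_dir / f"{p}_matrix.tsv",
                                       data_dir / f"{p}_design.tsv")
            write_gmt(gene_sets, data_dir / "gene_sets.gmt")
            write_results_table(
                truth.effects.rename("delta").reset_index(),
                data_dir / "ground_truth.tsv")
    else:
        studies = [read_expression_matrix(m, d)
                   for m, d in zip(config.matrix_paths, config.design_paths)]
        gene_sets = read_gmt(config.gmt_path)
        manifest["mode"] = "load"
    manifest["timings_s"]["data"] = round(time.time() - t0, 2)

    t1 = time.time()
    result = analyze_study(studies, gene_sets, config.criteria,
                           seed=config.seed, fdr_cutoff=config.fdr_cutoff,
                           gsea_params=config.gsea_params,
                           lrpath_params=config.lrpath_params,
                           engines=config.engines)
    manifest["failures"] = result.failures
    manifest["timings_s"]["analysis"] = round(time.time() - t1, 2)

    # (a) DEG count table
    counts = deg_count_table(result.deg_lists)
    counts.to_csv(out / "deg_counts.tsv", sep="\t", index_label="criterion")

    # (b) per-combination enrichment tables
    enr_dir = out / "enrichment"
    enr_dir.mkdir(exist_ok=True)
    for key, res in result.gsea_results.items():
        name = "gsea_" + "_".join(str(k) for k in key) + ".tsv"
        write_results_table(
            [{"set_id": r.set_id, "direction": r.direction, "size": r.size,
              "es": r.es, "nes": r.nes, "fdr_q": r.fdr_q,
              "significant": r.significant(config.fdr_cutoff)} for r in res],
            enr_dir / name)
    for key, res in result.lrpath_results.items():
        name = "lrpath_" + "_".join(str(k) for k in key) + ".tsv"
        write_results_table(
            [{"set_id": r.set_id, "size": r.size, "b0": r.beta0,
              "b1": r.beta1, "se": r.slope_se, "wald_p": r.wald_p,
              "bh_q": r.bh_q,
              "significant": r.significant(config.fdr_cutoff)} for r in res],
            enr_dir / name)

    # (c) concordance tables and curves
    plan = cc.ComparisonPlan(
        platforms=result.platforms, sites=result.sites,
        criteria=[(c.method, c.p_cutoff) for c in config.criteria],
        engines=[e for e in config.engines],
    )
    table, curves, exclusions = cc.compare_all(result.catalog, plan)
    manifest["exclusions"] = exclusions
    curve_dir = out / "curves"
    curve_dir.mkdir(exist_ok=True)
    refs = []
    for idx in table.index if len(table) else []:
        if idx in curves:
            fname = f"curve_{idx:04d}.tsv"
            write_results_table(curves[idx].to_frame(), curve_dir / fname)
            refs.append(fname)
        else:
            refs.append("")
    if len(table):
        table = table.assign(curve_file=refs)
    write_results_table(table, out / "concordance.tsv")

    # (d) manifest
    n_enr = len(result.gsea_results) + len(result.lrpath_results)
    planned = (len(result.stats) * len(config.criteria) * len(config.engines))
    manifest["work_items"] = {
        "planned_enrichment_runs": planned,
        "completed_enrichment_runs": n_enr,
        "failed_or_skipped": planned - n_enr,
        "comparisons_emitted": int(len(table)),
        "comparisons_excluded": len(exclusions),
    }
    from . import __version__
    manifest["version"] = __version__
    manifest["timings_s"]["total"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    if manifest["failures"]:
        logger.warning("run finished with %d stage failure(s)",
                       len(manifest["failures"]))
    return manifest


# ---------------------------------------------------------------------------
# the criterion-comparison study (heteroscedastic, multi-seed)
# ---------------------------------------------------------------------------

def criterion_comparison_study(
        seeds: Sequence[int],
        design_factory=StudyDesign.heteroscedastic_pair,
        criteria: Sequence[DEGCriterion] = tuple(DEFAULT_CRITERIA),
        gsea_params: Mapping | None = None,
        lrpath_params: Mapping | None = None) -> pd.DataFrame:
    """Intra-site criterion-pair concordance over a family of seeds.

    Runs the full pipeline on ``design_factory(seed)`` for every seed and
    returns one row per (seed, engine, criterion pair, cell) with the
    terminal POG — the input for the fold-change-vs-SAM concordance
    contrast.  GSEA defaults to ``n_perm=500`` here; the desk-scale null is
    smooth enough at that depth and it halves the study's runtime.
    """
    gsea_params = dict(gsea_params or {})
    gsea_params.setdefault("n_perm", 500)
    frames = []
    for seed in seeds:
        studies, gene_sets, _truth = generate_study(design_factory(seed))
        result = analyze_study(studies, gene_sets, criteria, seed=seed,
                               gsea_params=gsea_params,
                               lrpath_params=lrpath_params)
        plan = cc.ComparisonPlan(
            platforms=result.platforms, sites=result.sites,
            criteria=[(c.method, c.p_cutoff) for c in criteria],
            families=(cc.FAMILY_INTRA_SITE,),
        )
        table, _curves, _exc = cc.compare_all(result.catalog, plan)
        table["seed"] = seed
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def criterion_pair_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Median terminal POG per (engine, criterion pair), NA comparisons dropped."""
    t = table.dropna(subset=["pog_terminal"]).copy()
    t["pair"] = t["method_a"] + "_vs_" + t["method_b"]
    return (t.groupby(["engine", "pair"])["pog_terminal"]
             .median().rename("median_pog").reset_index())
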