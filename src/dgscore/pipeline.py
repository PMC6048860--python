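"""End-to-end orchestration of the driver-gene pipeline.

Stage order: per-patient segmentation -> CNA filtering -> recurrent-region
detection -> gene annotation -> expression preprocessing -> FGS (full and
direction-pure common) -> AGS (per patient and common, optionally extended
with a literature list) -> NEA driver calling (common and patient-specific)
-> DGscore -> median split -> KM/log-rank and Cox validation -> optional
bootstrap stability.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from dgscore import io as dio
from dgscore.config import PipelineConfig
from dgscore.errors import DegenerateSplitError, DgscoreError
from dgscore.gene_sets import (ExpressionMatrix, FgsResult, GeneSet,
                               annotate_regions, build_common_ags,
                               build_common_fgs, build_fgs, build_patient_ags,
                               preprocess_expression)
from dgscore.nea import (DriverCall, InteractionNetwork, call_common_drivers,
                         call_patient_drivers)
from dgscore.segmentation import (CnaSegment, RecurrentRegion,
                                  SegmentationParams, detect_recurrent_regions,
                                  filter_segments, segment_profile)
from dgscore.stability import BootstrapResult, bootstrap_common_drivers
from dgscore.survival import (PatientScore, compute_dgscore, cox_models,
                              km_logrank, median_split)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    patients: List[str]
    segments_by_patient: Dict[str, List[CnaSegment]]
    cnas_by_patient: Dict[str, List[CnaSegment]]
    regions: List[RecurrentRegion]
    region_genes: List[List[str]]
    expr: ExpressionMatrix
    fgs: FgsResult
    fgs_common: GeneSet
    patient_ags: Dict[str, GeneSet]
    ags_common: GeneSet
    common_calls: List[DriverCall]
    patient_calls: List[DriverCall]
    scores: List[PatientScore]
    survival: dict
    cox: list
    bootstrap: Optional[BootstrapResult]
    report: dict

    @property
    def driver_calls(self) -> List[DriverCall]:
        return list(self.common_calls) + list(self.patient_calls)

    @property
    def unique_drivers(self) -> Set[str]:
        return {d.gene for d in self.driver_calls}

    def altered_genes_by_patient(self) -> Dict[str, Set[str]]:
        return {p: self.fgs.altered_genes_of(p) for p in self.patients}


def _segmentation_params(cfg: PipelineConfig) -> SegmentationParams:
    return SegmentationParams(
        gain_threshold=cfg.gain_threshold, loss_threshold=cfg.loss_threshold,
        max_fdr=cfg.max_fdr, min_length_bp=cfg.min_length_bp,
        min_probes=cfg.min_probes, recurrence_fraction=cfg.recurrence_fraction,
        penalty=cfg.penalty)


def segment_cohort(
    probe_map: pd.DataFrame,
    log_ratios: pd.DataFrame,
    params: SegmentationParams,
) -> Dict[str, List[CnaSegment]]:
    """Segment every patient's profile (the expensive, cacheable step)."""
    out = {}
    for pat in log_ratios.columns:
        out[pat] = segment_profile(probe_map, log_ratios[pat].to_numpy(),
                                   params, patient=pat)
    return out


def common_driver_stage(
    cnas_by_patient: Dict[str, Sequence[CnaSegment]],
    patients: Sequence[str],
    expression: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    network: InteractionNetwork,
    cfg: PipelineConfig,
    probe_map: pd.DataFrame,
    literature_genes: Optional[Sequence[str]] = None,
) -> dict:
    """Recurrence -> FGS -> AGS -> common-driver calls for a patient multiset.

    Duplicated patients (bootstrap resamples) are handled by giving each
    draw its own pseudo-id; recurrence thresholds and AGS recurrence counts
    then weight a duplicated patient accordingly.
    """
    pats = list(patients)
    if len(set(pats)) != len(pats):  # multiset: disambiguate duplicates
        ids = [f"{p}@{i}" for i, p in enumerate(pats)]
    else:
        ids = pats
    cnas = {i: list(cnas_by_patient[p]) for i, p in zip(ids, pats)}
    exprs = expression[pats].copy()
    exprs.columns = ids

    params = _segmentation_params(cfg)
    regions = detect_recurrent_regions(cnas, len(ids), probe_map,
                                       cfg.recurrence_fraction)
    region_genes = annotate_regions(regions, gene_annotation)
    expr = preprocess_expression(exprs)
    fgs = build_fgs(regions, region_genes, expr, cnas, gene_annotation, ids,
                    alpha=cfg.concordance_alpha)
    fgs_common = build_common_fgs(fgs, regions)
    patient_ags = {p: build_patient_ags(expr, p, cfg.ags_top_n) for p in ids}
    universe = network.nodes | set(expr.genes)
    ags_common = build_common_ags(patient_ags, cfg.common_ags_min_recurrence,
                                  literature_genes, universe=universe)
    if ags_common.genes:
        common_calls = call_common_drivers(
            fgs_common, ags_common, network, z_threshold=cfg.z_threshold,
            null_kind=cfg.nea_null_kind, n_permutations=cfg.nea_n_permutations,
            seed=cfg.seed)
    else:
        common_calls = []
    return dict(regions=regions, region_genes=region_genes, expr=expr,
                fgs=fgs, fgs_common=fgs_common, patient_ags=patient_ags,
                ags_common=ags_common, common_calls=common_calls, ids=ids)


def run_on_cohort(
    cohort,
    config: Optional[PipelineConfig] = None,
    literature_genes: Optional[Sequence[str]] = None,
    run_survival: bool = True,
    run_bootstrap: bool = False,
    segments_by_patient: Optional[Dict[str, List[CnaSegment]]] = None,
) -> PipelineResult:
    """Run the full pipeline on an in-memory cohort.

    ``cohort`` needs attributes probe_map, log_ratios, expression,
    gene_annotation, network (networkx Graph or InteractionNetwork) and
    clinical -- a :class:`dgscore.synth.SyntheticCohort` fits, as does any
    object assembled from the file readers.
    """
    cfg = (config or PipelineConfig()).validate()
    t0 = time.time()
    patients = list(cohort.log_ratios.columns)
    network = (cohort.network if isinstance(cohort.network, InteractionNetwork)
               else InteractionNetwork(cohort.network.edges()))
    params = _segmentation_params(cfg)

    if segments_by_patient is None:
        segments_by_patient = segment_cohort(cohort.probe_map, cohort.log_ratios, params)
    cnas_by_patient = {p: filter_segments(s, params)
                       for p, s in segments_by_patient.items()}

    stage = common_driver_stage(
        cnas_by_patient, patients, cohort.expression, cohort.gene_annotation,
        network, cfg, cohort.probe_map, literature_genes)

    fgs: FgsResult = stage["fgs"]
    altered = {p: fgs.altered_genes_of(p) for p in patients}
    patient_calls = call_patient_drivers(
        fgs.gene_set, stage["patient_ags"], altered, network,
        z_threshold=cfg.z_threshold, null_kind=cfg.nea_null_kind,
        n_permutations=cfg.nea_n_permutations, seed=cfg.seed)
    all_calls = list(stage["common_calls"]) + patient_calls

    scores = compute_dgscore(all_calls, altered, patients, mode=cfg.dgscore_mode,
                             fgs_genes=fgs.gene_set.genes)
    survival_stats: dict = {}
    cox: list = []
    if run_survival:
        try:
            median_split(scores)
            groups = {"high": [s.patient for s in scores if s.group == "high"],
                      "low": [s.patient for s in scores if s.group == "low"]}
            survival_stats = km_logrank(groups, cohort.clinical)
            cox = cox_models(scores, cohort.clinical,
                             dg_continuous=cfg.dgscore_continuous)
        except DegenerateSplitError as e:
            log.warning("survival validation skipped: %s", e)
            survival_stats = {"error": str(e)}

    bootstrap = None
    if run_bootstrap:
        n_annotated = len(fgs.annotated_genes)
        observed = [d.gene for d in stage["common_calls"]]

        def rerun(resample: Sequence[str]) -> Sequence[str]:
            st = common_driver_stage(
                cnas_by_patient, resample, cohort.expression,
                cohort.gene_annotation, network, cfg, cohort.probe_map,
                literature_genes)
            return [d.gene for d in st["common_calls"]]

        bootstrap = bootstrap_common_drivers(
            rerun, patients, B=cfg.bootstrap_B, seed=cfg.seed,
            p_null=cfg.bootstrap_p_null, observed_drivers=observed,
            n_annotated_genes=n_annotated)

    report = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_patients": len(patients),
        "n_segments": sum(len(s) for s in segments_by_patient.values()),
        "n_cnas": sum(len(s) for s in cnas_by_patient.values()),
        "n_recurrent_regions": len(stage["regions"]),
        "n_annotated_genes": len(fgs.annotated_genes),
        "n_fgs": len(fgs.gene_set),
        "n_fgs_common": len(stage["fgs_common"]),
        "n_ags_common": len(stage["ags_common"]),
        "common_drivers": sorted(d.gene for d in stage["common_calls"]),
        "n_patient_driver_calls": len(patient_calls),
        "unique_patient_drivers": sorted({d.gene for d in patient_calls}),
        "dgscore": {s.patient: s.dgscore for s in scores},
        "logrank_p": survival_stats.get("logrank_p"),
        "cox": [{"model": c.model_id, "terms": c.terms, "converged": c.converged,
                 "note": c.note} for c in cox],
        "runtime_s": round(time.time() - t0, 2),
    }
    if bootstrap is not None:
        report["bootstrap"] = {
            "B": bootstrap.B, "p_null": bootstrap.p_null,
            "selection_count": bootstrap.selection_count,
            "proportion": bootstrap.proportion,
            "p_value": bootstrap.p_value,
        }
    return PipelineResult(
        config=cfg, patients=patients, segments_by_patient=segments_by_patient,
        cnas_by_patient=cnas_by_patient, regions=stage["regions"],
        region_genes=stage["region_genes"], expr=stage["expr"], fgs=fgs,
        fgs_common=stage["fgs_common"], patient_ags=stage["patient_ags"],
        ags_common=stage["ags_common"], common_calls=stage["common_calls"],
        patient_calls=patient_calls, scores=scores, survival=survival_stats,
        cox=cox, bootstrap=bootstrap, report=report)


@dataclass
class _FileCohort:
    probe_map: pd.DataFrame
    log_ratios: pd.DataFrame
    expression: pd.DataFrame
    gene_annotation: pd.DataFrame
    network: InteractionNetwork
    clinical: pd.DataFrame


def load_cohort(cfg: PipelineConfig) -> _FileCohort:
    """Read all pipeline inputs from the paths in the configuration."""
    for name in ("probe_map", "log_ratios", "expression", "gene_annotation",
                 "network", "clinical"):
        if getattr(cfg, name) is None:
            raise DgscoreError(f"config path {name!r} not set")
    clinical = dio.read_clinical(cfg.clinical)
    probe_map = dio.read_probe_map(cfg.probe_map)
    return _FileCohort(
        probe_map=probe_map,
        log_ratios=dio.read_probe_matrix(cfg.log_ratios, probe_map, clinical),
        expression=dio.read_expression(cfg.expression),
        gene_annotation=dio.read_gene_annotation(cfg.gene_annotation),
        network=dio.read_network(cfg.network),
        clinical=clinical,
    )


def run_pipeline(config: PipelineConfig, run_bootstrap: bool = False) -> dict:
    """File-to-file pipeline run: read inputs, run, write every stage output.

    Returns the JSON-ready run report; raises with a stage-labelled message
    on failure.
    """
    cfg = config.validate()
    cohort = load_cohort(cfg)
    lit = dio.read_literature_genes(cfg.literature_genes) if cfg.literature_genes else None
    res = run_on_cohort(cohort, cfg, literature_genes=lit,
                        run_bootstrap=run_bootstrap)
    if cfg.outdir:
        out = Path(cfg.outdir)
        h = cfg.hash()
        dio.write_segments([s for segs in res.segments_by_patient.values()
                            for s in segs], out / "segments.tsv", h)
        dio.write_segments([s for segs in res.cnas_by_patient.values()
                            for s in segs], out / "cnas.tsv", h)
        dio.write_regions_bed(res.regions, out / "regions.bed", h)
        dio.write_gene_set(res.fgs.gene_set, out / "fgs_full.tsv", h)
        dio.write_gene_set(res.fgs_common, out / "fgs_common.tsv", h)
        dio.write_gene_set(res.ags_common, out / "ags_common.tsv", h)
        dio.write_drivers(res.driver_calls, out / "drivers.tsv", h)
        dio.write_scores(res.scores, out / "scores.tsv", h)
        if res.bootstrap is not None:
            bs = res.bootstrap
            df = pd.DataFrame([
                {"gene": g, "x": x, "B": bs.B, "proportion": bs.proportion[g],
                 "p_null": bs.p_null, "p_value": bs.p_value[g]}
                for g, x in sorted(bs.selection_count.items())])
            dio.write_matrix(df.set_index("gene"), out / "bootstrap.tsv",
                             "bootstrap", h)
        dio.write_report(res.report, out / "report.json")
    return res.report
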