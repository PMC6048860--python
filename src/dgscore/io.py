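"""Readers and writers for all interchange formats (plain TSV/BED/JSON).

Every writer stamps a comment header naming the producing stage and the
configuration hash; readers skip ``#`` comment lines.  Genomic intervals
are BED-convention (0-based half-open) throughout.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from dgscore.errors import InputError
from dgscore.gene_sets import GeneSet
from dgscore.nea import DriverCall, InteractionNetwork
from dgscore.segmentation import CnaSegment, RecurrentRegion
from dgscore.survival import PatientScore

log = logging.getLogger(__name__)

_INSS_STAGES = {"1", "2", "3", "4", "4S"}


def _header(stage: str, config_hash: str = "") -> str:
    h = f"# stage={stage}"
    if config_hash:
        h += f" config={config_hash}"
    return h + " coords=0-based-half-open\n"


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, config_hash: str,
               index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(stage, config_hash))
        df.to_csv(fh, sep="\t", index=index)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", comment="#", dtype={"probe": str, "chrom": str})
    for col in ("probe", "chrom", "pos"):
        if col not in pm.columns:
            raise InputError(f"probe map missing column {col!r}")
    if pm["probe"].duplicated().any():
        dup = pm.loc[pm["probe"].duplicated(), "probe"].iloc[0]
        raise InputError(f"duplicate probe id {dup!r} in probe map")
    pm = pm.set_index("probe")
    # sort by (chrom, pos) with a stable chromosome order of first appearance
    order = {c: i for i, c in enumerate(pd.unique(pm["chrom"]))}
    pm = pm.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s,
                        kind="stable")
    return pm


def read_probe_matrix(path: str | Path, probe_map: pd.DataFrame,
                      clinical: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Probe x patient log2-ratio matrix, aligned to the probe map order."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        raise InputError("duplicate probe ids in log-ratio matrix")
    missing = set(probe_map.index) - set(df.index)
    if missing:
        raise InputError(f"log-ratio matrix missing probes: {sorted(missing)[:5]}")
    df = df.loc[probe_map.index]
    bad = df.columns[~df.apply(lambda c: np.issubdtype(c.dtype, np.number))]
    if len(bad):
        raise InputError(f"non-numeric log-ratio columns: {list(bad)}")
    if clinical is not None:
        unknown = set(df.columns) - set(clinical.index)
        if unknown:
            raise InputError(f"samples absent from clinical table: {sorted(unknown)}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        raise InputError("duplicate gene ids in expression matrix")
    if (df.to_numpy() < 0).any():
        raise InputError("negative FPKM values in expression matrix")
    return df


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene": str, "chrom": str})
    for col in ("gene", "chrom", "start", "end"):
        if col not in df.columns:
            raise InputError(f"gene annotation missing column {col!r}")
    return df.set_index("gene")


def read_network(path: str | Path) -> InteractionNetwork:
    """2-column edge-list TSV; SIF (gene interaction gene) also accepted."""
    edges = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:  # SIF: source, interaction type (ignored), targets
                edges.extend((parts[0], t) for t in parts[2:])
            else:
                raise InputError(f"unparseable network line {i}: {line!r}")
    return InteractionNetwork(edges)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient": str, "stage": str})
    for col in ("patient", "os_days", "os_event", "age_days", "stage",
                "mycn_amp", "high_risk"):
        if col not in df.columns:
            raise InputError(f"clinical table missing column {col!r}")
    bad = set(df["stage"].astype(str)) - _INSS_STAGES
    if bad:
        raise InputError(f"unknown INSS stage label(s): {sorted(bad)}")
    if (df["os_days"] <= 0).any():
        raise InputError("os_days must be positive")
    return df.set_index("patient")


def read_literature_genes(path: str | Path) -> List[str]:
    genes = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    return genes


# ---------------------------------------------------------------- writers

def write_probe_map(pm: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    _write_tsv(pm.rename_axis("probe"), Path(path), "probe_map", config_hash)


def write_matrix(df: pd.DataFrame, path: str | Path, stage: str,
                 config_hash: str = "") -> None:
    _write_tsv(df, Path(path), stage, config_hash)


def write_gene_annotation(df: pd.DataFrame, path: str | Path,
                          config_hash: str = "") -> None:
    _write_tsv(df.rename_axis("gene"), Path(path), "gene_annotation", config_hash)


def write_network(net: InteractionNetwork | nx.Graph, path: str | Path,
                  config_hash: str = "") -> None:
    edges = net.edges() if isinstance(net, InteractionNetwork) else net.edges()
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        fh.write(_header("network", config_hash))
        for u, v in sorted(tuple(sorted(e)) for e in edges):
            fh.write(f"{u}\t{v}\n")


def write_clinical(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    _write_tsv(df.rename_axis("patient"), Path(path), "clinical", config_hash)


def write_segments(segments: Sequence[CnaSegment], path: str | Path,
                   config_hash: str = "") -> None:
    df = pd.DataFrame([{
        "patient": s.patient, "chrom": s.chromosome, "start": s.start,
        "end": s.end, "n_probes": s.n_probes, "mean_lr": round(s.mean_lr, 6),
        "state": s.state, "q_value": s.q_value,
    } for s in segments])
    _write_tsv(df, Path(path), "segments", config_hash, index=False)


def read_segments(path: str | Path) -> List[CnaSegment]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient": str, "chrom": str})
    return [CnaSegment(patient=r.patient, chromosome=r.chrom, start=int(r.start),
                       end=int(r.end), n_probes=int(r.n_probes),
                       mean_lr=float(r.mean_lr), state=r.state,
                       q_value=float(r.q_value))
            for r in df.itertuples()]


def write_regions_bed(regions: Sequence[RecurrentRegion], path: str | Path,
                      config_hash: str = "") -> None:
    """BED with the carrier count in the score column."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        fh.write(_header("recurrent_regions", config_hash))
        for i, r in enumerate(regions):
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\tregion_{i}\t{r.n_carriers}\t.\n")


def write_gene_set(gs: GeneSet, path: str | Path, config_hash: str = "") -> None:
    df = pd.DataFrame({
        "gene": gs.genes,
        "provenance": gs.provenance,
        "direction": [gs.direction.get(g, "") for g in gs.genes],
        "source": [gs.source.get(g, "") for g in gs.genes],
    })
    _write_tsv(df, Path(path), "gene_set", config_hash, index=False)


def write_drivers(calls: Sequence[DriverCall], path: str | Path,
                  config_hash: str = "") -> None:
    df = pd.DataFrame([{
        "gene": d.gene, "scope": d.scope, "d_AF": d.d_af,
        "mu_AF": round(d.mu_af, 6), "sigma_AF": round(d.sigma_af, 6),
        "z": round(d.z, 6), "null_kind": d.null_kind, "ags": d.ags_used,
    } for d in calls])
    _write_tsv(df, Path(path), "drivers", config_hash, index=False)


def write_scores(scores: Sequence[PatientScore], path: str | Path,
                 config_hash: str = "") -> None:
    df = pd.DataFrame([{
        "patient": s.patient, "dgscore": s.dgscore, "group": s.group,
        "drivers": ",".join(s.contributing_drivers),
    } for s in scores])
    _write_tsv(df, Path(path), "scores", config_hash, index=False)


def write_report(report: dict, path: str | Path) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))


def write_cohort(cohort, outdir: str | Path) -> Dict[str, Path]:
    """Write a synthetic cohort in the exact formats the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "probe_map": out / "probe_map.tsv",
        "log_ratios": out / "log_ratios.tsv",
        "expression": out / "expression.tsv",
        "gene_annotation": out / "gene_annotation.tsv",
        "network": out / "network.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    write_probe_map(cohort.probe_map, paths["probe_map"])
    write_matrix(cohort.log_ratios.rename_axis("probe"), paths["log_ratios"], "log_ratios")
    write_matrix(cohort.expression.rename_axis("gene"), paths["expression"], "expression")
    write_gene_annotation(cohort.gene_annotation, paths["gene_annotation"])
    write_network(InteractionNetwork(cohort.network.edges()), paths["network"])
    write_clinical(cohort.clinical, paths["clinical"])
    truth = cohort.truth
    paths["truth"].write_text(json.dumps({
        "planted_regions": [
            {k: v for k, v in reg.items() if k != "carriers"}
            | {"carriers": reg["carriers"]}
            for reg in truth.planted_regions],
        "planted_drivers": truth.planted_drivers,
        "driver_targets": truth.driver_targets,
        "per_patient_driver_count": truth.per_patient_driver_count,
        "mycn_locus": truth.mycn_locus,
    }, indent=1, default=str))
    return paths
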