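"""Synthetic multi-omics cohorts with planted ground truth.

Emulates the joint structure of a neuroblastoma-style integration cohort:
per-patient aCGH probe log2-ratios with planted recurrent gain/loss regions,
RNA-seq-like FPKM expression with cis dosage effects on planted driver genes
and trans effects on their network neighbors, a scale-free functional
interaction network with planted driver hubs, and exponential survival whose
hazard scales with each patient's planted driver burden.  Every planted fact
is recorded in a :class:`GroundTruth` so downstream stages can be tested for
recovery without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from dgscore.errors import InvalidConfigError

# expression baseline: per-gene lognormal abundance (log2 scale)
_MEANLOG_MEAN = 3.0
_MEANLOG_SD = 1.5
_EXPR_NOISE_SD = 1.0
# nominal within-patient sd of log2 expression; cis/trans effects are given
# in units of this scale ("within-patient z-units")
_WITHIN_PATIENT_SD = math.sqrt(_MEANLOG_SD**2 + _EXPR_NOISE_SD**2)

_GENE_LENGTH = 5_000
_GENE_SPACING = 10_000
_REGION_GENE_GAP = 10  # genes left untouched between planted regions
_STAGES = np.array(["1", "2", "3", "4", "4S"])
_STAGE_P = np.array([0.05, 0.05, 0.10, 0.70, 0.10])  # high-risk cohorts are stage-4 heavy


@dataclass
class SynthConfig:
    """Generator settings; defaults define the standard study conditions.

    Cohort shape follows the integration subset of the motivating study
    (48 high-risk patients with matched copy-number and expression data),
    scaled down to 2000 genes.  Effect sizes (``gain_shift``/``loss_shift``
    of +-0.5 log2-ratio units, ``cis_effect`` 2 and ``trans_effect`` 1.5
    within-patient z-units, 15-gene driver fanout) are the default planted
    signal strengths; ``log_hr_per_driver`` defaults to ln(2.7), mirroring
    the hazard ratio scale the score is validated against.
    """

    n_patients: int = 48
    n_genes: int = 2000
    n_chromosomes: int = 8
    probes_per_gene: int = 2

    n_planted_regions: int = 16
    planted_region_gene_span: int = 8
    planted_carrier_fraction: float = 0.25
    gain_shift: float = 0.5
    loss_shift: float = -0.5
    probe_noise_sd: float = 0.05

    n_planted_drivers: int = 10
    cis_effect: float = 2.0
    trans_effect: float = 1.5
    neighbor_fanout: int = 15
    network_attachment: int = 2

    baseline_hazard: float = 5e-4  # events per day
    log_hr_per_driver: float = math.log(2.7)
    censor_rate: float = 0.2

    # optional structure for specific experiments (off by default)
    cis_effect_passenger: float = 0.0  # dosage response for non-driver region genes
    n_mixed_regions: int = 0  # driver-free regions planted with mixed gain/loss carriers
    mycn_linked_region: bool = False  # tie region 0 carriers to MYCN-amplified patients

    seed: int = 0

    def validate(self) -> "SynthConfig":
        counts = dict(
            n_patients=self.n_patients, n_genes=self.n_genes,
            n_chromosomes=self.n_chromosomes, probes_per_gene=self.probes_per_gene,
            n_planted_regions=self.n_planted_regions,
            planted_region_gene_span=self.planted_region_gene_span,
            neighbor_fanout=self.neighbor_fanout,
            network_attachment=self.network_attachment,
        )
        for name, v in counts.items():
            if v < 1:
                raise InvalidConfigError(f"{name} must be a positive count, got {v}")
        if self.n_planted_drivers < 0:
            raise InvalidConfigError("n_planted_drivers must be >= 0")
        if not (0 < self.planted_carrier_fraction <= 1):
            raise InvalidConfigError("planted_carrier_fraction must lie in (0,1]")
        if self.planted_carrier_fraction * self.n_patients < 1:
            raise InvalidConfigError("carrier fraction yields < 1 carrier")
        if self.n_planted_drivers > self.n_planted_regions * self.planted_region_gene_span:
            raise InvalidConfigError("more drivers than planted region genes")
        if self.n_planted_drivers > self.n_planted_regions:
            # one driver per region keeps driver carriage independent across regions
            raise InvalidConfigError("at most one driver per region is supported")
        if self.n_mixed_regions > self.n_planted_regions - self.n_planted_drivers:
            raise InvalidConfigError("mixed regions must be driver-free regions")
        if self.neighbor_fanout >= self.n_genes:
            raise InvalidConfigError("neighbor_fanout must be < n_genes")
        if self.n_genes < self.network_attachment + 1:
            raise InvalidConfigError("n_genes must exceed network_attachment")
        if not (0 <= self.censor_rate < 1):
            raise InvalidConfigError("censor_rate must lie in [0,1)")
        if self.gain_shift <= 0 or self.loss_shift >= 0:
            raise InvalidConfigError("need gain_shift > 0 > loss_shift")
        # geometry feasibility: regions placed round-robin over chromosomes
        genes_per_chrom = -(-self.n_genes // self.n_chromosomes)
        per_chrom = -(-self.n_planted_regions // self.n_chromosomes)
        need = per_chrom * (self.planted_region_gene_span + _REGION_GENE_GAP)
        if need > genes_per_chrom:
            raise InvalidConfigError(
                f"planted regions do not fit: need {need} genes per chromosome, "
                f"have {genes_per_chrom}")
        return self


@dataclass
class GroundTruth:
    """Everything that was planted, for recovery checks downstream."""

    planted_regions: List[dict]  # chrom,start,end,direction,carriers,genes,driver
    planted_drivers: List[str]
    driver_targets: Dict[str, List[str]]  # driver -> trans-wired neighbor genes
    per_patient_driver_count: Dict[str, int]
    mycn_locus: Optional[Tuple[str, int, int]] = None


@dataclass
class SyntheticCohort:
    gene_annotation: pd.DataFrame  # index gene; chrom, start, end
    probe_map: pd.DataFrame  # index probe; chrom, pos
    log_ratios: pd.DataFrame  # probe x patient
    expression: pd.DataFrame  # gene x patient (FPKM-like, nonnegative)
    network: nx.Graph
    clinical: pd.DataFrame  # index patient
    truth: GroundTruth
    config: SynthConfig

    @property
    def patients(self) -> List[str]:
        return list(self.clinical.index)


def _gene_layout(cfg: SynthConfig) -> pd.DataFrame:
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    rows = []
    for i in range(cfg.n_genes):
        c, j = divmod(i, genes_per_chrom)
        start = j * _GENE_SPACING
        rows.append((f"G{i:04d}", f"chr{c + 1}", start, start + _GENE_LENGTH))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).set_index("gene")


def _probe_layout(cfg: SynthConfig, genes: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray]:
    """Probes evenly placed inside each gene; returns map plus gene index per probe."""
    ppg = cfg.probes_per_gene
    offsets = (np.arange(1, ppg + 1) * _GENE_LENGTH) // (ppg + 1)
    chroms = np.repeat(genes["chrom"].to_numpy(), ppg)
    pos = (np.repeat(genes["start"].to_numpy(), ppg)
           + np.tile(offsets, len(genes)))
    probe_ids = [f"PR{i:06d}" for i in range(len(genes) * ppg)]
    pm = pd.DataFrame({"chrom": chroms, "pos": pos}, index=pd.Index(probe_ids, name="probe"))
    gene_idx = np.repeat(np.arange(len(genes)), ppg)
    return pm, gene_idx


def generate_network(
    n_genes: int,
    network_attachment: int,
    planted_drivers: Optional[List[str]] = None,
    neighbor_fanout: int = 0,
    seed: int = 0,
    gene_ids: Optional[List[str]] = None,
    target_pool: Optional[List[str]] = None,
) -> Tuple[nx.Graph, Dict[str, List[str]]]:
    """Scale-free interaction network with optional planted driver hubs.

    Grows a Barabasi-Albert graph (``network_attachment`` edges per new
    node), then wires every planted driver to ``neighbor_fanout`` distinct
    target genes drawn from ``target_pool`` (default: all other genes).
    Returns the graph and the driver -> targets map.
    """
    if n_genes < network_attachment + 1:
        raise InvalidConfigError("n_genes must exceed network_attachment")
    if neighbor_fanout >= n_genes:
        raise InvalidConfigError("neighbor_fanout must be < n_genes")
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise InvalidConfigError("gene_ids length must equal n_genes")
    rng = np.random.default_rng(seed)
    ba_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(n_genes, network_attachment, seed=ba_seed)
    # decouple topology from genomic order: node age (hence degree) must not
    # correlate with gene position, so assign gene ids in shuffled order
    shuffled = list(rng.permutation(gene_ids))
    g = nx.relabel_nodes(g, dict(enumerate(shuffled)))
    targets: Dict[str, List[str]] = {}
    planted_drivers = planted_drivers or []
    pool_base = target_pool if target_pool is not None else gene_ids
    for drv in planted_drivers:
        pool = [x for x in pool_base
                if x != drv and not g.has_edge(drv, x) and x not in planted_drivers]
        if neighbor_fanout > len(pool):
            raise InvalidConfigError("not enough eligible target genes for fanout")
        chosen = list(rng.choice(pool, size=neighbor_fanout, replace=False))
        g.add_edges_from((drv, t) for t in chosen)
        targets[drv] = chosen
    return g, targets


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Generate a fully synthetic cohort; deterministic given ``config.seed``."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = _gene_layout(cfg)
    gene_ids = list(genes.index)
    probe_map, probe_gene = _probe_layout(cfg, genes)
    patients = [f"P{i:03d}" for i in range(1, cfg.n_patients + 1)]

    # ---- plant regions -------------------------------------------------
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    n_carriers = max(1, round(cfg.planted_carrier_fraction * cfg.n_patients))
    span = cfg.planted_region_gene_span
    chrom_slots: Dict[int, int] = {}
    regions: List[dict] = []
    mixed_ids = set(range(cfg.n_planted_regions - cfg.n_mixed_regions,
                          cfg.n_planted_regions))
    for r in range(cfg.n_planted_regions):
        c = r % cfg.n_chromosomes
        k = chrom_slots.get(c, 0)
        chrom_slots[c] = k + 1
        g0 = c * genes_per_chrom + k * (span + _REGION_GENE_GAP)
        region_genes = gene_ids[g0:g0 + span]
        if len(region_genes) < span:
            raise InvalidConfigError("planted region exceeds chromosome")
        direction = "gain" if rng.random() < 0.5 else "loss"
        carriers = sorted(rng.choice(patients, size=n_carriers, replace=False))
        if r in mixed_ids:
            half = len(carriers) // 2
            dirs = {p: ("gain" if i < half else "loss") for i, p in enumerate(carriers)}
            direction = "mixed"
        else:
            dirs = {p: direction for p in carriers}
        regions.append(dict(
            chrom=genes.loc[region_genes[0], "chrom"],
            start=int(genes.loc[region_genes[0], "start"]),
            end=int(genes.loc[region_genes[-1], "end"]),
            direction=direction,
            carriers=dirs,
            genes=region_genes,
            driver=None,
        ))

    # drivers: one per region, in the middle of the first n_planted_drivers regions
    drivers: List[str] = []
    for r in range(cfg.n_planted_drivers):
        drv = regions[r]["genes"][span // 2]
        regions[r]["driver"] = drv
        drivers.append(drv)

    if cfg.mycn_linked_region and cfg.n_planted_drivers >= 1:
        regions[0]["direction"] = "gain"
        regions[0]["carriers"] = {p: "gain" for p in regions[0]["carriers"]}

    region_gene_set = {g for reg in regions for g in reg["genes"]}

    # ---- network -------------------------------------------------------
    net_seed = int(rng.integers(2**31))
    target_pool = [g for g in gene_ids if g not in region_gene_set]
    network, driver_targets = generate_network(
        cfg.n_genes, cfg.network_attachment, planted_drivers=drivers,
        neighbor_fanout=cfg.neighbor_fanout, seed=net_seed,
        gene_ids=gene_ids, target_pool=target_pool)

    # ---- probe log-ratios ---------------------------------------------
    lr = rng.normal(0.0, cfg.probe_noise_sd, size=(len(probe_map), cfg.n_patients))
    pat_index = {p: i for i, p in enumerate(patients)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for reg in regions:
        gidx = np.array([gene_index[g] for g in reg["genes"]])
        pmask = np.isin(probe_gene, gidx)
        for p, d in reg["carriers"].items():
            shift = cfg.gain_shift if d == "gain" else cfg.loss_shift
            lr[pmask, pat_index[p]] += shift
    log_ratios = pd.DataFrame(lr, index=probe_map.index, columns=patients)

    # ---- expression ----------------------------------------------------
    meanlog = rng.normal(_MEANLOG_MEAN, _MEANLOG_SD, size=cfg.n_genes)
    log2e = meanlog[:, None] + rng.normal(0.0, _EXPR_NOISE_SD,
                                          size=(cfg.n_genes, cfg.n_patients))
    sw = _WITHIN_PATIENT_SD
    for reg in regions:
        drv = reg["driver"]
        for p, d in reg["carriers"].items():
            sign = 1.0 if d == "gain" else -1.0
            j = pat_index[p]
            if drv is not None:
                log2e[gene_index[drv], j] += sign * cfg.cis_effect * sw
                tidx = [gene_index[t] for t in driver_targets[drv]]
                log2e[tidx, j] += sign * cfg.trans_effect * sw
            if cfg.cis_effect_passenger:
                pidx = [gene_index[g] for g in reg["genes"] if g != drv]
                log2e[pidx, j] += sign * cfg.cis_effect_passenger * sw
    expression = pd.DataFrame(np.exp2(log2e), index=gene_ids, columns=patients)

    # ---- survival & clinical ------------------------------------------
    counts = {p: 0 for p in patients}
    for reg in regions:
        if reg["driver"] is not None:
            for p in reg["carriers"]:
                counts[p] += 1
    count_arr = np.array([counts[p] for p in patients], dtype=float)
    rate = cfg.baseline_hazard * np.exp(cfg.log_hr_per_driver * count_arr)
    event_time = rng.exponential(1.0 / rate)
    censored = rng.random(cfg.n_patients) < cfg.censor_rate
    os_days = np.where(censored, rng.uniform(0.0, event_time), event_time)
    os_days = np.maximum(os_days, 1.0)
    os_event = (~censored).astype(int)

    age_days = np.clip(rng.lognormal(math.log(450.0), 1.0, cfg.n_patients), 1, 9000)
    stage = rng.choice(_STAGES, size=cfg.n_patients, p=_STAGE_P)
    if cfg.mycn_linked_region and cfg.n_planted_drivers >= 1:
        mycn = np.array([1 if p in regions[0]["carriers"] else 0 for p in patients])
    else:
        mycn = (rng.random(cfg.n_patients) < 0.3).astype(int)
    clinical = pd.DataFrame({
        "os_days": np.round(os_days, 1),
        "os_event": os_event,
        "age_days": np.round(age_days).astype(int),
        "stage": stage,
        "mycn_amp": mycn,
        "high_risk": np.ones(cfg.n_patients, dtype=int),
    }, index=pd.Index(patients, name="patient"))

    mycn_locus = None
    if cfg.mycn_linked_region and cfg.n_planted_drivers >= 1:
        drv = regions[0]["driver"]
        mycn_locus = (genes.loc[drv, "chrom"],
                      int(genes.loc[drv, "start"]), int(genes.loc[drv, "end"]))

    truth = GroundTruth(
        planted_regions=[{k: v for k, v in reg.items()} for reg in regions],
        planted_drivers=drivers,
        driver_targets=driver_targets,
        per_patient_driver_count=counts,
        mycn_locus=mycn_locus,
    )
    return SyntheticCohort(
        gene_annotation=genes, probe_map=probe_map, log_ratios=log_ratios,
        expression=expression, network=network, clinical=clinical,
        truth=truth, config=cfg)
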