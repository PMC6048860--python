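"""Functional (FGS) and altered (AGS) gene-set construction.

FGS: genes inside recurrent CNA regions whose expression responds in the
direction of the alteration (one-sided Welch t-test, carriers vs
copy-neutral patients, raw P < 0.05 -- sensitivity is deliberately
prioritized at this stage; later filters add specificity).  The "common"
FGS additionally drops genes from regions carrying both gains and losses.

AGS: per patient, the genes whose cross-sample expression rank for that
patient is among the top 100 (up) or bottom 100 (down); the common AGS
collects genes recurrent in >= 5 patient AGS, optionally extended by a
literature gene list.  Expression is log2(FPKM+1)-transformed then centered
and variance-scaled within each patient before ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from dgscore.errors import InputError, InvalidConfigError
from dgscore.segmentation import CnaSegment, RecurrentRegion

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix", "GeneSet", "ConcordanceResult", "FgsResult",
    "preprocess_expression", "annotate_regions", "concordance_filter",
    "alteration_matrix", "build_fgs", "build_common_fgs",
    "build_patient_ags", "build_common_ags",
]


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # gene x patient, FPKM
    scaled: pd.DataFrame  # within-patient standardized log2(FPKM+1)
    ranks: pd.DataFrame  # per gene: rank of each patient across the cohort

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def patients(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneSet:
    genes: List[str]
    provenance: str  # fgs_full / fgs_common / ags_patient:<id> / ags_common / ...
    direction: Dict[str, str] = field(default_factory=dict)
    source: Dict[str, str] = field(default_factory=dict)  # per-gene origin notes

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in set(self.genes)


@dataclass
class ConcordanceResult:
    gene: str
    direction: str  # gain / loss
    t_statistic: float
    df: float
    p_one_sided: float
    kept: bool


def preprocess_expression(values: pd.DataFrame) -> ExpressionMatrix:
    """log2(FPKM+1), center and variance-scale within each patient, then rank.

    Ranks are per gene across patients (average ranks on ties), computed on
    the scaled values.
    """
    if values.shape[0] < 2:
        raise InputError("need at least 2 genes")
    if (values.to_numpy() < 0).any():
        raise InputError("FPKM values must be nonnegative")
    logv = np.log2(values.to_numpy(dtype=float) + 1.0)
    mu = logv.mean(axis=0, keepdims=True)
    sd = logv.std(axis=0, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = values.columns[np.flatnonzero(sd[0] == 0)]
        raise InputError(f"zero expression variance for patient(s) {list(bad)}")
    scaled = (logv - mu) / sd
    ranks = stats.rankdata(scaled, axis=1)
    return ExpressionMatrix(
        values=values,
        scaled=pd.DataFrame(scaled, index=values.index, columns=values.columns),
        ranks=pd.DataFrame(ranks, index=values.index, columns=values.columns),
    )


def annotate_regions(
    regions: Sequence[RecurrentRegion],
    gene_annotation: pd.DataFrame,
) -> List[List[str]]:
    """Genes overlapping each region by >= 1 bp (half-open intervals)."""
    out: List[List[str]] = []
    chrom = gene_annotation["chrom"].to_numpy()
    start = gene_annotation["start"].to_numpy()
    end = gene_annotation["end"].to_numpy()
    idx = gene_annotation.index.to_numpy()
    for reg in regions:
        m = (chrom == reg.chromosome) & (start < reg.end) & (end > reg.start)
        out.append(list(idx[m]))
    return out


def alteration_matrix(
    cnas_by_patient: Dict[str, Sequence[CnaSegment]],
    gene_annotation: pd.DataFrame,
    patients: Sequence[str],
) -> pd.DataFrame:
    """Gene x patient alteration states from each patient's filtered CNAs.

    Entries are ``gain``/``loss``/``""`` (copy-neutral).  A gene is altered
    in a patient iff one of that patient's CNAs overlaps the gene; on the
    rare overlap by both directions the larger overlap wins.
    """
    chrom = gene_annotation["chrom"].to_numpy()
    start = gene_annotation["start"].to_numpy()
    end = gene_annotation["end"].to_numpy()
    states = np.full((len(gene_annotation), len(patients)), "", dtype=object)
    best_ov = np.zeros((len(gene_annotation), len(patients)), dtype=int)
    for j, pat in enumerate(patients):
        for s in cnas_by_patient.get(pat, ()):  # filtered CNAs only
            m = (chrom == s.chromosome) & (start < s.end) & (end > s.start)
            if not m.any():
                continue
            ov = np.minimum(end[m], s.end) - np.maximum(start[m], s.start)
            rows = np.flatnonzero(m)
            take = ov > best_ov[rows, j]
            states[rows[take], j] = s.state
            best_ov[rows[take], j] = ov[take]
    return pd.DataFrame(states, index=gene_annotation.index, columns=list(patients))


def concordance_filter(
    gene: str,
    expr: ExpressionMatrix,
    carriers: Sequence[str],
    neutral: Sequence[str],
    direction: str,
    alpha: float = 0.05,
) -> Optional[ConcordanceResult]:
    """One-sided Welch t-test of dosage concordance on scaled expression.

    Alternative is carriers > neutral for gains, carriers < neutral for
    losses; the gene is kept iff p < alpha.  Returns None (gene dropped,
    logged) when either group has fewer than 2 patients.
    """
    if len(carriers) < 2 or len(neutral) < 2:
        log.debug("concordance undetermined for %s: group too small", gene)
        return None
    x = expr.scaled.loc[gene, list(carriers)].to_numpy(dtype=float)
    y = expr.scaled.loc[gene, list(neutral)].to_numpy(dtype=float)
    alternative = "greater" if direction == "gain" else "less"
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    if not np.isfinite(t):  # both groups constant and equal
        t, p = 0.0, 0.5
    return ConcordanceResult(gene=gene, direction=direction, t_statistic=t,
                             df=df, p_one_sided=p, kept=bool(p < alpha))


@dataclass
class FgsResult:
    """Full FGS plus the evidence behind it."""

    gene_set: GeneSet  # provenance fgs_full; direction(s) per gene
    concordance: List[ConcordanceResult]
    region_genes: List[List[str]]  # per region, annotated genes
    annotated_genes: List[str]  # union over regions
    alterations: pd.DataFrame  # gene x patient states for annotated genes

    def altered_genes_of(self, patient: str) -> Set[str]:
        col = self.alterations[patient]
        return set(col.index[col != ""])


def build_fgs(
    regions: Sequence[RecurrentRegion],
    region_genes: Sequence[List[str]],
    expr: ExpressionMatrix,
    cnas_by_patient: Dict[str, Sequence[CnaSegment]],
    gene_annotation: pd.DataFrame,
    patients: Sequence[str],
    alpha: float = 0.05,
) -> FgsResult:
    """All annotated recurrent-region genes passing the concordance filter.

    A gene lying in several regions is kept if concordant in at least one;
    both directions are tested where both kinds of carriers exist.
    """
    annotated = sorted({g for gl in region_genes for g in gl})
    ann = gene_annotation.loc[annotated]
    alter = alteration_matrix(cnas_by_patient, ann, patients)
    expr_genes = set(expr.genes)

    results: List[ConcordanceResult] = []
    kept: Dict[str, Set[str]] = {}
    for g in annotated:
        if g not in expr_genes:
            log.debug("gene %s absent from expression matrix; skipped", g)
            continue
        row = alter.loc[g]
        neutral = list(row.index[row == ""])
        for direction in ("gain", "loss"):
            carriers = list(row.index[row == direction])
            if not carriers:
                continue
            res = concordance_filter(g, expr, carriers, neutral, direction, alpha)
            if res is None:
                continue
            results.append(res)
            if res.kept:
                kept.setdefault(g, set()).add(direction)

    genes = sorted(kept)
    direction = {g: "/".join(sorted(kept[g])) for g in genes}
    gs = GeneSet(genes=genes, provenance="fgs_full", direction=direction)
    return FgsResult(gene_set=gs, concordance=results,
                     region_genes=[list(gl) for gl in region_genes],
                     annotated_genes=annotated, alterations=alter)


def build_common_fgs(
    fgs: FgsResult,
    regions: Sequence[RecurrentRegion],
) -> GeneSet:
    """FGS genes whose every containing region is direction-pure."""
    pure = []
    for reg in regions:
        dirs = set(reg.carriers.values())
        pure.append(dirs <= {"gain"} or dirs <= {"loss"})
    genes = []
    for g in fgs.gene_set.genes:
        containing = [i for i, gl in enumerate(fgs.region_genes) if g in gl]
        if containing and all(pure[i] for i in containing):
            genes.append(g)
    direction = {g: fgs.gene_set.direction[g] for g in genes}
    return GeneSet(genes=genes, provenance="fgs_common", direction=direction)


def build_patient_ags(
    expr: ExpressionMatrix,
    patient: str,
    top_n: int = 100,
) -> GeneSet:
    """Top ``top_n`` up plus ``top_n`` down genes by this patient's rank.

    Ties at the rank cutoff are broken by |scaled expression| (larger
    first), then lexicographic gene id, making the set deterministic.
    """
    n_genes = len(expr.genes)
    if n_genes < 2 * top_n:
        raise InvalidConfigError(
            f"need >= {2 * top_n} genes for top_n={top_n}, have {n_genes}")
    r = expr.ranks[patient].to_numpy(dtype=float)
    mag = np.abs(expr.scaled[patient].to_numpy(dtype=float))
    ids = expr.genes.to_numpy()
    lex = np.lexsort((ids, -mag, -r))  # primary: rank desc
    up = list(ids[lex[:top_n]])
    lex_lo = np.lexsort((ids, -mag, r))  # primary: rank asc
    down = list(ids[lex_lo[:top_n]])
    direction = {g: "up" for g in up}
    direction.update({g: "down" for g in down})
    return GeneSet(genes=up + down, provenance=f"ags_patient:{patient}",
                   direction=direction)


def build_common_ags(
    patient_ags: Dict[str, GeneSet],
    min_recurrence: int = 5,
    literature_genes: Optional[Iterable[str]] = None,
    universe: Optional[Set[str]] = None,
) -> GeneSet:
    """Genes recurrent in >= ``min_recurrence`` patient AGS, plus literature.

    Literature genes are kept only when present in ``universe`` (the
    network/expression gene space) if one is given; each member's
    provenance (expression / literature / both) is recorded.
    """
    counts: Dict[str, int] = {}
    for gs in patient_ags.values():
        for g in set(gs.genes):
            counts[g] = counts.get(g, 0) + 1
    from_expr = {g for g, c in counts.items() if c >= min_recurrence}
    lit = set(literature_genes or ())
    if not lit and literature_genes is not None:
        log.warning("empty literature gene list; using expression-derived AGS only")
    if universe is not None:
        dropped = lit - universe
        if dropped:
            log.info("%d literature genes outside the gene universe dropped: %s",
                     len(dropped), sorted(dropped)[:10])
        lit &= universe
    genes = sorted(from_expr | lit)
    source = {}
    for g in genes:
        tags = []
        if g in from_expr:
            tags.append("expression")
        if g in lit:
            tags.append("literature")
        source[g] = "+".join(tags)
    return GeneSet(genes=genes, provenance="ags_common", source=source)
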