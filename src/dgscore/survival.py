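"""DGscore computation and clinical validation.

The driver-gene score of a patient is the number of called driver genes the
patient actually carries as a (filtered) copy-number alteration: common
drivers count in every patient whose CNAs cover them, patient-specific
drivers only in their own patient.  Patients are split at the cohort median
(strictly greater than the median = high), and the split is validated by
Kaplan-Meier curves with a log-rank test and by Cox proportional-hazards
models mirroring the standard univariate/adjusted model battery
(DGscore, tumor stage 4/4S vs 1-3, MYCN amplification, age in days, and
their combinations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from dgscore.errors import DegenerateSplitError, InputError
from dgscore.nea import DriverCall

log = logging.getLogger(__name__)

__all__ = [
    "PatientScore", "CoxResult", "compute_dgscore", "median_split",
    "km_logrank", "cox_models", "single_gene_split", "COX_MODEL_SPECS",
]


@dataclass
class PatientScore:
    patient: str
    dgscore: int
    contributing_drivers: List[str]
    group: str = ""  # high / low, set by median_split


@dataclass
class CoxResult:
    model_id: str
    terms: List[Tuple[str, float, float]]  # (variable, hazard_ratio, wald_p)
    converged: bool = True
    note: str = ""


def compute_dgscore(
    drivers: Sequence[DriverCall],
    altered_genes_by_patient: Dict[str, Set[str]],
    patients: Sequence[str],
    mode: str = "all",
    fgs_genes: Optional[Sequence[str]] = None,
) -> List[PatientScore]:
    """Per-patient driver burden under one of four scoring modes.

    The called drivers (common plus patient-specific) form one pooled gene
    list; a patient's score is the number of listed genes the patient
    carries as a filtered CNA -- the driver-gene count "with CNAs in each
    patient".  ``common_only`` and ``patient_specific_only`` restrict the
    pooled list to one source; ``raw_fgs`` counts every FGS gene altered in
    the patient with no network filter (requires ``fgs_genes``).  A
    patient's own specific drivers are always credited (they are altered in
    that patient by construction).
    """
    known = set(patients)
    common = sorted({d.gene for d in drivers if d.scope == "common"})
    specific: Dict[str, Set[str]] = {}
    for d in drivers:
        if d.scope.startswith("patient:"):
            pat = d.scope.split(":", 1)[1]
            if pat not in known:
                raise InputError(f"driver call for unknown patient {pat!r}")
            specific.setdefault(pat, set()).add(d.gene)

    all_specific = set().union(*specific.values()) if specific else set()
    scores = []
    for pat in patients:
        altered = altered_genes_by_patient.get(pat, set())
        if mode == "all":
            contrib = (((set(common) | all_specific) & altered)
                       | specific.get(pat, set()))
        elif mode == "common_only":
            contrib = set(common) & altered
        elif mode == "patient_specific_only":
            contrib = (all_specific & altered) | specific.get(pat, set())
        elif mode == "raw_fgs":
            if fgs_genes is None:
                raise InputError("raw_fgs mode requires fgs_genes")
            contrib = set(fgs_genes) & altered
        else:
            raise InputError(f"unknown DGscore mode {mode!r}")
        scores.append(PatientScore(patient=pat, dgscore=len(contrib),
                                   contributing_drivers=sorted(contrib)))
    return scores


def median_split(scores: Sequence[PatientScore]) -> List[PatientScore]:
    """High = strictly greater than the cohort median; ties go low."""
    if len(scores) < 2:
        raise InputError("need at least 2 patients for a median split")
    med = float(np.median([s.dgscore for s in scores]))
    for s in scores:
        s.group = "high" if s.dgscore > med else "low"
    groups = {s.group for s in scores}
    if groups != {"high", "low"}:
        raise DegenerateSplitError(
            f"median split degenerate (median={med}); only group(s) {groups}")
    return list(scores)


def km_logrank(
    groups: Dict[str, Sequence[str]],
    clinical: pd.DataFrame,
) -> dict:
    """Kaplan-Meier estimates per group and the two-group log-rank p.

    ``groups`` maps label -> patient ids; every patient must appear in the
    clinical table (os_days, os_event).
    """
    if len(groups) != 2:
        raise InputError("log-rank comparison needs exactly 2 groups")
    (la, pa), (lb, pb) = sorted(groups.items())
    missing = (set(pa) | set(pb)) - set(clinical.index)
    if missing:
        raise InputError(f"patients missing from clinical table: {sorted(missing)[:5]}")
    fits = {}
    for label, pats in ((la, pa), (lb, pb)):
        sub = clinical.loc[list(pats)]
        if sub["os_event"].sum() == 0:
            log.warning("group %s has zero events", label)
        kmf = KaplanMeierFitter(label=label)
        kmf.fit(sub["os_days"], sub["os_event"])
        fits[label] = kmf
    a, b = clinical.loc[list(pa)], clinical.loc[list(pb)]
    res = logrank_test(a["os_days"], b["os_days"],
                       event_observed_A=a["os_event"], event_observed_B=b["os_event"])
    return {"km": fits, "logrank_p": float(res.p_value),
            "logrank_statistic": float(res.test_statistic),
            "n": {la: len(pa), lb: len(pb)}}


# model_id -> covariate columns; dg = DGscore group (or count), stage4 = stage 4/4S
COX_MODEL_SPECS: List[Tuple[str, List[str]]] = [
    ("1a", ["dg"]),
    ("1b", ["stage4"]),
    ("1c", ["mycn_amp"]),
    ("1d", ["age_days"]),
    ("2", ["dg", "stage4"]),
    ("3", ["dg", "mycn_amp"]),
    ("4", ["dg", "age_days"]),
    ("5", ["age_days", "mycn_amp", "stage4"]),
    ("6", ["dg", "age_days", "mycn_amp", "stage4"]),
]

_TERM_NAMES = {"dg": "DGscore", "stage4": "Tumor stage",
               "mycn_amp": "MYCN amplification", "age_days": "Age"}


def cox_models(
    scores: Sequence[PatientScore],
    clinical: pd.DataFrame,
    dg_continuous: bool = False,
) -> List[CoxResult]:
    """The univariate/adjusted Cox proportional-hazards model battery.

    DGscore enters as the binary high/low group indicator by default
    (continuous count optional), tumor stage as 4/4S vs 1-3, MYCN with
    non-amplified as reference, age continuous in days.  Hazard ratios and
    Wald p-values are reported per term; non-convergent or non-identifiable
    models are flagged and the rest continue.
    """
    pats = [s.patient for s in scores]
    missing = set(pats) - set(clinical.index)
    if missing:
        raise InputError(f"patients missing from clinical table: {sorted(missing)[:5]}")
    cl = clinical.loc[pats]
    df = pd.DataFrame({
        "os_days": cl["os_days"].astype(float),
        "os_event": cl["os_event"].astype(int),
        "dg": ([float(s.dgscore) for s in scores] if dg_continuous
               else [1.0 if s.group == "high" else 0.0 for s in scores]),
        "stage4": cl["stage"].astype(str).isin(["4", "4S"]).astype(float),
        "mycn_amp": cl["mycn_amp"].astype(float),
        "age_days": cl["age_days"].astype(float),
    }, index=pats)

    out: List[CoxResult] = []
    for model_id, cols in COX_MODEL_SPECS:
        const = [c for c in cols if df[c].nunique() <= 1]
        if const:
            out.append(CoxResult(model_id=model_id, terms=[], converged=False,
                                 note=f"non-identifiable: constant {const}"))
            continue
        cph = CoxPHFitter()
        try:
            cph.fit(df[["os_days", "os_event"] + cols],
                    duration_col="os_days", event_col="os_event")
        except Exception as e:  # convergence failure: report, continue
            out.append(CoxResult(model_id=model_id, terms=[], converged=False,
                                 note=f"fit failed: {e}"))
            continue
        terms = [(_TERM_NAMES.get(c, c),
                  float(np.exp(cph.params_[c])), float(cph.summary.loc[c, "p"]))
                 for c in cols]
        out.append(CoxResult(model_id=model_id, terms=terms))
    return out


def single_gene_split(
    expr_scaled: pd.DataFrame,
    gene: str,
    clinical: pd.DataFrame,
    patients: Optional[Sequence[str]] = None,
) -> dict:
    """Median split on one gene's expression, then KM/log-rank.

    Comparator analysis for a single-marker stratification (e.g. TERT):
    high = expression strictly above the cohort median.
    """
    if gene not in expr_scaled.index:
        raise InputError(f"gene {gene!r} absent from expression matrix")
    pats = list(patients) if patients is not None else list(expr_scaled.columns)
    vals = expr_scaled.loc[gene, pats].astype(float)
    med = float(vals.median())
    hi = [p for p in pats if vals[p] > med]
    lo = [p for p in pats if vals[p] <= med]
    if not hi or not lo:
        raise DegenerateSplitError(f"expression split degenerate for {gene}")
    return km_logrank({"high": hi, "low": lo}, clinical)
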