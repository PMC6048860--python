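"""Per-patient CNA calling and cross-patient recurrent-region detection.

Segmentation is a penalized least-squares changepoint search (PELT-style
pruned dynamic programming) on each chromosome's ordered probe log2-ratios.
Downstream thresholds are the published ones: segments with mean log2-ratio
>= +0.15 are gains and <= -0.15 losses; called CNAs must have FDR-adjusted
significance <= 1e-05, length >= 1 kb and >= 10 probes; a region is
recurrent when altered (either direction) in at least 10% of patients
(ceil rule, e.g. 48 patients -> 5 carriers).

Per-segment significance: z = mean * sqrt(n_probes) / s_hat with the robust
noise scale s_hat = 1.4826 * median|successive difference| / sqrt(2),
two-sided normal p, Benjamini-Hochberg adjusted within each patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from dgscore.errors import InputError

__all__ = [
    "SegmentationParams", "CnaSegment", "RecurrentRegion",
    "segment_profile", "filter_segments", "detect_recurrent_regions",
    "detect_label_reversal", "robust_noise_sd", "pelt",
]


@dataclass
class SegmentationParams:
    gain_threshold: float = 0.15
    loss_threshold: float = -0.15
    max_fdr: float = 1e-05
    min_length_bp: int = 1000
    min_probes: int = 10
    recurrence_fraction: float = 0.10
    penalty: float = 3.0  # lambda = penalty * sigma^2 * log(n)


@dataclass
class CnaSegment:
    patient: str
    chromosome: str
    start: int  # 0-based half-open basepair interval
    end: int
    n_probes: int
    mean_lr: float
    state: str  # gain / loss / neutral
    q_value: float = float("nan")
    p_value: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RecurrentRegion:
    chromosome: str
    start: int
    end: int
    carriers: Dict[str, str]  # patient -> direction (gain/loss)

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def robust_noise_sd(values_by_chrom: Sequence[np.ndarray]) -> float:
    """Noise scale from successive probe differences, robust to true jumps."""
    parts = [np.abs(np.diff(v)) for v in values_by_chrom if len(v) > 1]
    if not parts:
        return float("nan")
    diffs = np.concatenate(parts)
    s = 1.4826 * float(np.median(diffs)) / math.sqrt(2.0)
    # floor keeps the changepoint penalty above float rounding noise on
    # (near-)noiseless profiles
    rms = math.sqrt(float(np.mean(np.concatenate(values_by_chrom) ** 2)))
    return max(s, 1e-5 * (1.0 + rms))


def _pelt_kernel(y: np.ndarray, penalty: float) -> np.ndarray:
    n = y.shape[0]
    s1 = np.zeros(n + 1)
    s2 = np.zeros(n + 1)
    for i in range(n):
        s1[i + 1] = s1[i] + y[i]
        s2[i + 1] = s2[i] + y[i] * y[i]
    f = np.empty(n + 1)
    f[0] = -penalty
    prev = np.zeros(n + 1, np.int64)
    cands = np.empty(n + 1, np.int64)
    costs = np.empty(n + 1)
    cands[0] = 0
    m = 1
    for t in range(1, n + 1):
        best = np.inf
        best_s = 0
        for i in range(m):
            s = cands[i]
            d = s1[t] - s1[s]
            c = (s2[t] - s2[s]) - d * d / (t - s)
            costs[i] = c
            if f[s] + c < best:
                best = f[s] + c
                best_s = s
        f[t] = best + penalty
        prev[t] = best_s
        # prune: s cannot be optimal for any t' > t if f[s] + cost > f[t]
        k = 0
        for i in range(m):
            if f[cands[i]] + costs[i] <= f[t]:
                cands[k] = cands[i]
                k += 1
        cands[k] = t
        m = k + 1
    out = np.empty(n, np.int64)
    j = 0
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            out[j] = s
            j += 1
        t = s
    return out[:j][::-1].copy()


try:  # the JIT makes the O(n * candidates) recursion cheap on long profiles
    from numba import njit

    _pelt_kernel = njit(cache=True)(_pelt_kernel)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def pelt(y: np.ndarray, penalty: float) -> List[int]:
    """Optimal mean-shift changepoints by penalized least squares.

    Returns interior changepoint indices (segment boundaries) for the cost
    sum_i (y_i - mean_seg)^2 + penalty per segment, found exactly via the
    pruned-exact-linear-time recursion.
    """
    n = len(y)
    if n < 2:
        return []
    return [int(c) for c in _pelt_kernel(np.ascontiguousarray(y, dtype=np.float64),
                                         float(penalty))]


def segment_profile(
    probe_map: pd.DataFrame,
    log_ratios: np.ndarray | pd.Series,
    params: SegmentationParams = SegmentationParams(),
    patient: str = "",
) -> List[CnaSegment]:
    """Segment one patient's probe profile into mean-constant pieces.

    ``probe_map`` must be sorted by (chrom, pos); ``log_ratios`` is aligned
    with its rows.  Segments partition each chromosome's probes; each
    carries its mean, a state from the gain/loss thresholds, and a BH
    q-value from the robust per-patient noise model.
    """
    values = np.asarray(log_ratios, dtype=float)
    if len(values) != len(probe_map):
        raise InputError("log_ratios length does not match probe map")
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite log-ratio values")

    chroms = probe_map["chrom"].to_numpy()
    pos = probe_map["pos"].to_numpy()
    # chromosome blocks in file order
    blocks: List[Tuple[str, np.ndarray, np.ndarray]] = []
    for c in pd.unique(chroms):
        m = chroms == c
        p = pos[m]
        if np.any(np.diff(p) < 0):
            raise InputError(f"probes not sorted by position on {c}")
        blocks.append((c, p, values[m]))

    sigma = robust_noise_sd([v for _, _, v in blocks])
    segments: List[CnaSegment] = []
    for c, p, v in blocks:
        n = len(v)
        if n < 2:
            # nothing to segment or call on a 1-probe chromosome
            segments.append(CnaSegment(
                patient=patient, chromosome=c, start=int(p[0]), end=int(p[0]) + 1,
                n_probes=n, mean_lr=float(v.mean()), state="neutral",
                p_value=1.0))
            continue
        lam = params.penalty * sigma * sigma * math.log(n)
        cps = pelt(v, lam)
        bounds = [0] + cps + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            mean = float(np.mean(v[a:b]))
            if mean >= params.gain_threshold:
                state = "gain"
            elif mean <= params.loss_threshold:
                state = "loss"
            else:
                state = "neutral"
            z = mean * math.sqrt(b - a) / sigma
            pval = 2.0 * stats.norm.sf(abs(z))
            segments.append(CnaSegment(
                patient=patient, chromosome=c,
                start=int(p[a]), end=int(p[b - 1]) + 1,
                n_probes=b - a, mean_lr=mean, state=state, p_value=pval))
    if segments:
        qs = stats.false_discovery_control([s.p_value for s in segments], method="bh")
        for s, q in zip(segments, qs):
            s.q_value = float(q)
    return segments


def filter_segments(
    segments: Sequence[CnaSegment],
    params: SegmentationParams = SegmentationParams(),
) -> List[CnaSegment]:
    """Keep only called CNAs: non-neutral, q <= max_fdr, >= 1 kb, >= 10 probes."""
    return [
        s for s in segments
        if s.state != "neutral"
        and s.q_value <= params.max_fdr
        and s.length >= params.min_length_bp
        and s.n_probes >= params.min_probes
    ]


def recurrence_threshold(n_patients: int, fraction: float) -> int:
    """Minimum carrier count for recurrence (ceil rule: 48 x 0.10 -> 5)."""
    return max(1, math.ceil(fraction * n_patients))


def detect_recurrent_regions(
    cnas_by_patient: Dict[str, Sequence[CnaSegment]],
    n_patients: int,
    probe_map: pd.DataFrame,
    recurrence_fraction: float = 0.10,
) -> List[RecurrentRegion]:
    """Maximal probe runs altered in >= ceil(fraction * n_patients) patients.

    Counting is probe-resolution and direction-agnostic; each carrier's
    direction in a region is the state of its largest-overlapping CNA.
    """
    thr = recurrence_threshold(n_patients, recurrence_fraction)
    regions: List[RecurrentRegion] = []
    chroms = probe_map["chrom"].to_numpy()
    for c in pd.unique(chroms):
        p = probe_map["pos"].to_numpy()[chroms == c]
        counts = np.zeros(len(p), dtype=int)
        per_patient: Dict[str, List[CnaSegment]] = {}
        for pat, segs in cnas_by_patient.items():
            segs_c = [s for s in segs if s.chromosome == c]
            if not segs_c:
                continue
            per_patient[pat] = segs_c
            covered = np.zeros(len(p), dtype=bool)
            for s in segs_c:
                covered |= (p >= s.start) & (p < s.end)
            counts += covered
        above = counts >= thr
        if not above.any():
            continue
        # maximal runs of probes above threshold
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            start, end = int(p[i0]), int(p[i1 - 1]) + 1
            carriers: Dict[str, str] = {}
            for pat, segs_c in per_patient.items():
                best, best_ov = None, 0
                for s in segs_c:
                    ov = min(s.end, end) - max(s.start, start)
                    if ov > best_ov:
                        best, best_ov = s, ov
                if best is not None:
                    carriers[pat] = best.state
            regions.append(RecurrentRegion(chromosome=c, start=start, end=end,
                                           carriers=carriers))
    return regions


def detect_label_reversal(
    probe_map: pd.DataFrame,
    log_ratios: np.ndarray | pd.Series,
    mycn_amplified: bool,
    mycn_locus: Tuple[str, int, int],
    loss_threshold: float = -0.15,
    min_probes: int = 10,
) -> Tuple[str, float]:
    """Tumor/normal label-reversal QC against the MYCN locus.

    A patient recorded as MYCN-amplified whose aCGH shows a *loss* over the
    MYCN locus has most likely had tumor and reference channels swapped.
    Returns (status, evidence) with status one of ``flagged``,
    ``not_flagged``, ``undetermined`` (locus insufficiently covered);
    evidence is -mean log2-ratio over the locus (positive when flagged).
    """
    chrom, start, end = mycn_locus
    values = np.asarray(log_ratios, dtype=float)
    m = ((probe_map["chrom"].to_numpy() == chrom)
         & (probe_map["pos"].to_numpy() >= start)
         & (probe_map["pos"].to_numpy() < end))
    if m.sum() < min_probes:
        return "undetermined", float("nan")
    mean = float(values[m].mean())
    if mycn_amplified and mean <= loss_threshold:
        return "flagged", -mean
    return "not_flagged", -mean
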