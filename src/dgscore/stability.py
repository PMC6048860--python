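"""Bootstrap stability of common-driver detection with an exact binomial null.

Patients are resampled with replacement B times (default 50); the full
common-driver pipeline (recurrence -> FGS -> AGS -> NEA) is rerun on each
replicate and the number of times each gene is selected is tallied.  Under
the null of no driver structure, a gene's selection count is Binomial(B, p)
with p the per-trial selection probability (observed common drivers divided
by annotated genes, unless overridden); the reported p-value is the exact
upper tail P(X >= x), accumulated in log space so values around 1e-54
remain accurate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from dgscore.errors import InputError, InvalidConfigError

log = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "binomial_tail_pvalue", "bootstrap_common_drivers"]


@dataclass
class BootstrapResult:
    B: int
    selection_count: Dict[str, int]
    p_null: float
    proportion: Dict[str, float] = field(default_factory=dict)
    p_value: Dict[str, float] = field(default_factory=dict)

    def finalize(self) -> "BootstrapResult":
        self.proportion = {g: x / self.B for g, x in self.selection_count.items()}
        if 0 < self.p_null < 1:
            self.p_value = {g: binomial_tail_pvalue(x, self.B, self.p_null)
                            for g, x in self.selection_count.items()}
        else:  # degenerate null (e.g. no drivers observed): tail undefined
            self.p_value = {g: float("nan") for g in self.selection_count}
        return self


def binomial_tail_pvalue(x: int, n: int, p: float) -> float:
    """Exact upper-tail binomial probability P(X >= x), X ~ Binomial(n, p).

    Computed as a log-space sum of C(n,j) p^j (1-p)^(n-j) over j = x..n,
    exact to double precision even deep in the tail.
    """
    if not (0 <= x <= n):
        raise InputError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not (0 < p < 1):
        raise InputError(f"need 0 < p < 1, got p={p}")
    if x == 0:
        return 1.0
    j = np.arange(x, n + 1)
    logpmf = (gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
              + j * np.log(p) + (n - j) * np.log1p(-p))
    return float(np.exp(logsumexp(logpmf)))


def bootstrap_common_drivers(
    run_common_drivers: Callable[[Sequence[str]], Sequence[str]],
    patients: Sequence[str],
    B: int = 50,
    seed: int = 0,
    p_null: Optional[float] = None,
    observed_drivers: Optional[Sequence[str]] = None,
    n_annotated_genes: Optional[int] = None,
) -> BootstrapResult:
    """Resample patients with replacement and tally common-driver selections.

    ``run_common_drivers`` maps a patient multiset (a resampled cohort, with
    duplicates) to the list of common drivers called on it -- the caller
    supplies the pipeline closure so per-patient segmentation can be cached
    across replicates.  ``p_null`` defaults to
    len(observed_drivers) / n_annotated_genes.  Replicate seeds are derived
    from ``seed`` by fixed increments.
    """
    if B < 1:
        raise InvalidConfigError("B must be >= 1")
    if p_null is None:
        if observed_drivers is None or not n_annotated_genes:
            raise InvalidConfigError(
                "p_null not given and observed_drivers/n_annotated_genes missing")
        p_null = len(observed_drivers) / n_annotated_genes
    counts: Dict[str, int] = {}
    pats = list(patients)
    for b in range(B):
        rng = np.random.default_rng(seed + b)
        resample = list(rng.choice(pats, size=len(pats), replace=True))
        for g in set(run_common_drivers(resample)):
            counts[g] = counts.get(g, 0) + 1
    return BootstrapResult(B=B, selection_count=counts, p_null=float(p_null)).finalize()
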