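"""Network enrichment analysis (NEA) driver calling.

Each candidate (FGS) gene is scored by the over-representation of its direct
network links to an altered gene set (AGS):

    z = (d_AF - mu_AF) / sigma_AF

where d_AF is the observed number of AGS members adjacent to the candidate
and mu_AF, sigma_AF are the null mean and standard deviation.  The default
null is exact hypergeometric over AGS placements: conditioning on the
candidate's degree k, the a AGS members are a uniform draw from the N-1
other nodes, so d_AF ~ Hypergeom(N-1, k, a).  Degree-aware alternatives are
provided: an analytic degree-product (Poisson-like) null with
mu = k * D_AGS / (2m), and a Monte-Carlo degree-preserving edge-rewiring
null.  Candidates with z above the threshold (default 2) are called
putative drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from dgscore.errors import InputError, InvalidConfigError
from dgscore.gene_sets import GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork", "NeaResult", "DriverCall",
    "count_links", "nea_zscore", "call_common_drivers", "call_patient_drivers",
]


class InteractionNetwork:
    """Undirected simple graph over gene ids (no self-loops, no duplicates)."""

    def __init__(self, edges: Iterable[Tuple[str, str]]):
        self.adj: Dict[str, Set[str]] = {}
        n_self = n_dup = 0
        for u, v in edges:
            if u == v:
                n_self += 1
                continue
            if v in self.adj.get(u, ()):  # already present (either orientation)
                n_dup += 1
                continue
            self.adj.setdefault(u, set()).add(v)
            self.adj.setdefault(v, set()).add(u)
        if n_self or n_dup:
            log.warning("network cleanup: dropped %d self-loops, %d duplicate edges",
                        n_self, n_dup)
        self.n_dropped_self = n_self
        self.n_dropped_dup = n_dup

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionNetwork":
        return cls(g.edges())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.adj)
        g.add_edges_from(self.edges())
        return g

    def edges(self) -> Iterable[Tuple[str, str]]:
        for u, nb in self.adj.items():
            for v in nb:
                if u < v:
                    yield (u, v)

    @property
    def nodes(self) -> Set[str]:
        return set(self.adj)

    def __contains__(self, g: str) -> bool:
        return g in self.adj

    def __len__(self) -> int:
        return len(self.adj)

    def degree(self, g: str) -> int:
        return len(self.adj.get(g, ()))

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.adj.values()) // 2

    def neighbors(self, g: str) -> Set[str]:
        return self.adj.get(g, set())


@dataclass
class NeaResult:
    candidate: str
    ags_size: int  # a (candidate excluded, restricted to network nodes)
    k: int  # candidate degree
    d_af: int  # observed candidate-AGS links
    mu_af: float
    sigma_af: float
    z: float
    null_kind: str


@dataclass
class DriverCall:
    gene: str
    scope: str  # "common" or "patient:<id>"
    z: float
    ags_used: str
    d_af: int = 0
    mu_af: float = float("nan")
    sigma_af: float = float("nan")
    null_kind: str = "hypergeometric"


def _ags_genes(ags: GeneSet | Iterable[str]) -> List[str]:
    return list(ags.genes) if isinstance(ags, GeneSet) else list(ags)


def count_links(candidate: str, ags: GeneSet | Iterable[str],
                network: InteractionNetwork) -> int:
    """Number of AGS members directly linked to the candidate.

    The candidate itself is excluded from the AGS before counting (a gene
    cannot provide enrichment evidence for itself).
    """
    if candidate not in network:
        raise InputError(f"candidate {candidate} absent from network")
    members = set(_ags_genes(ags)) - {candidate}
    return len(members & network.neighbors(candidate))


def nea_zscore(
    candidate: str,
    ags: GeneSet | Iterable[str],
    network: InteractionNetwork,
    null_kind: str = "hypergeometric",
    n_permutations: int = 1000,
    seed: int = 0,
) -> Optional[NeaResult]:
    """Standardized link enrichment of one candidate against one AGS.

    Returns None (gene skipped, logged) when the candidate is isolated or
    the null variance vanishes.
    """
    if candidate not in network:
        log.info("candidate %s not in network; skipped", candidate)
        return None
    members = (set(_ags_genes(ags)) - {candidate}) & network.nodes
    a = len(members)
    if a == 0:
        raise InvalidConfigError("AGS is empty (after restriction to the network)")
    n_nodes = len(network)
    if a >= n_nodes - 1:
        raise InvalidConfigError("AGS spans the whole network; null undefined")
    k = network.degree(candidate)
    d = len(members & network.neighbors(candidate))

    if null_kind == "hypergeometric":
        ne = n_nodes - 1  # eligible nodes for AGS membership
        frac = k / ne
        mu = a * frac
        var = a * frac * (1.0 - frac) * (ne - a) / (ne - 1)
        sigma = float(np.sqrt(var))
    elif null_kind == "degree_product":
        two_m = 2.0 * network.n_edges
        d_ags = sum(network.degree(g) for g in members)
        mu = k * d_ags / two_m
        sigma = float(np.sqrt(mu))
    elif null_kind == "edge_permutation":
        mu, sigma = _edge_permutation_null(candidate, members, network,
                                           n_permutations, seed)
    else:
        raise InvalidConfigError(f"unknown null kind {null_kind!r}")

    if sigma == 0 or not np.isfinite(sigma):
        log.info("sigma_AF = 0 for %s (k=%d); z undefined, gene skipped", candidate, k)
        return None
    z = (d - mu) / sigma
    return NeaResult(candidate=candidate, ags_size=a, k=k, d_af=d,
                     mu_af=float(mu), sigma_af=float(sigma), z=float(z),
                     null_kind=null_kind)


def _edge_permutation_null(
    candidate: str,
    members: Set[str],
    network: InteractionNetwork,
    n_permutations: int,
    seed: int,
) -> Tuple[float, float]:
    """Null moments of d_AF from degree-preserving edge rewires.

    A single double-edge-swap Markov chain is run, sampling d_AF every m
    swaps; per-candidate substreams are derived from the seed so results
    are reproducible and independent across genes.
    """
    import hashlib

    gene_key = int.from_bytes(hashlib.sha256(candidate.encode()).digest()[:4], "big")
    sub = np.random.SeedSequence(entropy=seed, spawn_key=(gene_key,))
    rng = np.random.default_rng(sub)
    g = network.to_networkx()
    m = g.number_of_edges()
    samples = np.empty(n_permutations)
    for i in range(n_permutations):
        nx.double_edge_swap(g, nswap=m, max_tries=20 * m,
                            seed=int(rng.integers(2**31)))
        samples[i] = len(members & set(g.neighbors(candidate)))
    return float(samples.mean()), float(samples.std(ddof=1))


def call_common_drivers(
    fgs_common: GeneSet,
    ags_common: GeneSet,
    network: InteractionNetwork,
    z_threshold: float = 2.0,
    null_kind: str = "hypergeometric",
    n_permutations: int = 1000,
    seed: int = 0,
) -> List[DriverCall]:
    """Score every common-FGS gene against the common AGS; call at z > threshold."""
    calls: List[DriverCall] = []
    ags_nodes = set(_ags_genes(ags_common)) & network.nodes
    if len(ags_nodes) >= len(network) - 1:
        log.warning("common AGS saturates the network (%d of %d nodes); "
                    "enrichment undefined, no common drivers called",
                    len(ags_nodes), len(network))
        return calls
    for g in fgs_common.genes:
        if g not in network:
            log.info("common candidate %s not in network; skipped", g)
            continue
        res = nea_zscore(g, ags_common, network, null_kind=null_kind,
                         n_permutations=n_permutations, seed=seed)
        if res is not None and res.z > z_threshold:
            calls.append(DriverCall(gene=g, scope="common", z=res.z,
                                    ags_used=ags_common.provenance,
                                    d_af=res.d_af, mu_af=res.mu_af,
                                    sigma_af=res.sigma_af, null_kind=res.null_kind))
    return calls


def call_patient_drivers(
    fgs_full,
    patient_ags: Dict[str, GeneSet],
    altered_genes_by_patient: Dict[str, Set[str]],
    network: InteractionNetwork,
    z_threshold: float = 2.0,
    null_kind: str = "hypergeometric",
    n_permutations: int = 1000,
    seed: int = 0,
) -> List[DriverCall]:
    """Per-patient NEA: candidates are the patient's own altered FGS genes,
    scored against that patient's AGS."""
    fgs_genes = set(fgs_full.genes if isinstance(fgs_full, GeneSet) else fgs_full)
    calls: List[DriverCall] = []
    for pat, ags in patient_ags.items():
        candidates = sorted(fgs_genes & altered_genes_by_patient.get(pat, set()))
        for g in candidates:
            if g not in network:
                continue
            res = nea_zscore(g, ags, network, null_kind=null_kind,
                             n_permutations=n_permutations, seed=seed)
            if res is not None and res.z > z_threshold:
                calls.append(DriverCall(gene=g, scope=f"patient:{pat}", z=res.z,
                                        ags_used=ags.provenance,
                                        d_af=res.d_af, mu_af=res.mu_af,
                                        sigma_af=res.sigma_af,
                                        null_kind=res.null_kind))
    return calls
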