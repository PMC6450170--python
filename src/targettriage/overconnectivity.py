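"""Interactome over-connectivity: per-gene hypergeometric excess of
network neighbors inside an experimental gene set.

For a focal gene with R neighbors in a background of N genes (focal gene
excluded from both), and an experimental set of n genes, the neighbor
count inside the set (Actual) is compared to Hypergeometric(N, R, n):
Expected = n*R/N, z = (Actual - Expected)/sd, p = P(X >= Actual).
Direction and effect signs are ignored for counting — both incoming and
outgoing interactions contribute — and self-loops never count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError
from .io import InteractionNetwork, canonical_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConnectivityResult:
    """One gene's over-connectivity record (Actual/n/R/N/Expected/Ratio/z/p)."""

    gene: str
    actual: int
    n: int
    R: int
    N: int
    expected: float
    ratio: float | None  # None when expected == 0
    z: float
    p: float


def connectivity_stats(network: InteractionNetwork, deg_set: set[str],
                       background: set[str], gene: str) -> ConnectivityResult:
    """Over-connectivity of ``gene`` to ``deg_set`` within ``background``.

    The focal gene is excluded from its own background, neighbor count
    and experimental set, so it never contributes to its own statistic.
    """
    gene = canonical_symbol(gene)
    background = {canonical_symbol(g) for g in background}
    deg_set = {canonical_symbol(g) for g in deg_set}
    if gene not in background:
        raise DomainError(f"focal gene {gene!r} not in background")
    if not background <= network.nodes:
        missing = sorted(background - network.nodes)
        raise DomainError(f"background genes absent from network: {missing[:5]}")
    unmapped = deg_set - background
    if unmapped:
        logger.warning("%d experimental gene(s) outside background dropped: %s%s",
                       len(unmapped), sorted(unmapped)[:5],
                       "..." if len(unmapped) > 5 else "")
        deg_set = deg_set & background

    pool = background - {gene}
    members = deg_set - {gene}
    neighbors = network.neighbors(gene) & pool
    N = len(pool)
    R = len(neighbors)
    n = len(members)
    actual = len(neighbors & members)

    if N == 0 or n == 0 or R == 0:
        expected = 0.0
        sd = 0.0
    else:
        expected = n * R / N
        sd = float(np.sqrt(n * (R / N) * (1 - R / N) * (N - n) / (N - 1))) if N > 1 else 0.0
    if sd == 0.0:
        z = 0.0 if actual == expected else float("inf") * np.sign(actual - expected)
    else:
        z = (actual - expected) / sd
    if n == 0 or N == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(actual - 1, N, R, n))
    ratio = actual / expected if expected > 0 else None
    return ConnectivityResult(gene=gene, actual=actual, n=n, R=R, N=N,
                              expected=expected, ratio=ratio, z=float(z), p=p)


def overconnected_genes(network: InteractionNetwork, deg_set: set[str],
                        background: set[str], p_max: float = 0.05,
                        candidates: set[str] | None = None
                        ) -> list[ConnectivityResult]:
    """Rank candidate genes by over-connectivity to the experimental set.

    Candidates default to the experimental set itself.  Results with
    p <= p_max are kept, sorted by z descending, ties by p ascending
    then symbol.
    """
    if candidates is None:
        candidates = {canonical_symbol(g) for g in deg_set} & {canonical_symbol(g) for g in background}
    results = [connectivity_stats(network, deg_set, background, g)
               for g in sorted(candidates)]
    kept = [r for r in results if r.p <= p_max]
    kept.sort(key=lambda r: (-r.z, r.p, r.gene))
    return kept


def expand_network(network: InteractionNetwork, seeds: set[str]) -> InteractionNetwork:
    """One-step expansion: induce the subnetwork on the seeds plus every
    node one directed interaction away, in either direction.  Seeds
    absent from the network are reported and skipped."""
    seeds = {canonical_symbol(s) for s in seeds}
    absent = seeds - network.nodes
    if absent:
        logger.warning("%d seed(s) absent from network skipped: %s%s",
                       len(absent), sorted(absent)[:5], "..." if len(absent) > 5 else "")
    seeds = seeds & network.nodes
    if not seeds:
        return InteractionNetwork()
    nodes = set(seeds)
    for s in seeds:
        nodes |= network.neighbors(s)
    return network.subnetwork(nodes)


def hub_rank(network: InteractionNetwork) -> list[tuple[str, int]]:
    """Nodes sorted by total degree (distinct partners, in + out,
    self-loops excluded) descending; ties alphabetical."""
    if not network.nodes:
        raise DomainError("empty network")
    ranked = [(g, network.degree(g)) for g in network.nodes]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


def write_connectivity(results: list[ConnectivityResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tActual\tn\tR\tN\tExpected\tRatio\tz\tp\n")
        for r in results:
            ratio = f"{r.ratio:.6g}" if r.ratio is not None else "NA"
            fh.write(f"{r.gene}\t{r.actual}\t{r.n}\t{r.R}\t{r.N}\t"
                     f"{r.expected:.6g}\t{ratio}\t{r.z:.6g}\t{r.p:.6g}\n")


def read_connectivity(path) -> list[ConnectivityResult]:
    results: list[ConnectivityResult] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields == [""]:
                continue
            gene, actual, n, R, N, expected, ratio, z, p = fields
            results.append(ConnectivityResult(
                gene=gene, actual=int(actual), n=int(n), R=int(R), N=int(N),
                expected=float(expected),
                ratio=None if ratio == "NA" else float(ratio),
                z=float(z), p=float(p)))
    return results
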