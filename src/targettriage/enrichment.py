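"""Gene-set over-representation with Benjamini-Hochberg adjustment.

One-sided hypergeometric test of a DEG list against each set of a
collection, conditioned on the platform universe: every set is
intersected with the universe before testing and DEGs outside the
universe are dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deg import DEGRecord, UP
from .errors import DomainError
from .io import GeneSetCollection, canonical_symbol

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    name: str
    overlap: set[str]
    k_up: int
    k_down: int
    p: float
    q: float


def enrich(deg_list: list[DEGRecord], collection: GeneSetCollection,
           universe: set[str]) -> list[EnrichmentResult]:
    """Test each gene set for over-representation of the DEG list.

    p = P(X >= |overlap|) with X ~ Hypergeometric(|universe|,
    |set & universe|, |degs & universe|); q is the BH-adjusted value
    across all tested sets.  Results are sorted by p ascending.
    """
    universe = {canonical_symbol(g) for g in universe}
    if not universe:
        raise DomainError("empty universe")
    directions = {r.gene: r.direction for r in deg_list}
    degs = set(directions)
    dropped = degs - universe
    if dropped:
        logger.warning("%d DEG(s) outside universe dropped: %s%s",
                       len(dropped), sorted(dropped)[:5],
                       "..." if len(dropped) > 5 else "")
    degs &= universe
    N = len(universe)
    n = len(degs)

    results: list[EnrichmentResult] = []
    for gs in collection:
        members = gs.members & universe
        overlap = members & degs
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, len(members), n)) if members else 1.0
        k_up = sum(1 for g in overlap if directions[g] == UP)
        results.append(EnrichmentResult(name=gs.name, overlap=overlap,
                                        k_up=k_up, k_down=k - k_up, p=p, q=1.0))
    if results:
        qvals = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.name))
    return results


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("set\tk_up\tk_down\tp\tq\toverlap\n")
        for r in results:
            fh.write(f"{r.name}\t{r.k_up}\t{r.k_down}\t{r.p:.6g}\t{r.q:.6g}\t"
                     f"{','.join(sorted(r.overlap))}\n")
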