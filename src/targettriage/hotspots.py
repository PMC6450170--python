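"""Chromosomal hot-spot scan: stretches of consecutive genes where DEGs
cluster beyond a hypergeometric null.

The null model draws the w genes of a stretch from the platform
universe of G genes containing K DEGs; the stretch p-value is the
hypergeometric upper tail P(X >= k).  Candidate stretches are restricted
to runs whose first and last genes are DEGs, which loses no significant
window: trimming non-DEG ends lowers w at fixed k and the tail is
monotone decreasing in w.  Overlapping or book-ended significant runs
merge into maximal hot spots.  Strand is ignored: both strands share one
positional order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError
from .io import GeneLocus, canonical_symbol

logger = logging.getLogger(__name__)


@dataclass
class GenomeLayout:
    """Per-chromosome positional gene order plus universe counts."""

    chromosomes: dict[str, list[GeneLocus]]
    G: int
    K: int
    deg_set: set[str]
    unmapped_degs: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class WindowStat:
    w: int
    k: int
    p: float


@dataclass
class HotSpot:
    """A maximal significant stretch of consecutive genes."""

    chromosome: str
    span: tuple[int, int]
    genes: list[str]
    deg_genes: set[str]
    w: int
    k: int
    p: float


def build_layout(loci: list[GeneLocus], deg_set: set[str]) -> GenomeLayout:
    """Sort loci per chromosome by (start, end, symbol) and count the
    universe.  DEG symbols absent from the map are reported, not dropped
    silently."""
    deg_set = {canonical_symbol(g) for g in deg_set}
    chromosomes: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        chromosomes.setdefault(loc.chromosome, []).append(loc)
    for chrom in chromosomes:
        chromosomes[chrom].sort(key=lambda l: (l.start, l.end, l.gene))
    mapped = {loc.gene for locs in chromosomes.values() for loc in locs}
    unmapped = deg_set - mapped
    if unmapped:
        logger.warning("%d DEG symbol(s) absent from the gene map: %s%s",
                       len(unmapped), sorted(unmapped)[:5],
                       "..." if len(unmapped) > 5 else "")
    return GenomeLayout(
        chromosomes=chromosomes,
        G=len(mapped),
        K=len(deg_set & mapped),
        deg_set=deg_set & mapped,
        unmapped_degs=unmapped,
    )


def window_pvalue(w: int, k: int, K: int, G: int) -> float:
    """Hypergeometric upper tail P(X >= k) for a w-gene window drawn
    from a universe of G genes containing K DEGs."""
    if not (0 <= k <= w <= G and k <= K <= G):
        raise DomainError(f"invalid window parameters w={w}, k={k}, K={K}, G={G}")
    return float(stats.hypergeom.sf(k - 1, G, K, w))


def scan_hotspots(layout: GenomeLayout, min_degs: int = 5,
                  p_max: float = 0.001) -> list[HotSpot]:
    """Scan every chromosome for significant DEG stretches.

    Evaluates every contiguous run of consecutive genes bounded by DEGs,
    keeps runs with k >= min_degs and window_pvalue <= p_max, and merges
    overlapping or book-ended significant runs into maximal hot spots
    reporting the minimum constituent window p.  Output is ordered by
    (chromosome, start).
    """
    if min_degs < 1 or not 0 < p_max <= 1:
        raise DomainError("min_degs must be >= 1 and p_max in (0, 1]")
    G, K = layout.G, layout.K
    hotspots: list[HotSpot] = []
    for chrom in sorted(layout.chromosomes):
        genes = layout.chromosomes[chrom]
        is_deg = np.array([g.gene in layout.deg_set for g in genes])
        deg_pos = np.flatnonzero(is_deg)
        if deg_pos.size < min_degs:
            continue
        # All (i, j) DEG-ordinal pairs with at least min_degs DEGs between.
        n_deg = deg_pos.size
        ii, jj = np.triu_indices(n_deg, k=min_degs - 1)
        w = deg_pos[jj] - deg_pos[ii] + 1
        k = jj - ii + 1
        p = stats.hypergeom.sf(k - 1, G, K, w)
        sig = p <= p_max
        if not sig.any():
            continue
        runs = sorted(
            (int(deg_pos[a]), int(deg_pos[b]), float(pv), int(wv), int(kv))
            for a, b, pv, wv, kv in zip(ii[sig], jj[sig], p[sig], w[sig], k[sig])
        )
        hotspots.extend(_merge_runs(chrom, genes, layout.deg_set, runs))
    hotspots.sort(key=lambda h: (h.chromosome, h.span[0]))
    return hotspots


def _merge_runs(chrom: str, genes: list[GeneLocus], deg_set: set[str],
                runs: list[tuple[int, int, float, int, int]]) -> list[HotSpot]:
    """Merge overlapping/book-ended index runs into maximal hot spots."""
    merged: list[HotSpot] = []
    cur_start, cur_end = runs[0][0], runs[0][1]
    cur_best = (runs[0][2], runs[0][3], runs[0][4])
    for start, end, p, w, k in itertools.chain(runs[1:], [(None,) * 5]):
        if start is not None and start <= cur_end + 1:
            cur_end = max(cur_end, end)
            if p < cur_best[0]:
                cur_best = (p, w, k)
            continue
        members = genes[cur_start:cur_end + 1]
        symbols = [g.gene for g in members]
        merged.append(HotSpot(
            chromosome=chrom,
            span=(members[0].start, members[-1].end),
            genes=symbols,
            deg_genes=set(symbols) & deg_set,
            w=cur_best[1], k=cur_best[2], p=cur_best[0],
        ))
        if start is not None:
            cur_start, cur_end = start, end
            cur_best = (p, w, k)
    return merged


def overlap_hotspots(hotspots_a: list[HotSpot], hotspots_b: list[HotSpot]
                     ) -> list[tuple[HotSpot, HotSpot, set[str]]]:
    """Pair hot spots whose spans intersect (>= 1 bp, half-open) on the
    same chromosome; shared genes are the intersection of their DEG
    members."""
    pairs: list[tuple[HotSpot, HotSpot, set[str]]] = []
    for ha in hotspots_a:
        for hb in hotspots_b:
            if ha.chromosome != hb.chromosome:
                continue
            if ha.span[0] < hb.span[1] and hb.span[0] < ha.span[1]:
                pairs.append((ha, hb, ha.deg_genes & hb.deg_genes))
    pairs.sort(key=lambda t: (t[0].chromosome, t[0].span[0], t[1].span[0]))
    return pairs


def permutation_hotspot_rate(G: int, K: int, chromosome_sizes: list[int],
                             min_degs: int, p_max: float, n_perm: int,
                             rng: np.random.Generator) -> float:
    """Estimate the expected hot-spot count per genome under uniform DEG
    placement (optional family-wise calibration aid; off by default in
    the scan)."""
    counts = []
    for _ in range(n_perm):
        layout = _random_layout(G, K, chromosome_sizes, rng)
        counts.append(len(scan_hotspots(layout, min_degs=min_degs, p_max=p_max)))
    return float(np.mean(counts))


def _random_layout(G: int, K: int, chromosome_sizes: list[int],
                   rng: np.random.Generator) -> GenomeLayout:
    if sum(chromosome_sizes) != G:
        raise DomainError("chromosome sizes must sum to G")
    deg_idx = set(rng.choice(G, size=K, replace=False).tolist())
    loci: list[GeneLocus] = []
    i = 0
    for c, size in enumerate(chromosome_sizes):
        for j in range(size):
            loci.append(GeneLocus(chromosome=f"chr{c + 1}", start=j * 10_000,
                                  end=j * 10_000 + 5_000, gene=f"G{i:05d}"))
            i += 1
    deg_set = {f"G{i:05d}" for i in deg_idx}
    return build_layout(loci, deg_set)


def write_hotspots(hotspots: list[HotSpot], path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\tw\tk\tp\tn_genes\tdeg_genes\n")
        for h in hotspots:
            fh.write(f"{h.chromosome}\t{h.span[0]}\t{h.span[1]}\t{h.w}\t{h.k}\t"
                     f"{h.p:.6g}\t{len(h.genes)}\t{','.join(sorted(h.deg_genes))}\n")


def read_hotspots(path) -> list[HotSpot]:
    hotspots: list[HotSpot] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields == [""]:
                continue
            chrom, start, end, w, k, p, _n, degs = fields
            deg_genes = set(degs.split(",")) if degs else set()
            hotspots.append(HotSpot(
                chromosome=chrom, span=(int(start), int(end)),
                genes=sorted(deg_genes), deg_genes=deg_genes,
                w=int(w), k=int(k), p=float(p)))
    return hotspots
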