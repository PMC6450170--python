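"""Multi-criterion druggable-target triage.

Each candidate gene receives a boolean profile over seven evidence
criteria — (a) DEG in both tissues, (b) qPCR direction concordant with
the array, (c) member of a significantly enriched set, (d)
over-connected against both tissue DEG sets, (e) hub of the expanded
subnetwork, (f) inside an overlapping cross-tissue hot spot, (g) at
least one drug link — and is ranked by criteria count, ties broken by
mean over-connectivity z then symbol.  Criteria whose evidence channel
is absent evaluate false and are flagged "not evaluated"; the
score-and-rank formalization of the checklist is this package's own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .crosscompare import OverlapReport
from .enrichment import EnrichmentResult
from .hotspots import HotSpot
from .io import ProteinAnnotation, canonical_symbol
from .overconnectivity import ConnectivityResult
from .qpcr import FoldChangeResult

logger = logging.getLogger(__name__)

CRITERIA = ("a", "b", "c", "d", "e", "f", "g")


@dataclass
class EvidenceBundle:
    """Everything score_candidates consumes, keyed by gene symbol.

    Any channel may be None, in which case its criterion is false for
    every gene and flagged as not evaluated.
    """

    overlap: OverlapReport | None = None
    qpcr: list[FoldChangeResult] | None = None
    enrichment: list[EnrichmentResult] | None = None
    connectivity_a: list[ConnectivityResult] | None = None
    connectivity_b: list[ConnectivityResult] | None = None
    hub_list: list[tuple[str, int]] | None = None
    hotspot_overlaps: list[tuple[HotSpot, HotSpot, set[str]]] | None = None
    annotations: ProteinAnnotation | None = None


@dataclass
class PriorityScore:
    gene: str
    criteria: dict[str, bool]
    score: int
    rank: int = 0
    not_evaluated: set[str] = field(default_factory=set)
    mean_z: float = 0.0


def score_candidates(evidence: EvidenceBundle,
                     candidates: set[str] | None = None,
                     q_max: float = 0.05, conn_p_max: float = 0.05,
                     hub_quantile: float = 0.9) -> list[PriorityScore]:
    """Score and rank candidate genes over the (a)-(g) criteria.

    Candidates default to the cross-tissue common DEG set.  Rank is by
    score descending, ties by larger mean over-connectivity z, then
    symbol.
    """
    if candidates is None:
        if evidence.overlap is None:
            raise ValueError("no candidates given and no overlap report to default to")
        candidates = set(evidence.overlap.common)
    candidates = {canonical_symbol(g) for g in candidates}

    not_evaluated: set[str] = set()
    common = evidence.overlap.common if evidence.overlap else set()
    if evidence.overlap is None:
        not_evaluated.add("a")

    qpcr_dir: dict[str, str] = {}
    if evidence.qpcr is None:
        not_evaluated.add("b")
    else:
        for r in evidence.qpcr:
            if np.isfinite(r.case_mean) and np.isfinite(r.control_mean):
                qpcr_dir[r.gene] = "UP" if r.case_mean >= r.control_mean else "DOWN"

    enriched_members: set[str] = set()
    if evidence.enrichment is None:
        not_evaluated.add("c")
    else:
        for er in evidence.enrichment:
            if er.q <= q_max:
                enriched_members |= er.overlap

    if evidence.connectivity_a is None or evidence.connectivity_b is None:
        not_evaluated.add("d")
        conn_a: dict[str, ConnectivityResult] = {}
        conn_b: dict[str, ConnectivityResult] = {}
    else:
        conn_a = {r.gene: r for r in evidence.connectivity_a}
        conn_b = {r.gene: r for r in evidence.connectivity_b}

    hub_set: set[str] = set()
    if evidence.hub_list is None:
        not_evaluated.add("e")
    elif evidence.hub_list:
        degrees = np.array([d for _g, d in evidence.hub_list], dtype=float)
        cutoff = float(np.quantile(degrees, hub_quantile))
        hub_set = {g for g, d in evidence.hub_list if d >= cutoff}

    hotspot_shared: set[str] = set()
    if evidence.hotspot_overlaps is None:
        not_evaluated.add("f")
    else:
        for _ha, _hb, shared in evidence.hotspot_overlaps:
            hotspot_shared |= shared

    if evidence.annotations is None:
        not_evaluated.add("g")

    scores: list[PriorityScore] = []
    for gene in sorted(candidates):
        array_dir = None
        if evidence.overlap is not None and gene in evidence.overlap.same_direction:
            array_dir = evidence.overlap.directions_a.get(gene)
        elif evidence.overlap is not None:
            # discordant or absent: fall back to whichever tissue has a call
            array_dir = (evidence.overlap.directions_b.get(gene)
                         or evidence.overlap.directions_a.get(gene))
        ann = evidence.annotations.get(gene) if evidence.annotations else None
        criteria = {
            "a": gene in common,
            "b": gene in qpcr_dir and array_dir is not None and qpcr_dir[gene] == array_dir,
            "c": gene in enriched_members,
            "d": (gene in conn_a and gene in conn_b
                  and conn_a[gene].p <= conn_p_max and conn_b[gene].p <= conn_p_max),
            "e": gene in hub_set,
            "f": gene in hotspot_shared,
            "g": ann is not None and len(ann.drugs) > 0,
        }
        zs = [conn[gene].z for conn in (conn_a, conn_b) if gene in conn]
        scores.append(PriorityScore(
            gene=gene, criteria=criteria, score=sum(criteria.values()),
            not_evaluated=set(not_evaluated),
            mean_z=float(np.mean(zs)) if zs else float("-inf")))
    scores.sort(key=lambda s: (-s.score, -s.mean_z, s.gene))
    for i, s in enumerate(scores, start=1):
        s.rank = i
    return scores


def filter_receptors(genes: set[str], annotations: ProteinAnnotation) -> set[str]:
    """Keep genes annotated as membrane-localized receptors; unannotated
    genes are excluded with a warning."""
    kept: set[str] = set()
    for gene in sorted({canonical_symbol(g) for g in genes}):
        rec = annotations.get(gene)
        if rec is None:
            logger.warning("gene %r has no annotation; excluded from receptor filter", gene)
            continue
        if rec.protein_class == "receptor" and rec.membrane_localized:
            kept.add(gene)
    return kept


def attach_drugs(genes: set[str], annotations: ProteinAnnotation
                 ) -> list[tuple[str, str, str]]:
    """Flatten drug links into (gene, drug, stage) rows, deduplicated."""
    rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for gene in sorted({canonical_symbol(g) for g in genes}):
        rec = annotations.get(gene)
        if rec is None:
            continue
        for link in rec.drugs:
            row = (gene, link.drug, link.stage)
            if row not in seen:
                seen.add(row)
                rows.append(row)
    return rows


def write_scores(scores: list[PriorityScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgene\tscore\t" + "\t".join(CRITERIA) + "\tmean_z\tnot_evaluated\n")
        for s in scores:
            flags = "\t".join(str(int(s.criteria[c])) for c in CRITERIA)
            mean_z = f"{s.mean_z:.6g}" if np.isfinite(s.mean_z) else "NA"
            fh.write(f"{s.rank}\t{s.gene}\t{s.score}\t{flags}\t{mean_z}\t"
                     f"{','.join(sorted(s.not_evaluated))}\n")
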