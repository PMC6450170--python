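"""Seeded generators for every pipeline input type, with planted truth.

Each generator returns its artifact together with a :class:`TruthRecord`
describing exactly what signal was planted, so recovery tests never need
external data.  All generators are bit-reproducible from (parameters,
seed).  Noise is Gaussian on the log2/Ct scale — an idealization of
microarray and qPCR error.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .io import (CtTable, ExpressionMatrix, GeneLocus, GeneSet,
                 GeneSetCollection, InteractionNetwork, EFFECTS)


@dataclass
class TruthRecord:
    """Planted ground truth for one generated artifact."""

    deg_effects: dict[str, float] = field(default_factory=dict)
    clusters: list[dict] = field(default_factory=list)
    hubs: dict[str, int] = field(default_factory=dict)
    enriched_sets: list[str] = field(default_factory=list)
    qpcr_fc: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


@dataclass(frozen=True)
class ClusterSpec:
    """A planted positional DEG cluster: ``n_degs`` DEGs placed inside
    ``size`` consecutive gene slots starting at ordinal ``start`` on
    ``chromosome``."""

    chromosome: str
    start: int
    size: int
    n_degs: int


def default_gene_names(G: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(G)))
    return [f"{prefix}{i:0{width}d}" for i in range(G)]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(G: int, n_case: int, n_control: int,
                        deg_fraction: float = 0.1, effect_log2: float = 1.0,
                        noise_sd: float = 0.25, seed: int = 0,
                        genes: Sequence[str] | None = None,
                        extra_effects: Mapping[str, float] | None = None,
                        ) -> tuple[ExpressionMatrix, TruthRecord]:
    """Two-group log2 expression with a planted DEG fraction.

    Baselines are uniform on [6, 12] log2 units; planted DEGs shift the
    case mean by +/- ``effect_log2`` (half up, half down); Gaussian noise
    of sd ``noise_sd`` is added everywhere.  ``extra_effects`` plants
    specific per-gene log2 shifts on top of (and excluded from) the
    random selection.
    """
    if G <= 0 or n_case <= 0 or n_control <= 0:
        raise DomainError("G, n_case and n_control must be positive")
    if not 0 <= deg_fraction <= 1:
        raise DomainError("deg_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    gene_names = list(genes) if genes is not None else default_gene_names(G)
    if len(gene_names) != G:
        raise DomainError(f"got {len(gene_names)} gene names for G={G}")
    extra = dict(extra_effects or {})
    unknown = set(extra) - set(gene_names)
    if unknown:
        raise DomainError(f"extra_effects genes not in universe: {sorted(unknown)[:5]}")

    pool = [i for i, g in enumerate(gene_names) if g not in extra]
    n_planted = round(G * deg_fraction)
    n_planted = min(n_planted, len(pool))
    planted_idx = rng.choice(len(pool), size=n_planted, replace=False)
    effects = np.zeros(G)
    for rank, j in enumerate(sorted(planted_idx.tolist())):
        sign = 1.0 if rank < math.ceil(n_planted / 2) else -1.0
        effects[pool[j]] = sign * effect_log2
    for g, e in extra.items():
        effects[gene_names.index(g)] = e

    baseline = rng.uniform(6.0, 12.0, size=G)
    case = baseline[:, None] + effects[:, None] + rng.normal(0, noise_sd, (G, n_case))
    ctrl = baseline[:, None] + rng.normal(0, noise_sd, (G, n_control))
    samples = [f"CASE{i + 1}" for i in range(n_case)] + [f"CTRL{i + 1}" for i in range(n_control)]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=gene_names, columns=samples)
    groups = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    truth = TruthRecord(deg_effects={gene_names[i]: float(effects[i])
                                     for i in np.flatnonzero(effects)})
    return ExpressionMatrix(values=values, groups=groups).validate(), truth


# ---------------------------------------------------------------------------
# Genome maps
# ---------------------------------------------------------------------------

def simulate_genome_map(G: int, n_chromosomes: int,
                        cluster_spec: Sequence[ClusterSpec],
                        deg_set: set[str], seed: int = 0,
                        genes: Sequence[str] | None = None,
                        ) -> tuple[list[GeneLocus], TruthRecord]:
    """Assign genes to ascending non-overlapping intervals with planted
    positional DEG clusters; all other genes (DEG or not) are placed
    uniformly at random."""
    if G <= 0 or n_chromosomes <= 0:
        raise DomainError("G and n_chromosomes must be positive")
    rng = np.random.default_rng(seed)
    gene_names = list(genes) if genes is not None else default_gene_names(G)
    if len(gene_names) != G:
        raise DomainError(f"got {len(gene_names)} gene names for G={G}")
    deg_set = set(deg_set) & set(gene_names)

    base = G // n_chromosomes
    sizes = [base + (1 if c < G % n_chromosomes else 0) for c in range(n_chromosomes)]
    chrom_names = [f"chr{c + 1}" for c in range(n_chromosomes)]
    slots: dict[str, list[str | None]] = {name: [None] * size
                                          for name, size in zip(chrom_names, sizes)}

    truth = TruthRecord()
    free_degs = sorted(deg_set)
    for spec in cluster_spec:
        if spec.chromosome not in slots:
            raise DomainError(f"unknown chromosome {spec.chromosome!r}")
        chrom = slots[spec.chromosome]
        if spec.start < 0 or spec.start + spec.size > len(chrom):
            raise DomainError(f"cluster {spec} exceeds chromosome capacity ({len(chrom)})")
        if spec.n_degs > spec.size:
            raise DomainError(f"cluster {spec} wants more DEGs than slots")
        if spec.n_degs > len(free_degs):
            raise DomainError("not enough unplaced DEGs for cluster request")
        window = range(spec.start, spec.start + spec.size)
        if any(chrom[i] is not None for i in window):
            raise DomainError(f"cluster {spec} overlaps a previous cluster")
        positions = sorted(rng.choice(spec.size, size=spec.n_degs, replace=False).tolist())
        chosen_idx = rng.choice(len(free_degs), size=spec.n_degs, replace=False)
        chosen = [free_degs[i] for i in sorted(chosen_idx.tolist())]
        for pos, gene in zip(positions, chosen):
            chrom[spec.start + pos] = gene
        free_degs = [g for g in free_degs if g not in set(chosen)]
        truth.clusters.append({"chromosome": spec.chromosome,
                               "start_ordinal": spec.start, "size": spec.size,
                               "deg_genes": chosen})

    remaining = [g for g in gene_names if not _is_placed(g, slots)]
    order = rng.permutation(len(remaining))
    queue = [remaining[i] for i in order]
    for chrom in chrom_names:
        for i, val in enumerate(slots[chrom]):
            if val is None:
                slots[chrom][i] = queue.pop()

    loci: list[GeneLocus] = []
    for chrom in chrom_names:
        for j, gene in enumerate(slots[chrom]):
            start = j * 10_000
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(GeneLocus(chromosome=chrom, start=start, end=start + 5_000,
                                  gene=gene, strand=strand))
    return loci, truth


def _is_placed(gene: str, slots: dict[str, list[str | None]]) -> bool:
    return any(gene in chrom for chrom in slots.values())


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def simulate_network(G: int, mean_degree: float,
                     hub_spec: Sequence[tuple[str, int]],
                     deg_set: set[str], seed: int = 0,
                     genes: Sequence[str] | None = None,
                     ) -> tuple[InteractionNetwork, TruthRecord]:
    """Random background graph plus planted hubs preferentially wired
    into the DEG set.

    The background is an Erdos-Renyi G(n, m) graph with
    m = round(G * mean_degree / 2) undirected pairs; each pair gets a
    random orientation and effect sign.  Each (gene, extra) hub entry
    adds ``extra`` edges from the hub to distinct, uniformly chosen
    DEG-set members it is not yet connected to.
    """
    if G <= 1 or mean_degree < 0:
        raise DomainError("need G > 1 and mean_degree >= 0")
    rng = np.random.default_rng(seed)
    gene_names = list(genes) if genes is not None else default_gene_names(G)
    if len(gene_names) != G:
        raise DomainError(f"got {len(gene_names)} gene names for G={G}")
    deg_members = sorted(set(deg_set) & set(gene_names))

    m = round(G * mean_degree / 2)
    graph = nx.gnm_random_graph(G, m, seed=int(rng.integers(2 ** 31)))
    pairs = {tuple(sorted(e)) for e in graph.edges()}

    truth = TruthRecord()
    for hub, extra in hub_spec:
        if hub not in gene_names:
            raise DomainError(f"hub {hub!r} not in gene universe")
        hub_i = gene_names.index(hub)
        candidates = [gene_names.index(g) for g in deg_members
                      if g != hub and tuple(sorted((hub_i, gene_names.index(g)))) not in pairs]
        if extra > len(candidates):
            raise DomainError(f"hub {hub!r}: {extra} extra edges exceed capacity {len(candidates)}")
        chosen = rng.choice(len(candidates), size=extra, replace=False)
        for c in sorted(chosen.tolist()):
            pairs.add(tuple(sorted((hub_i, candidates[c]))))
        truth.hubs[hub] = extra

    net = InteractionNetwork()
    for g in gene_names:
        net.add_node(g)
    for (i, j) in sorted(pairs):
        if rng.random() < 0.5:
            i, j = j, i
        effect = EFFECTS[int(rng.integers(len(EFFECTS)))]
        net.add_edge(gene_names[i], gene_names[j], effect)
    return net.validate(), truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(universe: Sequence[str], deg_set: set[str],
                       n_sets: int = 20, set_size: int = 25,
                       planted: Sequence[tuple[str, int]] = (),
                       seed: int = 0) -> tuple[GeneSetCollection, TruthRecord]:
    """Random gene sets plus planted enriched sets.

    Each (name, n_deg_members) entry in ``planted`` creates a set of
    ``set_size`` genes of which ``n_deg_members`` are drawn from the DEG
    set; the rest of the sets are uniform draws from the universe.
    """
    if n_sets < 0 or set_size <= 0:
        raise DomainError("n_sets must be >= 0 and set_size positive")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    deg_members = sorted(set(deg_set) & set(universe))
    non_deg = sorted(set(universe) - set(deg_members))
    coll = GeneSetCollection()
    truth = TruthRecord()
    for name, n_deg_members in planted:
        if n_deg_members > len(deg_members) or set_size - n_deg_members > len(non_deg):
            raise DomainError(f"planted set {name!r} exceeds universe capacity")
        members = ([deg_members[i] for i in rng.choice(len(deg_members), n_deg_members, replace=False)]
                   + [non_deg[i] for i in rng.choice(len(non_deg), set_size - n_deg_members, replace=False)])
        coll.sets[name] = GeneSet(name=name, description="planted", members=frozenset(members))
        truth.enriched_sets.append(name)
    for i in range(n_sets):
        name = f"RANDOM_SET_{i + 1:03d}"
        members = [universe[j] for j in rng.choice(len(universe), set_size, replace=False)]
        coll.sets[name] = GeneSet(name=name, description="background", members=frozenset(members))
    return coll.validate(), truth


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def simulate_ct(genes: Sequence[str], planted_fc: Mapping[str, float],
                n_case: int = 5, n_control: int = 5, noise_sd: float = 0.0,
                seed: int = 0, housekeeping_gene: str = "ACTB",
                n_replicates: int = 2) -> tuple[CtTable, TruthRecord]:
    """Ct table with known fold changes and a stable housekeeping gene.

    The housekeeping gene sits at Ct 18 in every sample (up to noise);
    each target gene's case Ct is lowered by log2(planted fold change)
    cycles.  Two technical replicates per measurement by default; the
    reference sample is the first control.
    """
    for g, fc in planted_fc.items():
        if fc <= 0:
            raise DomainError(f"planted fold change for {g!r} must be > 0, got {fc}")
    if n_case <= 0 or n_control <= 0 or n_replicates < 1:
        raise DomainError("sample and replicate counts must be positive")
    rng = np.random.default_rng(seed)
    genes = [g for g in genes if g != housekeeping_gene]
    samples = ([(f"CR{i + 1}", "control") for i in range(n_control)]
               + [(f"LE{i + 1}", "case") for i in range(n_case)])
    base_ct = {g: float(rng.uniform(22.0, 26.0)) for g in genes}
    rows = []
    for sample, grp in samples:
        for rep in range(1, n_replicates + 1):
            rows.append((sample, housekeeping_gene, rep,
                         18.0 + float(rng.normal(0, noise_sd))))
        for g in genes:
            shift = -math.log2(planted_fc.get(g, 1.0)) if grp == "case" else 0.0
            for rep in range(1, n_replicates + 1):
                rows.append((sample, g, rep,
                             base_ct[g] + shift + float(rng.normal(0, noise_sd))))
    records = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    groups = dict(samples)
    table = CtTable(records=records, groups=groups,
                    housekeeping_gene=housekeeping_gene,
                    reference_sample=samples[0][0]).validate()
    truth = TruthRecord(qpcr_fc={g: float(planted_fc.get(g, 1.0)) for g in genes})
    return table, truth


# ---------------------------------------------------------------------------
# Coherent full-pipeline bundle
# ---------------------------------------------------------------------------

def simulate_bundle(outdir: str | Path, seed: int = 0, G: int = 800,
                    ) -> tuple[dict, TruthRecord, str]:
    """Write a coherent set of pipeline inputs with one planted
    all-criteria target gene.

    The target is planted as an up-regulated DEG in both tissues, sits
    in a shared positional cluster, is wired as a network hub into the
    shared DEG set, carries a planted qPCR induction, belongs to a
    planted enriched set and is annotated as a drugged membrane
    receptor.  Returns (config dict for :class:`RunConfig`, truth,
    target gene symbol).
    """
    from . import io as ttio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    gene_names = default_gene_names(G)
    target = gene_names[0]
    shared_idx = rng.choice(np.arange(1, G), size=39, replace=False)
    shared = [target] + [gene_names[i] for i in sorted(shared_idx.tolist())]
    extra_effects = {g: 1.2 for g in shared}

    truth = TruthRecord()
    matrices = {}
    for label, sub in (("a", 1), ("b", 2)):
        matrix, t = simulate_expression(
            G, n_case=5, n_control=5, deg_fraction=0.08, effect_log2=1.0,
            noise_sd=0.25, seed=seed * 10 + sub, genes=gene_names,
            extra_effects=extra_effects)
        ttio.write_expression_matrix(matrix, out / f"matrix_{label}.tsv",
                                     out / f"groups_{label}.tsv")
        matrices[label] = matrix
        truth.deg_effects.update(t.deg_effects)

    cluster_members = set(shared[:6])
    cluster_start = (G // 5) // 3  # keep the planted window inside chr1
    loci, map_truth = simulate_genome_map(
        G, n_chromosomes=5, deg_set=cluster_members,
        cluster_spec=[ClusterSpec(chromosome="chr1", start=cluster_start,
                                  size=8, n_degs=6)],
        seed=seed * 10 + 3, genes=gene_names)
    ttio.write_gene_map(loci, out / "genes.bed")
    truth.clusters = map_truth.clusters

    network, net_truth = simulate_network(
        G, mean_degree=6.0, hub_spec=[(target, 35)], deg_set=set(shared),
        seed=seed * 10 + 4, genes=gene_names)
    ttio.write_network(network, out / "network.sif")
    truth.hubs = net_truth.hubs

    coll, set_truth = simulate_gene_sets(
        gene_names, deg_set=set(shared), n_sets=20, set_size=25,
        planted=[("DISEASE_PATHWAY", 20)], seed=seed * 10 + 5)
    planted_set = coll.sets["DISEASE_PATHWAY"]
    if target not in planted_set.members:  # the target must sit in the enriched set
        members = set(planted_set.members)
        members.discard(sorted(members - set(shared))[0])
        members.add(target)
        coll.sets["DISEASE_PATHWAY"] = GeneSet(
            name=planted_set.name, description=planted_set.description,
            members=frozenset(members))
    ttio.write_gene_sets(coll, out / "sets.gmt")
    truth.enriched_sets = set_truth.enriched_sets

    qpcr_genes = [target] + shared[6:9]
    table, ct_truth = simulate_ct(
        qpcr_genes, planted_fc={g: 4.0 for g in qpcr_genes},
        n_case=5, n_control=5, noise_sd=0.3, seed=seed * 10 + 6)
    ttio.write_ct_table(table, out / "ct.csv", out / "ct_meta.csv")
    truth.qpcr_fc = ct_truth.qpcr_fc

    ann = ttio.ProteinAnnotation()
    ann.records[target] = ttio.AnnotationRecord(
        gene=target, protein_class="receptor", membrane_localized=True,
        drugs=(ttio.DrugLink("AGENT-A", "phase II"), ttio.DrugLink("AGENT-B", "preclinical")))
    classes = [c for c in ttio.PROTEIN_CLASSES if c != "receptor"]
    for g in shared[1:]:
        cls = classes[int(rng.integers(len(classes)))]
        drugs = ()
        if rng.random() < 0.3:
            drugs = (ttio.DrugLink(f"AGENT-{g}", "preclinical"),)
        ann.records[g] = ttio.AnnotationRecord(
            gene=g, protein_class=cls, membrane_localized=False, drugs=drugs)
    ttio.write_annotations(ann, out / "annotations.tsv")

    config = {
        "matrix_a": str(out / "matrix_a.tsv"), "groups_a": str(out / "groups_a.tsv"),
        "matrix_b": str(out / "matrix_b.tsv"), "groups_b": str(out / "groups_b.tsv"),
        "gene_map": str(out / "genes.bed"), "network": str(out / "network.sif"),
        "gene_sets": str(out / "sets.gmt"), "annotations": str(out / "annotations.tsv"),
        "ct_table": str(out / "ct.csv"), "ct_meta": str(out / "ct_meta.csv"),
        "case_a": "case", "control_a": "control",
        "case_b": "case", "control_b": "control",
        "outdir": str(out / "results"), "seed": seed,
    }
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    truth.to_json(out / "truth.json")
    return config, truth, target


def simulate_evidence_bundle(n_candidates: int = 51, seed: int = 0):
    """Build a prioritization evidence bundle with one planted
    all-criteria gene among partial satisfiers.

    Every non-target candidate gets a uniformly chosen strict subset of
    the seven criteria; the target satisfies all of them and carries the
    largest over-connectivity z.  Returns (bundle, candidate set,
    target symbol).
    """
    from .crosscompare import OverlapReport
    from .enrichment import EnrichmentResult
    from .hotspots import HotSpot
    from .io import AnnotationRecord, DrugLink, ProteinAnnotation
    from .overconnectivity import ConnectivityResult
    from .prioritize import CRITERIA, EvidenceBundle
    from .qpcr import FoldChangeResult

    if n_candidates < 2:
        raise DomainError("need at least a target and one competitor")
    rng = np.random.default_rng(seed)
    genes = default_gene_names(n_candidates, prefix="C")
    target = genes[0]
    flags: dict[str, set[str]] = {target: set(CRITERIA)}
    for g in genes[1:]:
        size = int(rng.integers(0, len(CRITERIA)))  # strict subset
        flags[g] = set(rng.choice(CRITERIA, size=size, replace=False).tolist())

    common = {g for g in genes if "a" in flags[g]}
    directions_a = {g: "UP" for g in genes}
    directions_b = {g: "UP" for g in genes}
    overlap = OverlapReport(common=common, same_direction=set(common),
                            opposite_direction=set(), unique_a=0, unique_b=0,
                            directions_a=directions_a, directions_b=directions_b)
    qpcr_results = [
        FoldChangeResult(gene=g, relative_expression={},
                         control_mean=1.0, control_sem=0.1,
                         case_mean=4.0 if "b" in flags[g] else 0.25,
                         case_sem=0.1, p=0.01)
        for g in genes]
    enr = [EnrichmentResult(name="PLANTED", overlap={g for g in genes if "c" in flags[g]},
                            k_up=0, k_down=0, p=1e-5, q=1e-4)]
    conn = {}
    for side in ("a", "b"):
        conn[side] = [
            ConnectivityResult(gene=g, actual=10, n=20, R=30, N=200, expected=3.0,
                               ratio=3.3,
                               z=(50.0 if g == target else float(rng.uniform(1, 10)))
                               if "d" in flags[g] else 0.1,
                               p=0.001 if "d" in flags[g] else 0.6)
            for g in genes]
    hub_list = [(g, 1000 if "e" in flags[g] else 1) for g in genes]
    spot = HotSpot(chromosome="chr1", span=(0, 1000), genes=list(genes),
                   deg_genes={g for g in genes if "f" in flags[g]}, w=8, k=6, p=1e-5)
    hotspot_overlaps = [(spot, spot, {g for g in genes if "f" in flags[g]})]
    ann = ProteinAnnotation()
    for g in genes:
        drugs = (DrugLink("AGENT", "approved"),) if "g" in flags[g] else ()
        ann.records[g] = AnnotationRecord(gene=g, protein_class="receptor",
                                          membrane_localized=True, drugs=drugs)
    bundle = EvidenceBundle(overlap=overlap, qpcr=qpcr_results, enrichment=enr,
                            connectivity_a=conn["a"], connectivity_b=conn["b"],
                            hub_list=hub_list, hotspot_overlaps=hotspot_overlaps,
                            annotations=ann)
    return bundle, set(genes), target
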