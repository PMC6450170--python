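"""End-to-end orchestration from a single YAML configuration.

Stage order: DEG calling per tissue -> cross-tissue overlap -> hot-spot
scan per tissue + overlap -> over-connectivity per tissue (intersection
for the shared set) -> enrichment -> qPCR (optional) -> prioritization.
Every stage writes a TSV; a JSON run summary records counts at each
gate and all effective thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import crosscompare, deg, enrichment, hotspots, overconnectivity, prioritize, qpcr
from . import io as ttio
from .errors import TargetTriageError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    matrix_a: str
    groups_a: str
    matrix_b: str
    groups_b: str
    gene_map: str
    network: str
    gene_sets: str
    annotations: str
    outdir: str
    case_a: str = "case"
    control_a: str = "control"
    case_b: str = "case"
    control_b: str = "control"
    tissue_a: str = "skin"
    tissue_b: str = "blood"
    background: str | None = None
    ct_table: str | None = None
    ct_meta: str | None = None
    housekeeping_gene: str = "ACTB"
    reference_sample: str | None = None
    p_max_deg: float = 0.05
    fc_min: float = 1.1
    min_degs: int = 5
    p_max_hotspot: float = 0.001
    p_max_conn: float = 0.05
    q_max_enrich: float = 0.05
    hub_quantile: float = 0.9
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"{path}: {exc}") from exc

    def validate(self) -> "RunConfig":
        required = ["matrix_a", "groups_a", "matrix_b", "groups_b", "gene_map",
                    "network", "gene_sets", "annotations"]
        optional = ["background", "ct_table", "ct_meta"]
        for name in required:
            value = getattr(self, name)
            if value is None:
                raise ValidationError(f"config field {name!r} is required")
            if not Path(value).exists():
                raise ValidationError(f"{name}: file not found: {value}")
        for name in optional:
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ValidationError(f"{name}: file not found: {value}")
        if (self.ct_table is None) != (self.ct_meta is None):
            raise ValidationError("ct_table and ct_meta must be given together")
        for name, lo, hi in [("p_max_deg", 0, 1), ("p_max_hotspot", 0, 1),
                             ("p_max_conn", 0, 1), ("q_max_enrich", 0, 1),
                             ("hub_quantile", 0, 1)]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValidationError(f"{name} must be in ({lo}, {hi}], got {v}")
        if self.fc_min < 1:
            raise ValidationError(f"fc_min must be >= 1, got {self.fc_min}")
        if self.min_degs < 1:
            raise ValidationError(f"min_degs must be >= 1, got {self.min_degs}")
        return self


class StageError(TargetTriageError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute the full chain and return the run summary dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"thresholds": {
        "p_max_deg": config.p_max_deg, "fc_min": config.fc_min,
        "min_degs": config.min_degs, "p_max_hotspot": config.p_max_hotspot,
        "p_max_conn": config.p_max_conn, "q_max_enrich": config.q_max_enrich,
        "hub_quantile": config.hub_quantile},
        "seed": config.seed, "counts": {}, "test": "welch-t (unequal variance)"}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except TargetTriageError as exc:
                raise StageError(name, exc) from exc
        return wrap

    # --- DEG calling, both tissues
    degs = {}
    for label, (mpath, gpath, case, ctrl, tissue) in {
        "a": (config.matrix_a, config.groups_a, config.case_a, config.control_a, config.tissue_a),
        "b": (config.matrix_b, config.groups_b, config.case_b, config.control_b, config.tissue_b),
    }.items():
        matrix = stage(f"deg_{label}")(ttio.read_expression_matrix, mpath, gpath)
        records = stage(f"deg_{label}")(
            deg.call_degs, matrix, case, ctrl,
            p_max=config.p_max_deg, fc_min=config.fc_min, tissue=tissue)
        deg.write_degs(records, out / f"degs_{label}.tsv")
        degs[label] = records
        summary["counts"][f"degs_{label}"] = len(records)
        if label == "a":
            platform = {ttio.canonical_symbol(g) for g in matrix.genes}
        else:
            platform |= {ttio.canonical_symbol(g) for g in matrix.genes}

    # --- Cross-tissue overlap
    report = stage("overlap")(crosscompare.overlap_profiles, degs["a"], degs["b"])
    crosscompare.write_overlap(report, out / "overlap.tsv")
    summary["counts"]["common"] = len(report.common)
    summary["counts"]["same_direction"] = len(report.same_direction)
    summary["counts"]["opposite_direction"] = len(report.opposite_direction)

    # --- Hot spots per tissue, then cross-tissue overlap
    loci = stage("hotspots")(ttio.read_gene_map, config.gene_map)
    spots = {}
    for label in ("a", "b"):
        deg_syms = {r.gene for r in degs[label]}
        layout = hotspots.build_layout(loci, deg_syms)
        summary["counts"][f"unmapped_degs_{label}"] = len(layout.unmapped_degs)
        spots[label] = stage(f"hotspots_{label}")(
            hotspots.scan_hotspots, layout,
            min_degs=config.min_degs, p_max=config.p_max_hotspot)
        hotspots.write_hotspots(spots[label], out / f"hotspots_{label}.tsv")
        summary["counts"][f"hotspots_{label}"] = len(spots[label])
    spot_pairs = stage("hotspot_overlap")(hotspots.overlap_hotspots, spots["a"], spots["b"])
    with open(out / "hotspot_overlap.tsv", "w") as fh:
        fh.write("chromosome\tstart_a\tend_a\tstart_b\tend_b\tshared_genes\n")
        for ha, hb, shared in spot_pairs:
            fh.write(f"{ha.chromosome}\t{ha.span[0]}\t{ha.span[1]}\t{hb.span[0]}\t"
                     f"{hb.span[1]}\t{','.join(sorted(shared))}\n")
    summary["counts"]["hotspot_overlaps"] = len(spot_pairs)

    # --- Over-connectivity of the shared DEGs against each tissue set
    network = stage("overconnect")(ttio.read_network, config.network)
    if config.background is not None:
        with open(config.background) as fh:
            background = {ttio.canonical_symbol(line.strip()) for line in fh if line.strip()}
        background &= network.nodes
    else:
        background = network.nodes & platform
    summary["counts"]["background"] = len(background)
    candidates = report.common & background
    conn = {}
    for label in ("a", "b"):
        deg_syms = {r.gene for r in degs[label]}
        results = stage(f"overconnect_{label}")(
            overconnectivity.overconnected_genes, network, deg_syms, background,
            p_max=1.0, candidates=candidates)
        conn[label] = results
        significant = [r for r in results if r.p <= config.p_max_conn]
        overconnectivity.write_connectivity(significant, out / f"overconnected_{label}.tsv")
        summary["counts"][f"overconnected_{label}"] = len(significant)
    shared_over = ({r.gene for r in conn["a"] if r.p <= config.p_max_conn}
                   & {r.gene for r in conn["b"] if r.p <= config.p_max_conn})
    summary["counts"]["shared_overconnected"] = len(shared_over)

    # --- One-step expansion and hub ranking around the shared set
    seeds = shared_over or (report.common & network.nodes)
    if seeds:
        expanded = overconnectivity.expand_network(network, seeds)
        hubs = overconnectivity.hub_rank(expanded)
    else:
        hubs = []
    with open(out / "hubs.tsv", "w") as fh:
        fh.write("gene\tdegree\n")
        for g, d in hubs:
            fh.write(f"{g}\t{d}\n")
    summary["counts"]["expanded_nodes"] = len(hubs)

    # --- Enrichment of the shared DEGs
    collection = stage("enrich")(ttio.read_gene_sets, config.gene_sets)
    common_records = [r for r in degs["a"] if r.gene in report.common]
    enr = stage("enrich")(enrichment.enrich, common_records, collection, platform)
    enrichment.write_enrichment(enr, out / "enrichment.tsv")
    summary["counts"]["enriched_sets"] = sum(1 for r in enr if r.q <= config.q_max_enrich)

    # --- qPCR (optional)
    fold = None
    if config.ct_table is not None:
        table = stage("qpcr")(ttio.read_ct_table, config.ct_table, config.ct_meta,
                              housekeeping_gene=config.housekeeping_gene,
                              reference_sample=config.reference_sample)
        fold = stage("qpcr")(qpcr.quantify, table)
        qpcr.write_fold_changes(fold, out / "qpcr.tsv")
        summary["counts"]["qpcr_genes"] = len(fold)

    # --- Prioritization
    annotations = stage("prioritize")(ttio.read_annotations, config.annotations)
    bundle = prioritize.EvidenceBundle(
        overlap=report, qpcr=fold, enrichment=enr,
        connectivity_a=conn["a"], connectivity_b=conn["b"],
        hub_list=hubs or None, hotspot_overlaps=spot_pairs,
        annotations=annotations)
    scores = stage("prioritize")(
        prioritize.score_candidates, bundle,
        q_max=config.q_max_enrich, conn_p_max=config.p_max_conn,
        hub_quantile=config.hub_quantile)
    prioritize.write_scores(scores, out / "ranked.tsv")
    summary["counts"]["candidates"] = len(scores)
    receptors = prioritize.filter_receptors({s.gene for s in scores}, annotations)
    drug_rows = prioritize.attach_drugs(receptors, annotations)
    with open(out / "drug_links.tsv", "w") as fh:
        fh.write("gene\tdrug\tstage\n")
        for gene, drug, stg in drug_rows:
            fh.write(f"{gene}\t{drug}\t{stg}\n")
    summary["counts"]["membrane_receptors"] = len(receptors)
    summary["counts"]["drug_links"] = len(drug_rows)
    if scores:
        summary["top_candidate"] = scores[0].gene

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
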