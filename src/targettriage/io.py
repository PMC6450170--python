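"""Readers and writers for the text formats the pipeline touches.

Formats handled: TSV expression matrices, BED gene maps (0-based,
half-open), SIF-style interaction edge lists, GMT gene-set collections,
CSV Ct tables and TSV protein/drug annotation tables.  Every reader
validates the container invariants of the corresponding domain type and
raises :class:`~targettriage.errors.FormatError` or
:class:`~targettriage.errors.ValidationError` on bad input.

Gene identity throughout the package is the uppercased symbol string;
:func:`canonical_symbol` is the single canonicalization point.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

EFFECTS = ("positive", "negative", "unspecified")
_SIF_RELATIONS = {
    "activates": "positive",
    "inhibits": "negative",
    "interacts": "unspecified",
}
_SIF_RELATION_OF_EFFECT = {v: k for k, v in _SIF_RELATIONS.items()}

DRUG_STAGES = ("preclinical", "phase I", "phase II", "phase III", "approved")
PROTEIN_CLASSES = (
    "ligand",
    "protease",
    "receptor",
    "kinase",
    "transcription factor",
    "enzyme",
    "other",
)


def canonical_symbol(symbol: str) -> str:
    """Canonicalize a gene symbol (strip surrounding space, uppercase)."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2 intensities for genes x samples plus a sample->group map.

    ``values`` is a DataFrame indexed by gene/probe identifier with one
    column per sample, preserving file order.  ``probe_to_gene`` is an
    optional probe->symbol mapping; probe collapse happens downstream in
    the DEG caller, not here.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    probe_to_gene: dict[str, str] | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == label]

    def validate(self) -> "ExpressionMatrix":
        idx = self.values.index
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise ValidationError(f"samples missing from group map: {missing}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        counts: dict[str, int] = {}
        for s in cols:
            g = self.groups[s]
            counts[g] = counts.get(g, 0) + 1
        for g, c in counts.items():
            if c < 2:
                raise ValidationError(f"group {g!r} has {c} sample(s); need >= 2")
        return self


def read_expression_matrix(path: str | Path, group_map_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix plus a sample->group map.

    The matrix header row holds sample ids; the first column holds
    gene/probe ids.  Row and column order are preserved.
    """
    path = Path(path)
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse TSV matrix: {exc}") from exc
    # pandas mangles duplicate headers ("S1.1"); detect dupes from the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for s in header:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample id {s!r}")
        seen.add(s)
    values.columns = header
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any():
            gene = values.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value for gene {gene!r}, sample {col!r}"
            )
        if coerced.isna().any():
            gene = values.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(f"{path}: missing value for gene {gene!r}, sample {col!r}")
        values[col] = coerced.astype(float)
    values.index = values.index.astype(str).rename(None)
    groups = _read_group_map(group_map_path)
    return ExpressionMatrix(values=values.astype(float), groups=groups).validate()


def _read_group_map(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{i}: expected 2 tab-separated fields")
            sample, label = fields
            if sample in ("sample", "Sample") and label in ("group", "Group"):
                continue  # tolerate a header row
            if sample in groups:
                raise FormatError(f"{path}:{i}: duplicate sample {sample!r}")
            groups[sample] = label
    return groups


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            group_map_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    if group_map_path is not None:
        with open(group_map_path, "w") as fh:
            for s in matrix.samples:
                fh.write(f"{s}\t{matrix.groups[s]}\n")


# ---------------------------------------------------------------------------
# Gene maps (BED)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GeneLocus:
    """A gene interval in BED convention (0-based, half-open)."""

    chromosome: str
    start: int
    end: int
    gene: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValidationError("chromosome name must be non-empty")
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene}: bad strand {self.strand!r}")


def read_gene_map(path: str | Path) -> list[GeneLocus]:
    """Read a >=4 column BED file into a list of loci.

    Duplicate gene names are collapsed to the first occurrence with a
    logged warning.
    """
    path = Path(path)
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{i}: BED needs >= 4 columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(f"{path}:{i}: start ({start}) >= end ({end})")
            strand = fields[5] if len(fields) >= 6 else "+"
            symbol = canonical_symbol(name)
            if symbol in seen:
                logger.warning("%s:%d: duplicate gene %s; keeping first occurrence",
                               path, i, symbol)
                continue
            seen.add(symbol)
            loci.append(GeneLocus(chromosome=chrom, start=start, end=end,
                                  gene=symbol, strand=strand))
    return loci


def write_gene_map(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chromosome}\t{loc.start}\t{loc.end}\t{loc.gene}\t0\t{loc.strand}\n")


# ---------------------------------------------------------------------------
# Interaction networks (SIF dialect)
# ---------------------------------------------------------------------------

@dataclass
class InteractionNetwork:
    """A directed interaction network over gene symbols.

    Edges carry an effect sign in {positive, negative, unspecified}.
    Self-loops are recorded separately and excluded from neighbor and
    degree computations.
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], str] = field(default_factory=dict)
    self_loops: set[str] = field(default_factory=set)
    _adj: dict[str, set[str]] | None = field(default=None, repr=False, compare=False)

    def add_node(self, node: str) -> None:
        self.nodes.add(canonical_symbol(node))
        self._adj = None

    def add_edge(self, source: str, target: str, effect: str = "unspecified") -> None:
        if effect not in EFFECTS:
            raise ValidationError(f"unknown effect {effect!r}")
        s, t = canonical_symbol(source), canonical_symbol(target)
        self.nodes.add(s)
        self.nodes.add(t)
        if s == t:
            self.self_loops.add(s)
            return
        self.edges.setdefault((s, t), effect)
        self._adj = None

    def neighbors(self, gene: str) -> set[str]:
        """Union of in- and out-neighbors, excluding the gene itself."""
        return self._adjacency().get(canonical_symbol(gene), set())

    def degree(self, gene: str) -> int:
        """Number of distinct interaction partners (self-loops excluded)."""
        return len(self.neighbors(gene))

    def _adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {n: set() for n in self.nodes}
            for (s, t) in self.edges:
                adj[s].add(t)
                adj[t].add(s)
            self._adj = adj
        return self._adj

    def subnetwork(self, nodes: Iterable[str]) -> "InteractionNetwork":
        keep = {canonical_symbol(n) for n in nodes} & self.nodes
        sub = InteractionNetwork(nodes=set(keep))
        for (s, t), effect in self.edges.items():
            if s in keep and t in keep:
                sub.edges[(s, t)] = effect
        sub.self_loops = self.self_loops & keep
        return sub

    def validate(self) -> "InteractionNetwork":
        for (s, t) in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise ValidationError(f"edge ({s}, {t}) endpoint not in node set")
            if s == t:
                raise ValidationError(f"self-loop ({s}, {t}) stored as an edge")
        return self


def read_network(path: str | Path) -> InteractionNetwork:
    """Read a SIF-style edge list: source<TAB>relation<TAB>target.

    Relations map to effect signs: activates -> positive, inhibits ->
    negative, interacts -> unspecified.  Duplicate (source, target)
    pairs keep the first effect seen; self-loops are recorded but carry
    no degree.
    """
    path = Path(path)
    net = InteractionNetwork()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                net.add_node(fields[0])  # isolated node, plain SIF allows this
                continue
            if len(fields) != 3:
                raise FormatError(f"{path}:{i}: expected 3 tab-separated fields")
            source, relation, target = fields
            if relation not in _SIF_RELATIONS:
                raise FormatError(f"{path}:{i}: unknown relation {relation!r}")
            net.add_edge(source, target, _SIF_RELATIONS[relation])
    return net.validate()


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    linked = {n for e in net.edges for n in e} | net.self_loops
    with open(path, "w") as fh:
        for (s, t), effect in sorted(net.edges.items()):
            fh.write(f"{s}\t{_SIF_RELATION_OF_EFFECT[effect]}\t{t}\n")
        for n in sorted(net.self_loops):
            fh.write(f"{n}\tinteracts\t{n}\n")
        for n in sorted(net.nodes - linked):
            fh.write(f"{n}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def validate(self) -> "GeneSetCollection":
        for name, gs in self.sets.items():
            if not gs.members:
                raise ValidationError(f"gene set {name!r} is empty")
        return self


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name<TAB>description<TAB>member..."""
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{i}: GMT line needs >= 3 fields")
            name, description = fields[0], fields[1]
            members = frozenset(canonical_symbol(g) for g in fields[2:] if g.strip())
            if not members:
                raise FormatError(f"{path}:{i}: gene set {name!r} has no members")
            coll.sets[name] = GeneSet(name=name, description=description, members=members)
    return coll.validate()


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Ct tables (CSV)
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Raw qPCR cycle-threshold measurements.

    One record per (sample, gene, technical replicate).  The
    housekeeping gene must be measured in every sample and the
    reference sample must belong to the control group.
    """

    records: pd.DataFrame  # columns: sample, gene, replicate, ct
    groups: dict[str, str]
    housekeeping_gene: str = "ACTB"
    reference_sample: str | None = None

    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample"]))

    def target_genes(self) -> list[str]:
        return [g for g in dict.fromkeys(self.records["gene"]) if g != self.housekeeping_gene]

    def validate(self) -> "CtTable":
        required = {"sample", "gene", "replicate", "ct"}
        if not required.issubset(self.records.columns):
            raise ValidationError(f"Ct table needs columns {sorted(required)}")
        if (self.records["ct"] <= 0).any():
            bad = self.records.loc[self.records["ct"] <= 0].iloc[0]
            raise ValidationError(f"non-positive Ct for sample {bad['sample']!r}, gene {bad['gene']!r}")
        for s in self.samples():
            if s not in self.groups:
                raise ValidationError(f"sample {s!r} missing from group map")
            sub = self.records[self.records["sample"] == s]
            if self.housekeeping_gene not in set(sub["gene"]):
                raise ValidationError(
                    f"housekeeping gene {self.housekeeping_gene!r} missing for sample {s!r}"
                )
        if self.reference_sample is not None:
            if self.groups.get(self.reference_sample) != "control":
                raise ValidationError(
                    f"reference sample {self.reference_sample!r} is not in the control group"
                )
        return self


def read_ct_table(path: str | Path, meta_path: str | Path,
                  housekeeping_gene: str = "ACTB",
                  reference_sample: str | None = None) -> CtTable:
    """Read a Ct CSV (sample,gene,replicate,ct) plus sample metadata CSV.

    The metadata file has columns sample,group with group in
    {case, control}.  If ``reference_sample`` is None the first control
    sample in metadata order is used.
    """
    path = Path(path)
    try:
        records = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing_cols = {"sample", "gene", "replicate", "ct"} - set(records.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    records["gene"] = records["gene"].map(canonical_symbol)
    records["sample"] = records["sample"].astype(str)
    groups: dict[str, str] = {}
    with open(meta_path) as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0] == "sample":
                continue
            if len(row) != 2:
                raise FormatError(f"{meta_path}:{i}: expected sample,group")
            sample, grp = row[0].strip(), row[1].strip().lower()
            if grp not in ("case", "control"):
                raise FormatError(f"{meta_path}:{i}: group must be case or control, got {grp!r}")
            groups[sample] = grp
    if reference_sample is None:
        controls = [s for s, g in groups.items() if g == "control"]
        if not controls:
            raise ValidationError(f"{meta_path}: no control samples")
        reference_sample = controls[0]
    return CtTable(records=records, groups=groups,
                   housekeeping_gene=canonical_symbol(housekeeping_gene),
                   reference_sample=reference_sample).validate()


def write_ct_table(table: CtTable, path: str | Path, meta_path: str | Path | None = None) -> None:
    table.records.to_csv(path, index=False)
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            fh.write("sample,group\n")
            for s, g in table.groups.items():
                fh.write(f"{s},{g}\n")


# ---------------------------------------------------------------------------
# Protein / drug annotations (TSV)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugLink:
    drug: str
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in DRUG_STAGES:
            raise ValidationError(f"unknown drug stage {self.stage!r}")


@dataclass
class AnnotationRecord:
    gene: str
    protein_class: str
    membrane_localized: bool
    drugs: tuple[DrugLink, ...] = ()

    def __post_init__(self) -> None:
        if self.protein_class not in PROTEIN_CLASSES:
            raise ValidationError(f"{self.gene}: unknown protein class {self.protein_class!r}")


@dataclass
class ProteinAnnotation:
    records: dict[str, AnnotationRecord] = field(default_factory=dict)

    def __contains__(self, gene: str) -> bool:
        return canonical_symbol(gene) in self.records

    def __getitem__(self, gene: str) -> AnnotationRecord:
        return self.records[canonical_symbol(gene)]

    def get(self, gene: str) -> AnnotationRecord | None:
        return self.records.get(canonical_symbol(gene))


def read_annotations(path: str | Path) -> ProteinAnnotation:
    """Read a TSV of gene, protein_class, membrane_localized, drugs.

    The drugs column is a semicolon-separated list of "name:stage"
    entries and may be empty; duplicate drug entries are dropped.
    """
    path = Path(path)
    ann = ProteinAnnotation()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{i}: expected >= 3 tab-separated fields")
            gene = canonical_symbol(fields[0])
            protein_class = fields[1].strip().lower()
            membrane = fields[2].strip().upper() in ("TRUE", "1", "YES")
            drugs: list[DrugLink] = []
            if len(fields) >= 4 and fields[3].strip():
                seen: set[tuple[str, str]] = set()
                for entry in fields[3].split(";"):
                    entry = entry.strip()
                    if not entry:
                        continue
                    if ":" not in entry:
                        raise FormatError(f"{path}:{i}: drug entry {entry!r} lacks ':stage'")
                    drug, stage = entry.rsplit(":", 1)
                    key = (drug.strip(), stage.strip())
                    if key in seen:
                        continue
                    seen.add(key)
                    drugs.append(DrugLink(drug=key[0], stage=key[1]))
            ann.records[gene] = AnnotationRecord(
                gene=gene, protein_class=protein_class,
                membrane_localized=membrane, drugs=tuple(drugs))
    return ann


def write_annotations(ann: ProteinAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tprotein_class\tmembrane_localized\tdrugs\n")
        for gene in sorted(ann.records):
            rec = ann.records[gene]
            drugs = ";".join(f"{d.drug}:{d.stage}" for d in rec.drugs)
            fh.write(f"{gene}\t{rec.protein_class}\t{str(rec.membrane_localized).upper()}\t{drugs}\n")
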