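"""Relative quantification from Ct tables by the 2^-ddCt method.

Technical replicates are averaged on the Ct scale, each sample's target
Ct is normalized against the housekeeping gene (dCt), referenced to one
control sample taken as unity (ddCt), and expressed as 2^-ddCt.  The
case-vs-control test runs on dCt values (log scale, additive noise);
group means and SEMs are reported on the 2^-ddCt scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError
from .io import CtTable

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeResult:
    """Per-gene relative expression with group summaries."""

    gene: str
    relative_expression: dict[str, float]  # sample -> 2^-ddCt
    control_mean: float
    control_sem: float
    case_mean: float
    case_sem: float
    p: float
    delta_cts: dict[str, float] = field(default_factory=dict)


def delta_ct(ct_table: CtTable) -> dict[tuple[str, str], float]:
    """dCt(sample, gene) = mean target Ct - mean housekeeping Ct.

    Technical replicates are averaged on the Ct scale first.  Samples
    missing a target gene are omitted for that gene with a warning.
    """
    means = (ct_table.records.groupby(["sample", "gene"])["ct"].mean())
    hk = ct_table.housekeeping_gene
    out: dict[tuple[str, str], float] = {}
    for sample in ct_table.samples():
        hk_ct = means.get((sample, hk))
        if hk_ct is None:
            raise ValidationError(f"housekeeping gene missing for sample {sample!r}")
        for gene in ct_table.target_genes():
            target_ct = means.get((sample, gene))
            if target_ct is None:
                logger.warning("no Ct for sample %r, gene %r; omitted", sample, gene)
                continue
            out[(sample, gene)] = float(target_ct - hk_ct)
    return out


def fold_changes(delta_cts: dict[tuple[str, str], float], reference_sample: str,
                 groups: dict[str, str]) -> list[FoldChangeResult]:
    """2^-ddCt per sample relative to the reference, with group means,
    SEMs and a Welch test on the dCt scale (case vs control)."""
    genes = sorted({g for (_s, g) in delta_cts})
    results: list[FoldChangeResult] = []
    for gene in genes:
        per_sample = {s: d for (s, g), d in delta_cts.items() if g == gene}
        if reference_sample not in per_sample:
            raise DomainError(f"reference sample {reference_sample!r} has no dCt for gene {gene!r}")
        ref = per_sample[reference_sample]
        rel = {s: float(2.0 ** -(d - ref)) for s, d in per_sample.items()}
        ctrl = [s for s in per_sample if groups.get(s) == "control"]
        case = [s for s in per_sample if groups.get(s) == "case"]
        ctrl_rel = np.array([rel[s] for s in ctrl])
        case_rel = np.array([rel[s] for s in case])
        ctrl_dct = np.array([per_sample[s] for s in ctrl])
        case_dct = np.array([per_sample[s] for s in case])
        if len(ctrl) >= 2 and len(case) >= 2:
            if ctrl_dct.var(ddof=1) == 0.0 and case_dct.var(ddof=1) == 0.0:
                p = 1.0 if ctrl_dct.mean() == case_dct.mean() else 0.0
            else:
                p = float(stats.ttest_ind(case_dct, ctrl_dct, equal_var=False).pvalue)
        else:
            p = math.nan
        results.append(FoldChangeResult(
            gene=gene,
            relative_expression=rel,
            control_mean=float(ctrl_rel.mean()) if ctrl else math.nan,
            control_sem=_sem(ctrl_rel),
            case_mean=float(case_rel.mean()) if case else math.nan,
            case_sem=_sem(case_rel),
            p=p,
            delta_cts=per_sample,
        ))
    return results


def quantify(ct_table: CtTable) -> list[FoldChangeResult]:
    """Convenience wrapper: delta_ct then fold_changes with the table's
    configured reference sample."""
    if ct_table.reference_sample is None:
        raise DomainError("Ct table has no reference sample configured")
    return fold_changes(delta_ct(ct_table), ct_table.reference_sample, ct_table.groups)


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return math.nan
    return float(values.std(ddof=1) / np.sqrt(values.size))


def write_fold_changes(results: list[FoldChangeResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcontrol_mean\tcontrol_sem\tcase_mean\tcase_sem\tp\n")
        for r in results:
            fh.write(f"{r.gene}\t{r.control_mean:.6g}\t{r.control_sem:.6g}\t"
                     f"{r.case_mean:.6g}\t{r.case_sem:.6g}\t{r.p:.6g}\n")


def read_fold_changes(path) -> list[FoldChangeResult]:
    results: list[FoldChangeResult] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields == [""]:
                continue
            gene, cm, cs, am, asd, p = fields
            results.append(FoldChangeResult(
                gene=gene, relative_expression={},
                control_mean=float(cm), control_sem=float(cs),
                case_mean=float(am), case_sem=float(asd), p=float(p)))
    return results
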