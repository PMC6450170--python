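"""Two-group differential expression with p-value and fold-change gates.

The location test is Welch's unequal-variance two-sample t on log2
intensities.  Fold changes use the signed-ratio convention: for a log2
mean difference d, fc = 2**d when d >= 0 and -(2**-d) otherwise, so no
value lies strictly between -1 and 1 and down-regulation is negative.
Both gates are closed (p <= p_max, |fc| >= fc_min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientReplicationError
from .io import ExpressionMatrix, canonical_symbol

UP = "UP"
DOWN = "DOWN"


@dataclass(frozen=True)
class DEGRecord:
    """One differentially expressed gene: symbol, signed linear fold
    change, two-sided p-value, direction and tissue label."""

    gene: str
    fc: float
    p: float
    direction: str
    tissue: str = ""

    def __post_init__(self) -> None:
        if abs(self.fc) < 1:
            raise ValueError(f"{self.gene}: |fc| must be >= 1, got {self.fc}")
        if not 0 <= self.p <= 1:
            raise ValueError(f"{self.gene}: p must be in [0, 1], got {self.p}")
        expected = UP if self.fc >= 1 else DOWN
        if self.direction != expected:
            raise ValueError(f"{self.gene}: direction {self.direction} inconsistent with fc {self.fc}")


def signed_fold_change(log2_diff: float) -> float:
    """Map a log2 mean difference to the signed linear ratio."""
    if log2_diff >= 0:
        return float(2.0 ** log2_diff)
    return float(-(2.0 ** (-log2_diff)))


def test_gene(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Welch t-test of group A vs group B log2 values.

    Returns (fc, p) where fc is the signed linear fold change of A over
    B.  Both groups need >= 2 finite values.  If both groups have zero
    variance and equal means the result is (1.0, 1.0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicationError(
            f"need >= 2 values per group, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DomainError("non-finite expression values")
    d = float(a.mean() - b.mean())
    fc = signed_fold_change(d)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        p = 1.0 if d == 0.0 else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return fc, p


def call_degs(matrix: ExpressionMatrix, case_group: str, control_group: str,
              p_max: float = 0.05, fc_min: float = 1.1,
              tissue: str = "") -> list[DEGRecord]:
    """Call DEGs (case vs control) under closed p and |fc| gates.

    Probes mapping to one symbol are collapsed before gating: the probe
    with the smallest p wins, ties go to the larger |fc|, remaining ties
    to the lexicographically first probe id.  The result is sorted by p
    ascending (ties by symbol).
    """
    if p_max <= 0 or fc_min <= 0:
        raise DomainError("thresholds must be positive")
    labels = set(matrix.groups.values())
    for grp in (case_group, control_group):
        if grp not in labels:
            raise DomainError(f"unknown group label {grp!r}")
    case_cols = matrix.group_samples(case_group)
    ctrl_cols = matrix.group_samples(control_group)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise InsufficientReplicationError(
            f"need >= 2 samples per group, got {len(case_cols)} and {len(ctrl_cols)}")

    a = matrix.values[case_cols].to_numpy()
    b = matrix.values[ctrl_cols].to_numpy()
    d = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    pvals[degenerate & (d == 0)] = 1.0
    pvals[degenerate & (d != 0)] = 0.0
    fcs = np.where(d >= 0, 2.0 ** d, -(2.0 ** (-d)))

    mapping = matrix.probe_to_gene or {}
    best: dict[str, tuple[float, float, str, float]] = {}
    for probe, fc, p in zip(matrix.genes, fcs, pvals):
        symbol = canonical_symbol(mapping.get(probe, probe))
        key = (p, -abs(fc), str(probe))
        if symbol not in best or key < (best[symbol][0], -abs(best[symbol][1]), best[symbol][2]):
            best[symbol] = (float(p), float(fc), str(probe), float(fc))
    records = [
        DEGRecord(gene=sym, fc=fc, p=p, direction=UP if fc >= 1 else DOWN, tissue=tissue)
        for sym, (p, fc, _probe, _) in best.items()
        if p <= p_max and abs(fc) >= fc_min
    ]
    records.sort(key=lambda r: (r.p, r.gene))
    return records


def write_degs(records: list[DEGRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tfc\tp\tdirection\ttissue\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.fc:.6g}\t{r.p:.6g}\t{r.direction}\t{r.tissue}\n")


def read_degs(path) -> list[DEGRecord]:
    records: list[DEGRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields == [""]:
                continue
            records.append(DEGRecord(
                gene=canonical_symbol(fields[idx["gene"]]),
                fc=float(fields[idx["fc"]]),
                p=float(fields[idx["p"]]),
                direction=fields[idx["direction"]],
                tissue=fields[idx["tissue"]] if "tissue" in idx and len(fields) > idx["tissue"] else "",
            ))
    return records
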