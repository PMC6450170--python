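"""Cross-tissue DEG list intersection with direction concordance."""

from __future__ import annotations

from dataclasses import dataclass, field

from .deg import DEGRecord
from .errors import ValidationError


@dataclass
class OverlapReport:
    """Symbols shared by two DEG lists, split by direction agreement."""

    common: set[str] = field(default_factory=set)
    same_direction: set[str] = field(default_factory=set)
    opposite_direction: set[str] = field(default_factory=set)
    unique_a: int = 0
    unique_b: int = 0
    directions_a: dict[str, str] = field(default_factory=dict)
    directions_b: dict[str, str] = field(default_factory=dict)


def overlap_profiles(degs_a: list[DEGRecord], degs_b: list[DEGRecord]) -> OverlapReport:
    """Intersect two DEG lists by symbol and partition by concordance.

    Each input must carry one record per symbol (probe collapse belongs
    upstream in the DEG caller).
    """
    dir_a = _directions(degs_a, "A")
    dir_b = _directions(degs_b, "B")
    common = set(dir_a) & set(dir_b)
    same = {g for g in common if dir_a[g] == dir_b[g]}
    return OverlapReport(
        common=common,
        same_direction=same,
        opposite_direction=common - same,
        unique_a=len(dir_a) - len(common),
        unique_b=len(dir_b) - len(common),
        directions_a=dir_a,
        directions_b=dir_b,
    )


def _directions(records: list[DEGRecord], label: str) -> dict[str, str]:
    directions: dict[str, str] = {}
    for r in records:
        if r.gene in directions:
            raise ValidationError(f"duplicate symbol {r.gene!r} in list {label}")
        directions[r.gene] = r.direction
    return directions


def write_overlap(report: OverlapReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdirection_a\tdirection_b\tconcordance\n")
        for g in sorted(report.common):
            concordance = "same" if g in report.same_direction else "opposite"
            fh.write(f"{g}\t{report.directions_a[g]}\t{report.directions_b[g]}\t{concordance}\n")
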