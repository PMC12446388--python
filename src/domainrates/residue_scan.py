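"""Reference-anchored residue scan.

Locates the alignment column homologous to a reference residue (position 878
on the human sequence by default), classifies each taxon's residue there as
V / G / other / gap, and tabulates the calls per clade group together with
the curated thermal-sensitivity labels.  Concordance is reported as counts
only; no significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import CoordinateError, ValidationError
from .io import GAP, Alignment, CladeGroupTable, DomainMap, ThermalAnnotation
from .domain_rates import map_reference_columns, slice_region

DEFAULT_POSITION = 878
CALL_CLASSES = ("V", "G", "other", "gap")


@dataclass(frozen=True)
class ResidueCall:
    taxon_id: str
    reference_position: int
    alignment_column: int  # 1-based
    residue: str
    call_class: str

    def __post_init__(self) -> None:
        if self.call_class not in CALL_CLASSES:
            raise ValidationError(f"bad call_class {self.call_class!r}")


def _classify(residue: str) -> str:
    if residue == GAP:
        return "gap"
    if residue in ("V", "G"):
        return residue
    return "other"


def call_reference_residue(
    alignment: Alignment,
    reference_taxon: str,
    position: int = DEFAULT_POSITION,
) -> list[ResidueCall]:
    """One call per taxon at the column homologous to the reference position."""
    colmap = map_reference_columns(alignment, reference_taxon)
    if not (1 <= position <= len(colmap)):
        raise CoordinateError(
            f"position {position} outside reference ungapped length {len(colmap)}"
        )
    column = colmap[position]
    calls = []
    for row in alignment.rows:
        residue = row.residues[column - 1]
        calls.append(
            ResidueCall(row.taxon_id, position, column, residue, _classify(residue))
        )
    return calls


@dataclass(frozen=True)
class ResidueByCladeRow:
    group_id: int
    group_name: str
    n_V: int
    n_G: int
    n_other: int
    n_gap: int
    thermal_label: str

    @property
    def total(self) -> int:
        return self.n_V + self.n_G + self.n_other + self.n_gap


class ResidueByCladeTable:
    """Per-group call counts with thermal labels, ordered by group_id."""

    def __init__(self, rows: Sequence[ResidueByCladeRow]):
        self.rows = sorted(rows, key=lambda r: r.group_id)

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, group_id: int) -> ResidueByCladeRow:
        for r in self.rows:
            if r.group_id == group_id:
                return r
        raise KeyError(group_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.group_id, r.group_name, r.n_V, r.n_G, r.n_other, r.n_gap, r.thermal_label)
                for r in self.rows
            ],
            columns=["group_id", "group_name", "n_V", "n_G", "n_other", "n_gap", "thermal_label"],
        )

    def to_tsv(self, metadata: dict[str, str] | None = None) -> str:
        lines = [f"# {k}={v}" for k, v in sorted((metadata or {}).items())]
        lines.append("group_id\tgroup_name\tn_V\tn_G\tn_other\tn_gap\tthermal_label")
        for r in self.rows:
            lines.append(
                f"{r.group_id}\t{r.group_name}\t{r.n_V}\t{r.n_G}\t{r.n_other}"
                f"\t{r.n_gap}\t{r.thermal_label}"
            )
        return "\n".join(lines) + "\n"


def tabulate_by_clade(
    calls: Iterable[ResidueCall],
    clade_groups: CladeGroupTable,
    thermal_annotation: ThermalAnnotation | None = None,
) -> ResidueByCladeTable:
    """Aggregate calls into per-clade-group counts with thermal labels."""
    thermal = thermal_annotation or ThermalAnnotation({})
    counts: dict[int, dict[str, int]] = {}
    for call in calls:
        gid = clade_groups.group_of(call.taxon_id)  # raises naming the taxon
        counts.setdefault(gid, {c: 0 for c in CALL_CLASSES})[call.call_class] += 1
    rows = [
        ResidueByCladeRow(
            gid,
            clade_groups.group_name(gid),
            c["V"],
            c["G"],
            c["other"],
            c["gap"],
            thermal.label(gid),
        )
        for gid, c in counts.items()
    ]
    return ResidueByCladeTable(rows)


def extract_region_alignment(
    alignment: Alignment, domain_map: DomainMap, region: str = "S5"
) -> Alignment:
    """Sliced sub-alignment of a display region (the S5 helix by default)."""
    return slice_region(alignment, domain_map, region)


def calls_to_tsv(calls: Iterable[ResidueCall], metadata: dict[str, str] | None = None) -> str:
    lines = [f"# {k}={v}" for k, v in sorted((metadata or {}).items())]
    lines.append("taxon_id\treference_position\talignment_column\tresidue\tcall_class")
    for c in calls:
        lines.append(
            f"{c.taxon_id}\t{c.reference_position}\t{c.alignment_column}"
            f"\t{c.residue}\t{c.call_class}"
        )
    return "\n".join(lines) + "\n"
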