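"""Readers, writers and validated domain types for all external formats.

Sequence data travel as FASTA / aligned FASTA, trees as Newick (via dendropy),
annotation tables as tab-separated text with a header row, and the domain map
as a small YAML document.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
import yaml

from .errors import (
    AlignmentShapeError,
    CoordinateError,
    ParseError,
    ValidationError,
)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
MISSING = "X"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + GAP + MISSING)

_REQUIRED_REGIONS = ("full_length", "ARD1_9", "ARD10_16_linker", "S1_S6_COOH")


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence; residues are uppercase over the 20 amino acids
    plus gap ``-`` and unknown ``X``."""

    taxon_id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValidationError("taxon_id must be non-empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"record {self.taxon_id!r} contains invalid residue "
                f"characters {sorted(bad)}"
            )

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


class Alignment:
    """Equal-length gapped rows keyed by taxon.

    Invariants enforced on construction: at least two rows, all rows the same
    length, no all-gap column, unique taxon ids.
    """

    def __init__(self, rows: Sequence[SequenceRecord]):
        rows = list(rows)
        if len(rows) < 2:
            raise ValidationError("alignment needs at least 2 rows")
        ncol = len(rows[0].residues)
        ragged = [r.taxon_id for r in rows if len(r.residues) != ncol]
        if ragged:
            raise AlignmentShapeError(
                f"rows with length differing from {ncol}: {ragged}"
            )
        seen = set()
        for r in rows:
            if r.taxon_id in seen:
                raise ValidationError(f"duplicate taxon_id {r.taxon_id!r}")
            seen.add(r.taxon_id)
        for j in range(ncol):
            if all(r.residues[j] == GAP for r in rows):
                raise ValidationError(f"column {j + 1} is all-gap")
        self.rows: list[SequenceRecord] = rows
        self.ncol: int = ncol
        self._index = {r.taxon_id: r for r in rows}

    @property
    def taxa(self) -> list[str]:
        return [r.taxon_id for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, taxon_id: str) -> SequenceRecord:
        try:
            return self._index[taxon_id]
        except KeyError:
            raise KeyError(f"taxon {taxon_id!r} not in alignment") from None

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.rows == other.rows

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """New alignment from 0-based column indices, dropping columns that
        become all-gap.  The drop count is stored on ``dropped_columns``."""
        kept, dropped = [], 0
        for j in columns:
            if all(r.residues[j] == GAP for r in self.rows):
                dropped += 1
            else:
                kept.append(j)
        out = Alignment(
            [
                SequenceRecord(
                    r.taxon_id,
                    "".join(r.residues[j] for j in kept),
                    r.description,
                )
                for r in self.rows
            ]
        )
        out.dropped_columns = dropped  # type: ignore[attr-defined]
        return out


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Strict FASTA reader.

    Deliberately not delegated to a lenient library parser: the contract here
    requires errors that name the offending line and rejection of duplicate
    ids at parse time.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        assert header is not None
        name, _, desc = header.partition(" ")
        if not name:
            raise ParseError(f"{path}:{header_line}: empty FASTA header")
        if name in seen:
            raise ParseError(f"{path}:{header_line}: duplicate taxon id {name!r}")
        seen.add(name)
        records.append(SequenceRecord(name, "".join(chunks).upper(), desc.strip()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(";"):
                continue
            if line.startswith(">"):
                if header is not None:
                    flush()
                header, header_line, chunks = line[1:].strip(), lineno, []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                if any(c.isspace() for c in line):
                    raise ParseError(f"{path}:{lineno}: whitespace inside residues")
                chunks.append(line)
    if header is None:
        raise ParseError(f"{path}: empty FASTA file")
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.taxon_id if not rec.description else f"{rec.taxon_id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    return Alignment(read_fasta(path))


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    write_fasta(alignment.rows, path)


# ---------------------------------------------------------------------------
# clade groups and thermal labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeGroupEntry:
    group_id: int
    group_name: str
    superorder: str


class CladeGroupTable:
    """Mapping taxon_id -> (group_id 1..26, group_name, superorder)."""

    MIN_GROUP, MAX_GROUP = 1, 26

    def __init__(self, entries: Mapping[str, CladeGroupEntry]):
        for taxon, e in entries.items():
            if not (self.MIN_GROUP <= e.group_id <= self.MAX_GROUP):
                raise ValidationError(
                    f"taxon {taxon!r}: group_id {e.group_id} outside "
                    f"[{self.MIN_GROUP}, {self.MAX_GROUP}]"
                )
        self.entries: dict[str, CladeGroupEntry] = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.entries

    def group_of(self, taxon_id: str) -> int:
        try:
            return self.entries[taxon_id].group_id
        except KeyError:
            raise ValidationError(f"taxon {taxon_id!r} absent from clade table") from None

    def group_name(self, group_id: int) -> str:
        for e in self.entries.values():
            if e.group_id == group_id:
                return e.group_name
        raise ValidationError(f"no taxon assigned to group {group_id}")

    def group_ids(self) -> list[int]:
        return sorted({e.group_id for e in self.entries.values()})

    def members(self, group_id: int) -> list[str]:
        return [t for t, e in self.entries.items() if e.group_id == group_id]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (t, e.group_id, e.group_name, e.superorder)
                for t, e in self.entries.items()
            ],
            columns=["taxon_id", "group_id", "group_name", "superorder"],
        )


def load_clade_groups(path: str | Path) -> CladeGroupTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"taxon_id", "group_id", "group_name", "superorder"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: clade table must have columns {sorted(required)}"
        )
    entries: dict[str, CladeGroupEntry] = {}
    for _, row in df.iterrows():
        taxon = str(row["taxon_id"])
        if taxon in entries:
            raise ValidationError(f"{path}: taxon {taxon!r} assigned more than once")
        try:
            gid = int(row["group_id"])
        except ValueError:
            raise ValidationError(
                f"{path}: non-integer group_id {row['group_id']!r} for {taxon!r}"
            ) from None
        entries[taxon] = CladeGroupEntry(gid, str(row["group_name"]), str(row["superorder"]))
    return CladeGroupTable(entries)


THERMAL_LABELS = ("heat", "cold", "insensitive", "unknown")


class ThermalAnnotation:
    """Per-group thermal-sensitivity label; missing groups read as unknown."""

    def __init__(self, labels: Mapping[int, str]):
        for gid, label in labels.items():
            if label not in THERMAL_LABELS:
                raise ValidationError(
                    f"group {gid}: label {label!r} not one of {THERMAL_LABELS}"
                )
        self.labels: dict[int, str] = dict(labels)

    def label(self, group_id: int) -> str:
        return self.labels.get(group_id, "unknown")

    def validate_against(self, clade_groups: CladeGroupTable) -> None:
        known = set(clade_groups.group_ids())
        orphans = sorted(set(self.labels) - known)
        if orphans:
            raise ValidationError(
                f"thermal labels reference group_ids with no taxa: {orphans}"
            )


def load_thermal_labels(path: str | Path) -> ThermalAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"group_id", "label"}.issubset(df.columns):
        raise ParseError(f"{path}: thermal table needs columns group_id, label")
    return ThermalAnnotation(
        {int(r["group_id"]): str(r["label"]) for _, r in df.iterrows()}
    )


# ---------------------------------------------------------------------------
# domain map
# ---------------------------------------------------------------------------

Interval = tuple[int, int]


@dataclass
class DomainMap:
    """Named regions as 1-based inclusive intervals on the ungapped reference.

    ``ard_annotation`` is an optional finer-grained listing of the individual
    ankyrin repeats; it is informational and not used for slicing.
    """

    reference_taxon: str
    reference_length: int
    regions: dict[str, list[Interval]]
    ard_annotation: dict[str, Interval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_length < 1:
            raise ValidationError("reference_length must be positive")
        if "full_length" not in self.regions:
            self.regions["full_length"] = [(1, self.reference_length)]
        for name, intervals in self.regions.items():
            self._check_intervals(name, intervals)
        if self.ard_annotation:
            for name, iv in self.ard_annotation.items():
                self._check_intervals(f"ard_annotation/{name}", [iv])

    def _check_intervals(self, name: str, intervals: Sequence[Interval]) -> None:
        if not intervals:
            raise ValidationError(f"region {name!r} has no intervals")
        prev_end = 0
        for start, end in intervals:
            if not (1 <= start <= end <= self.reference_length):
                raise CoordinateError(
                    f"region {name!r}: interval ({start}, {end}) outside "
                    f"[1, {self.reference_length}]"
                )
            if start <= prev_end:
                raise ValidationError(
                    f"region {name!r}: intervals overlap or are unsorted at "
                    f"({start}, {end})"
                )
            prev_end = end

    def region_positions(self, region_name: str) -> list[int]:
        """All reference positions (1-based) covered by the region, in order."""
        if region_name not in self.regions:
            raise CoordinateError(f"region {region_name!r} not in domain map")
        out: list[int] = []
        for start, end in self.regions[region_name]:
            out.extend(range(start, end + 1))
        return out


def load_domain_map(path: str | Path) -> DomainMap:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: domain map must be a YAML mapping")
    try:
        reference_taxon = str(doc["reference_taxon"])
        reference_length = int(doc["reference_length"])
        raw_regions = doc["regions"]
    except KeyError as exc:
        raise ParseError(f"{path}: missing domain-map key {exc}") from None
    regions = {
        str(name): [(int(a), int(b)) for a, b in intervals]
        for name, intervals in raw_regions.items()
    }
    ard = {
        str(name): (int(iv[0]), int(iv[1]))
        for name, iv in (doc.get("ard_annotation") or {}).items()
    }
    return DomainMap(reference_taxon, reference_length, regions, ard)


# ---------------------------------------------------------------------------
# trees (Newick via dendropy)
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"{path}: Newick parse failed: {exc}") from exc
    return tree


def newick_string(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        ).strip()
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# packaged defaults
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("domainrates").joinpath("data", name)))


def default_clade_groups() -> CladeGroupTable:
    """The packaged 26-group vertebrate clade table."""
    return load_clade_groups(_data_path("clade_groups.tsv"))


def default_thermal_labels() -> ThermalAnnotation:
    return load_thermal_labels(_data_path("thermal_labels.tsv"))


def default_domain_map() -> DomainMap:
    """Packaged human TRPA1 domain map (illustrative interval boundaries)."""
    return load_domain_map(_data_path("domain_map.yaml"))


def default_climate_table_path() -> Path:
    return _data_path("climate_table1.tsv")
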