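"""Marker panels, haplotype table I/O, allele canonicalization and anomaly QC.

The haplotype table dialect is UTF-8, tab-delimited, with a required header
row naming ``sample_id``, ``population``, optional ``region`` and
``haplogroup`` columns, and one column per marker.  Dual-copy markers carry
two hyphen-joined repeat values ("11-14"), a duplication at a single-copy
marker is comma-joined ("15,16"), a null allele is "-" (or empty), and
microvariant alleles use a decimal point ("17.2").
"""

from __future__ import annotations

import csv
import io
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence, TextIO, Union

__all__ = [
    "PanelError",
    "TableParseError",
    "AlleleRange",
    "LocusDefinition",
    "LocusPanel",
    "Allele",
    "Anomaly",
    "AnomalyCount",
    "HaplotypeRecord",
    "PopulationSample",
    "BUILTIN_PANELS",
    "RAPIDLY_MUTATING_DEFAULT",
    "build_panel",
    "parse_haplotype_table",
    "write_haplotype_table",
    "flag_anomalies",
    "derive_anomalies",
    "haplotype_key",
    "format_repeat",
]


class PanelError(ValueError):
    """Unknown panel, marker, or inconsistent panel definition."""


class TableParseError(ValueError):
    """Malformed haplotype table; carries 1-based row/column coordinates."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        prefix = ", ".join(loc)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.row = row
        self.column = column


# ---------------------------------------------------------------------------
# panel definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleRange:
    """Inclusive plausible repeat-count range used for validation."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise PanelError(f"allele range must satisfy lo < hi, got ({self.lo}, {self.hi})")

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


#: Default rapidly-mutating single-copy marker set (config-overridable).
RAPIDLY_MUTATING_DEFAULT = frozenset(
    {"DYS576", "DYS627", "DYS570", "DYS518", "DYS449", "DYS460", "DYS533", "DYS389II"}
)


@dataclass(frozen=True)
class LocusDefinition:
    name: str
    copy_number: int = 1
    mutation_class: str = "standard"
    allele_range: AlleleRange = AlleleRange(5.0, 50.0)

    def __post_init__(self) -> None:
        if self.copy_number not in (1, 2):
            raise PanelError(f"{self.name}: copy_number must be 1 or 2, got {self.copy_number}")
        if self.mutation_class not in ("standard", "rapidly_mutating"):
            raise PanelError(f"{self.name}: unknown mutation_class {self.mutation_class!r}")


@dataclass(frozen=True)
class LocusPanel:
    """Ordered marker catalogue defining table layout and analysis subsets."""

    name: str
    loci: tuple[LocusDefinition, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise PanelError(f"panel {self.name!r}: duplicate marker names")
        if not self.loci:
            raise PanelError(f"panel {self.name!r}: no loci")

    @property
    def value_count(self) -> int:
        return sum(l.copy_number for l in self.loci)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    def __contains__(self, marker: str) -> bool:
        return any(l.name == marker for l in self.loci)

    def __iter__(self) -> Iterator[LocusDefinition]:
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, marker: str) -> LocusDefinition:
        for l in self.loci:
            if l.name == marker:
                return l
        raise PanelError(f"marker {marker!r} not in panel {self.name!r}")

    def single_copy(self, name: str | None = None) -> "LocusPanel":
        return LocusPanel(
            name or f"{self.name}_single_copy",
            tuple(l for l in self.loci if l.copy_number == 1),
        )

    def subset(self, markers: Sequence[str], name: str | None = None) -> "LocusPanel":
        missing = [m for m in markers if m not in self]
        if missing:
            raise PanelError(f"markers not in panel {self.name!r}: {missing}")
        keep = set(markers)
        return LocusPanel(
            name or f"{self.name}_subset",
            tuple(l for l in self.loci if l.name in keep),
        )


# Yfiler Plus marker order; dual-copy markers flagged with copy_number 2.
_YFILER_PLUS = [
    # (name, copy_number, (lo, hi))
    ("DYS576", 1, (11, 25)),
    ("DYS389I", 1, (9, 17)),
    ("DYS635", 1, (15, 28)),
    ("DYS389II", 1, (24, 36)),
    ("DYS627", 1, (11, 27)),
    ("DYS460", 1, (7, 14)),
    ("DYS458", 1, (12, 24)),
    ("DYS19", 1, (10, 19)),
    ("YGATAH4", 1, (8, 15)),
    ("DYS448", 1, (14, 24)),
    ("DYS391", 1, (6, 14)),
    ("DYS456", 1, (11, 20)),
    ("DYS390", 1, (17, 28)),
    ("DYS438", 1, (6, 14)),
    ("DYS392", 1, (6, 18)),
    ("DYS518", 1, (32, 49)),
    ("DYS570", 1, (10, 26)),
    ("DYS437", 1, (12, 18)),
    ("DYS385", 2, (7, 28)),
    ("DYS449", 1, (22, 36)),
    ("DYS393", 1, (9, 17)),
    ("DYS439", 1, (8, 15)),
    ("DYS481", 1, (17, 32)),
    ("DYF387S1", 2, (30, 44)),
    ("DYS533", 1, (7, 17)),
]

_YFILER_17_MARKERS = (
    "DYS389I",
    "DYS635",
    "DYS389II",
    "DYS458",
    "DYS19",
    "YGATAH4",
    "DYS448",
    "DYS391",
    "DYS456",
    "DYS390",
    "DYS438",
    "DYS392",
    "DYS437",
    "DYS385",
    "DYS393",
    "DYS439",
)


def _make_yfiler_plus() -> LocusPanel:
    loci = tuple(
        LocusDefinition(
            name,
            copy_number=cn,
            mutation_class=(
                "rapidly_mutating" if name in RAPIDLY_MUTATING_DEFAULT else "standard"
            ),
            allele_range=AlleleRange(float(lo), float(hi)),
        )
        for name, cn, (lo, hi) in _YFILER_PLUS
    )
    return LocusPanel("yfiler_plus_27", loci)


def _make_single_copy_23() -> LocusPanel:
    return _make_yfiler_plus().single_copy("single_copy_23")


def _make_yfiler_17() -> LocusPanel:
    return _make_yfiler_plus().subset(_YFILER_17_MARKERS, "yfiler_17")


BUILTIN_PANELS = {
    "yfiler_plus_27": _make_yfiler_plus,
    "single_copy_23": _make_single_copy_23,
    "yfiler_17": _make_yfiler_17,
}


def build_panel(name: str) -> LocusPanel:
    """Return a built-in panel by name, or load one from a TSV config path.

    A panel config is a tab-delimited file with header
    ``marker  copy_number  mutation_class  min  max``; the panel name is the
    file stem.
    """
    if name in BUILTIN_PANELS:
        return BUILTIN_PANELS[name]()
    if os.path.exists(name):
        return _load_panel_config(Path(name))
    raise PanelError(
        f"unknown panel {name!r}; built-ins: {', '.join(sorted(BUILTIN_PANELS))}"
    )


def _load_panel_config(path: Path) -> LocusPanel:
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"marker", "copy_number", "mutation_class", "min", "max"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise PanelError(f"panel config {path}: header must contain {sorted(required)}")
        loci = []
        for row in reader:
            loci.append(
                LocusDefinition(
                    row["marker"],
                    copy_number=int(row["copy_number"]),
                    mutation_class=row["mutation_class"],
                    allele_range=AlleleRange(float(row["min"]), float(row["max"])),
                )
            )
    return LocusPanel(path.stem, tuple(loci))


def write_panel_config(panel: LocusPanel, dest: Union[str, Path, TextIO]) -> None:
    fh, close = _open_out(dest)
    try:
        fh.write("marker\tcopy_number\tmutation_class\tmin\tmax\n")
        for l in panel.loci:
            fh.write(
                f"{l.name}\t{l.copy_number}\t{l.mutation_class}"
                f"\t{l.allele_range.lo:g}\t{l.allele_range.hi:g}\n"
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# alleles
# ---------------------------------------------------------------------------

_MICROVARIANT_TENTHS = (1, 2, 3)


def _tenths(value: float) -> int:
    return round(value * 10)


def _canonical(value: float) -> float:
    # repeat values carry at most one decimal digit
    return _tenths(value) / 10.0


def format_repeat(value: float) -> str:
    t = _tenths(value)
    if t % 10 == 0:
        return str(t // 10)
    return f"{t // 10}.{t % 10}"


def _parse_repeat(token: str, row: int | None = None, column: str | None = None) -> float:
    try:
        value = float(token)
    except ValueError:
        raise TableParseError(f"unparseable allele token {token!r}", row, column) from None
    if value <= 0:
        raise TableParseError(f"non-positive repeat count {token!r}", row, column)
    frac = _tenths(value) % 10
    if frac not in (0, *_MICROVARIANT_TENTHS):
        raise TableParseError(
            f"microvariant fraction of {token!r} not in .1/.2/.3", row, column
        )
    return _canonical(value)


@dataclass(frozen=True, order=True)
class Allele:
    """Allele state at one marker: present, null, or duplicated.

    ``values`` holds canonicalized repeat counts: one value for a plain
    single-copy allele, two (nondecreasing) for a dual-copy pair or a
    duplication, none for a null.
    """

    kind: str
    values: tuple[float, ...] = ()

    @classmethod
    def present(cls, value: float) -> "Allele":
        return cls("present", (_canonical(value),))

    @classmethod
    def pair(cls, a: float, b: float) -> "Allele":
        return cls("present", tuple(sorted((_canonical(a), _canonical(b)))))

    @classmethod
    def null(cls) -> "Allele":
        return cls("null", ())

    @classmethod
    def duplicated(cls, a: float, b: float) -> "Allele":
        return cls("duplicated", tuple(sorted((_canonical(a), _canonical(b)))))

    @property
    def is_null(self) -> bool:
        return self.kind == "null"

    @property
    def is_duplicated(self) -> bool:
        return self.kind == "duplicated"

    @property
    def is_microvariant(self) -> bool:
        return any(_tenths(v) % 10 != 0 for v in self.values)

    def to_token(self, copy_number: int = 1) -> str:
        if self.is_null:
            return "-"
        if self.is_duplicated:
            return ",".join(format_repeat(v) for v in self.values)
        if copy_number == 2:
            return "-".join(format_repeat(v) for v in self.values)
        return format_repeat(self.values[0])

    @classmethod
    def parse(
        cls,
        token: str,
        copy_number: int = 1,
        row: int | None = None,
        column: str | None = None,
    ) -> "Allele":
        t = token.strip()
        if t in ("", "-"):
            return cls.null()
        if copy_number == 2:
            parts = t.split("-")
            if len(parts) != 2:
                raise TableParseError(
                    f"dual-copy allele must be two hyphen-joined values, got {t!r}",
                    row,
                    column,
                )
            return cls.pair(
                _parse_repeat(parts[0], row, column), _parse_repeat(parts[1], row, column)
            )
        if "," in t:
            parts = t.split(",")
            if len(parts) != 2:
                raise TableParseError(
                    f"duplication must be two comma-joined values, got {t!r}", row, column
                )
            return cls.duplicated(
                _parse_repeat(parts[0], row, column), _parse_repeat(parts[1], row, column)
            )
        return cls.present(_parse_repeat(t, row, column))


# ---------------------------------------------------------------------------
# records and samples
# ---------------------------------------------------------------------------

class Anomaly(NamedTuple):
    locus: str
    kind: str  # microvariant | duplication | null


class AnomalyCount(NamedTuple):
    locus: str
    kind: str
    count: int
    sample_ids: tuple[str, ...]


@dataclass(frozen=True)
class HaplotypeRecord:
    sample_id: str
    population: str
    alleles: Mapping[str, Allele]
    region: str | None = None
    haplogroup: str | None = None
    anomalies: tuple[Anomaly, ...] = ()

    def allele(self, marker: str) -> Allele:
        return self.alleles[marker]


def derive_anomalies(alleles: Mapping[str, Allele], panel: LocusPanel) -> tuple[Anomaly, ...]:
    """Anomaly flags are a pure function of the allele states."""
    out: list[Anomaly] = []
    for locus in panel:
        a = alleles[locus.name]
        if a.is_microvariant:
            out.append(Anomaly(locus.name, "microvariant"))
        if a.is_duplicated:
            out.append(Anomaly(locus.name, "duplication"))
        if a.is_null:
            out.append(Anomaly(locus.name, "null"))
    return tuple(out)


@dataclass(frozen=True)
class PopulationSample:
    name: str
    panel: LocusPanel
    records: tuple[HaplotypeRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"sample {self.name!r} is empty")
        for rec in self.records:
            for locus in self.panel:
                if locus.name not in rec.alleles:
                    raise ValueError(
                        f"record {rec.sample_id!r} lacks marker {locus.name!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HaplotypeRecord]:
        return iter(self.records)

    def split_by(self, attribute: str = "population") -> dict[str, "PopulationSample"]:
        """Partition into sub-samples keyed by a record attribute.

        Groups are ordered by first appearance; records with a None value for
        the attribute raise.
        """
        groups: dict[str, list[HaplotypeRecord]] = {}
        for rec in self.records:
            value = getattr(rec, attribute)
            if value is None:
                raise ValueError(
                    f"record {rec.sample_id!r} has no value for {attribute!r}"
                )
            groups.setdefault(value, []).append(rec)
        return {
            key: PopulationSample(key, self.panel, tuple(recs))
            for key, recs in groups.items()
        }


def haplotype_key(record: HaplotypeRecord, panel: LocusPanel) -> str:
    """Canonical full haplotype string; identity includes microvariants,
    duplications and nulls, and is invariant to dual-copy pair order."""
    return "|".join(
        record.alleles[l.name].to_token(l.copy_number) for l in panel
    )


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_ID_COL = "sample_id"
_POP_COL = "population"
_REGION_COL = "region"
_HG_COL = "haplogroup"


def _open_in(source: Union[str, Path, TextIO]):
    if isinstance(source, (str, Path)):
        return open(source, encoding="utf-8", newline=""), True
    return source, False


def _open_out(dest: Union[str, Path, TextIO]):
    if isinstance(dest, (str, Path)):
        return open(dest, "w", encoding="utf-8", newline=""), True
    return dest, False


def parse_haplotype_table(
    source: Union[str, Path, TextIO],
    panel: LocusPanel,
    name: str = "sample",
    strict: bool = False,
) -> PopulationSample:
    """Parse a tab-delimited haplotype table against a panel.

    Allele values outside a locus' plausible range produce a warning by
    default and an error under ``strict`` (real microvariants can exceed
    naive ranges).
    """
    fh, close = _open_in(source)
    try:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableParseError("empty table") from None
        header = [h.strip() for h in header]
        for required in (_ID_COL, _POP_COL):
            if required not in header:
                raise TableParseError(f"missing required column {required!r}")
        missing = [m for m in panel.marker_names if m not in header]
        if missing:
            raise TableParseError(f"missing marker columns: {missing}")
        col = {h: i for i, h in enumerate(header)}

        records: list[HaplotypeRecord] = []
        for row_num, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < len(header):
                row = row + [""] * (len(header) - len(row))

            def cell(column: str) -> str:
                return row[col[column]].strip() if column in col else ""

            alleles: dict[str, Allele] = {}
            for locus in panel:
                token = row[col[locus.name]]
                allele = Allele.parse(token, locus.copy_number, row_num, locus.name)
                for v in allele.values:
                    if not locus.allele_range.contains(v):
                        msg = (
                            f"row {row_num}, column {locus.name!r}: allele "
                            f"{format_repeat(v)} outside plausible range "
                            f"[{locus.allele_range.lo:g}, {locus.allele_range.hi:g}]"
                        )
                        if strict:
                            raise TableParseError(
                                f"allele {format_repeat(v)} outside plausible range",
                                row_num,
                                locus.name,
                            )
                        warnings.warn(msg, stacklevel=2)
                alleles[locus.name] = allele

            records.append(
                HaplotypeRecord(
                    sample_id=cell(_ID_COL),
                    population=cell(_POP_COL),
                    region=cell(_REGION_COL) or None,
                    haplogroup=cell(_HG_COL) or None,
                    alleles=alleles,
                    anomalies=derive_anomalies(alleles, panel),
                )
            )
    finally:
        if close:
            fh.close()
    return PopulationSample(name, panel, tuple(records))


def write_haplotype_table(sample: PopulationSample, dest: Union[str, Path, TextIO]) -> None:
    """Emit the sample in the table dialect; round-trips through the parser."""
    fh, close = _open_out(dest)
    try:
        has_region = any(r.region is not None for r in sample.records)
        has_hg = any(r.haplogroup is not None for r in sample.records)
        header = [_ID_COL, _POP_COL]
        if has_region:
            header.append(_REGION_COL)
        if has_hg:
            header.append(_HG_COL)
        header.extend(sample.panel.marker_names)
        fh.write("\t".join(header) + "\n")
        for rec in sample.records:
            fields = [rec.sample_id, rec.population]
            if has_region:
                fields.append(rec.region or "")
            if has_hg:
                fields.append(rec.haplogroup or "")
            fields.extend(
                rec.alleles[l.name].to_token(l.copy_number) for l in sample.panel
            )
            fh.write("\t".join(fields) + "\n")
    finally:
        if close:
            fh.close()


def flag_anomalies(sample: PopulationSample) -> list[AnomalyCount]:
    """Aggregate anomaly flags per (locus, kind), in panel order then kind."""
    agg: dict[tuple[str, str], list[str]] = {}
    for rec in sample.records:
        for anomaly in rec.anomalies:
            agg.setdefault((anomaly.locus, anomaly.kind), []).append(rec.sample_id)
    order = {name: i for i, name in enumerate(sample.panel.marker_names)}
    return [
        AnomalyCount(locus, kind, len(ids), tuple(ids))
        for (locus, kind), ids in sorted(
            agg.items(), key=lambda kv: (order[kv[0][0]], kv[0][1])
        )
    ]
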