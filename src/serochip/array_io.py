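"""Reading and writing spot-level two-channel array tables.

The on-disk dialect is a minimal GenePix-Results-like tab-delimited format:
optional ``key=value`` metadata lines, then a header row naming at least
``Block``, ``Column``, ``Row``, ``Name``, ``F635 Median``, ``F532 Median``
and ``Flags``, then one row per printed spot.  Both the space and underscore
spellings of the channel columns are accepted, unknown columns are ignored,
and parsing never drops rows — flagged spots survive with their flag intact
(filtering is a downstream processing decision, not a parsing one).

A *slide manifest* (YAML or CSV) maps each file to its slide, array position,
serum (or MOCK), day and serum dilution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import GPRFormatError, LayoutValidationError
from .layout import ArrayLayout, UNMAPPED

#: Sentinel serum label for mock (buffer + secondary antibody only) arrays.
MOCK = "MOCK"

_HEADER_ALIASES = {
    "block": "block",
    "column": "column",
    "row": "row",
    "name": "name",
    "id": "id",
    "f635 median": "red_median",
    "f635_median": "red_median",
    "f532 median": "green_median",
    "f532_median": "green_median",
    "flags": "flag",
    "replicate_index": "replicate_index",
}

_REQUIRED = ("block", "column", "row", "name", "red_median", "green_median", "flag")


@dataclass(frozen=True)
class SpotRecord:
    """One printed spot: grid position, label, channels, QC flag.

    ``red_median``/``green_median`` are the median foreground intensities at
    635 nm and 532 nm in arbitrary scanner units (>= 0).  Negative flag
    values mark bad / absent spots, following scanner convention.
    """

    block: int
    column: int
    row: int
    name: str
    replicate_index: int
    red_median: float
    green_median: float
    flag: int = 0

    def __post_init__(self) -> None:
        if self.red_median < 0 or self.green_median < 0:
            raise LayoutValidationError(
                f"negative intensity at ({self.block},{self.column},{self.row})"
            )
        if min(self.block, self.column, self.row, self.replicate_index) < 1:
            raise LayoutValidationError("grid coordinates and replicate index are 1-based")

    @property
    def position(self) -> tuple[int, int, int]:
        return (self.block, self.column, self.row)

    @property
    def flagged(self) -> bool:
        return self.flag < 0


@dataclass(frozen=True)
class ArrayMeta:
    """Experimental-design coordinates of one array."""

    slide_id: str = ""
    array_position: int = 1
    serum_id: str | None = None  # None for mock arrays
    day: str = ""
    dilution: float = 0.25

    @property
    def is_mock(self) -> bool:
        return self.serum_id is None


@dataclass
class ArrayScan:
    """All spots of one scanned array plus its design metadata."""

    spots: list[SpotRecord]
    meta: ArrayMeta = field(default_factory=ArrayMeta)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for s in self.spots:
            if s.position in seen:
                raise LayoutValidationError(f"duplicate grid position {s.position}")
            seen.add(s.position)

    def to_frame(self) -> pd.DataFrame:
        """Spot table as a DataFrame (one row per spot)."""
        return pd.DataFrame(
            {
                "block": [s.block for s in self.spots],
                "column": [s.column for s in self.spots],
                "row": [s.row for s in self.spots],
                "name": [s.name for s in self.spots],
                "replicate_index": [s.replicate_index for s in self.spots],
                "red_median": [s.red_median for s in self.spots],
                "green_median": [s.green_median for s in self.spots],
                "flag": [s.flag for s in self.spots],
            }
        )

    def __len__(self) -> int:
        return len(self.spots)


def _fmt_number(x: float) -> str:
    """Shortest decimal text that round-trips the value (ints stay ints)."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def read_gpr(path: str | Path, layout: ArrayLayout | None = None) -> ArrayScan:
    """Read one tab-delimited spot table.

    Metadata lines of the form ``key=value`` before the header are captured
    into :class:`ArrayMeta`.  If *layout* is given, spot labels are resolved
    against it; unknown labels are retained (role ``unmapped``) rather than
    dropped.  A ``replicate_index`` column is honoured if present, otherwise
    indices are assigned by order of appearance per label.
    """
    path = Path(path)
    meta_kv: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if header is None:
                if "\t" in line and line.split("\t")[0].strip().lower() in ("block",):
                    header = [c.strip() for c in line.split("\t")]
                    continue
                if "=" in line and line.strip():
                    key, _, value = line.partition("=")
                    meta_kv[key.strip()] = value.strip()
                    continue
                if not line.strip():
                    continue
                raise GPRFormatError(f"{path}: unexpected pre-header line: {line!r}")
            else:
                if not line.strip():
                    continue
                rows.append(dict(zip(header, line.split("\t"))))
    if header is None:
        raise GPRFormatError(f"{path}: no header row found")

    colmap: dict[str, str] = {}
    for col in header:
        canon = _HEADER_ALIASES.get(col.strip().lower())
        if canon is not None and canon not in colmap.values():
            colmap[col] = canon
    present = set(colmap.values())
    for need in _REQUIRED:
        if need not in present:
            raise GPRFormatError(f"{path}: missing mandatory column {need!r}")

    counters: dict[str, int] = {}
    spots: list[SpotRecord] = []
    for row in rows:
        rec = {canon: row.get(col, "") for col, canon in colmap.items()}
        name = rec["name"]
        if "replicate_index" in rec and rec.get("replicate_index", "").strip():
            rep = int(rec["replicate_index"])
        else:
            counters[name] = counters.get(name, 0) + 1
            rep = counters[name]
        spots.append(
            SpotRecord(
                block=int(rec["block"]),
                column=int(rec["column"]),
                row=int(rec["row"]),
                name=name,
                replicate_index=rep,
                red_median=float(rec["red_median"]),
                green_median=float(rec["green_median"]),
                flag=int(float(rec["flag"])),
            )
        )

    serum = meta_kv.get("serum_id")
    if serum in (None, "", MOCK):
        serum = None
    meta = ArrayMeta(
        slide_id=meta_kv.get("slide_id", ""),
        array_position=int(meta_kv.get("array_position", 1)),
        serum_id=serum,
        day=meta_kv.get("day", ""),
        dilution=float(meta_kv.get("dilution", 0.25)),
    )
    scan = ArrayScan(spots=spots, meta=meta)
    if layout is not None:
        # resolution is by lookup; unmapped labels are kept, not dropped
        _ = [layout.spot_role(s.name) for s in scan.spots]
    return scan


def write_gpr(scan: ArrayScan, path: str | Path) -> Path:
    """Write *scan* in the dialect read by :func:`read_gpr` (lossless round-trip)."""
    path = Path(path)
    m = scan.meta
    lines = [
        f"slide_id={m.slide_id}",
        f"array_position={m.array_position}",
        f"serum_id={m.serum_id if m.serum_id is not None else MOCK}",
        f"day={m.day}",
        f"dilution={_fmt_number(m.dilution)}",
        "Block\tColumn\tRow\tName\tID\treplicate_index\tF635 Median\tF532 Median\tFlags",
    ]
    for s in scan.spots:
        lines.append(
            "\t".join(
                [
                    str(s.block), str(s.column), str(s.row), s.name, s.name,
                    str(s.replicate_index),
                    _fmt_number(s.red_median), _fmt_number(s.green_median),
                    str(s.flag),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# -- layout validation ----------------------------------------------------


@dataclass(frozen=True)
class LayoutIssue:
    kind: str  # under_replicated | over_replicated | unmapped | missing_label
    label: str
    expected: int
    observed: int


@dataclass
class LayoutReport:
    issues: list[LayoutIssue]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_layout(scan: ArrayScan, layout: ArrayLayout) -> LayoutReport:
    """Report-only check of observed vs expected replicate counts.

    Never raises: missing replicates, extra replicates and unmapped labels
    are all returned as issues for the caller to act on.
    """
    expected = layout.expected_counts()
    observed: dict[str, int] = {}
    for s in scan.spots:
        observed[s.name] = observed.get(s.name, 0) + 1
    issues: list[LayoutIssue] = []
    for label, n_exp in expected.items():
        n_obs = observed.get(label, 0)
        if n_obs == 0:
            issues.append(LayoutIssue("missing_label", label, n_exp, 0))
        elif n_obs < n_exp:
            issues.append(LayoutIssue("under_replicated", label, n_exp, n_obs))
        elif n_obs > n_exp:
            issues.append(LayoutIssue("over_replicated", label, n_exp, n_obs))
    for label, n_obs in observed.items():
        if layout.spot_role(label) == UNMAPPED:
            issues.append(LayoutIssue("unmapped", label, 0, n_obs))
    return LayoutReport(issues=issues)


# -- slide manifest -------------------------------------------------------


@dataclass(frozen=True)
class ManifestEntry:
    """One line of a slide manifest: file plus design coordinates."""

    path: str
    slide_id: str
    array_position: int
    serum_id: str | None
    day: str
    dilution: float = 0.25

    def to_meta(self) -> ArrayMeta:
        return ArrayMeta(
            slide_id=self.slide_id,
            array_position=self.array_position,
            serum_id=self.serum_id,
            day=self.day,
            dilution=self.dilution,
        )


def _entry_from_mapping(d: dict) -> ManifestEntry:
    serum = d.get("serum_id")
    if serum in (None, "", MOCK):
        serum = None
    return ManifestEntry(
        path=str(d["path"]),
        slide_id=str(d["slide_id"]),
        array_position=int(d["array_position"]),
        serum_id=serum,
        day=str(d.get("day", "")),
        dilution=float(d.get("dilution", 0.25)),
    )


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a slide manifest (YAML list of mappings, or CSV by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, list):
            raise GPRFormatError(f"{path}: manifest must be a list of entries")
        return [_entry_from_mapping(d) for d in raw]
    with open(path, newline="") as fh:
        return [_entry_from_mapping(row) for row in csv.DictReader(fh)]


def write_manifest(entries: Sequence[ManifestEntry], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "path": e.path,
            "slide_id": e.slide_id,
            "array_position": e.array_position,
            "serum_id": e.serum_id if e.serum_id is not None else MOCK,
            "day": e.day,
            "dilution": e.dilution,
        }
        for e in entries
    ]
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(rows, sort_keys=False))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["path", "slide_id", "array_position",
                                "serum_id", "day", "dilution"]
            )
            writer.writeheader()
            writer.writerows(rows)
    return path


def load_scans(entries: Iterable[ManifestEntry],
               layout: ArrayLayout | None = None,
               base_dir: str | Path | None = None) -> list[ArrayScan]:
    """Read every manifest entry, overriding file metadata with manifest metadata."""
    scans = []
    for e in entries:
        p = Path(e.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        scan = read_gpr(p, layout)
        scans.append(ArrayScan(spots=scan.spots, meta=e.to_meta()))
    return scans
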