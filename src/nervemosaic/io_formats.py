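"""Reading and writing the pipeline's external formats.

Covers grayscale TIFF frame sequences, NeuronJ ``.ndf`` nerve tracing
files, and the CSV "key" table that indexes per-eye mosaics and their
clinical fields.

Coordinate convention used throughout the package: pixel coordinates are
0-based with ``x`` = column and ``y`` = row, origin at the top-left of the
image.  Physical scale is given in microns per pixel; the native frame
scale of the instrument is 400/384 μm/px (a 384×384 pixel frame covers a
400×400 μm field of view).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

#: Native micron-per-pixel scale of a standard frame.
DEFAULT_MICRONS_PER_PIXEL = 400.0 / 384.0

#: Standard frame side, in pixels.
FRAME_SIZE = 384

NDF_HEADER = "// NeuronJ Data File"
_NDF_VERSION = "1.4.3"


class TracingSource(str, Enum):
    MANUAL = "manual"
    AUTO = "auto"


class Group(str, Enum):
    """Cohort stratum: non-diabetic controls (NGT/IGT) and type 2
    diabetes with duration below / at least ten years."""

    NGT = "NGT"
    IGT = "IGT"
    LT10 = "lt10"
    GE10 = "ge10"


@dataclass
class Frame:
    """A single in vivo confocal microscopy frame.

    Parameters
    ----------
    pixels : ndarray
        2-D grayscale intensity array, normally 384×384.
    index : int
        Acquisition ordinal, 1-based.
    microns_per_pixel : float
        Physical scale in μm/px (> 0).
    source_id : str
        Identifier, typically the file stem.
    """

    pixels: np.ndarray
    index: int
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"frame pixels must be 2-D grayscale, got shape {self.pixels.shape}"
            )
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Tracing:
    """A set of nerve centerline polylines.

    Each polyline is an (n, 2) float array of (x, y) pixel coordinates
    with n ≥ 2.  Lengths are Euclidean arc lengths scaled by
    ``microns_per_pixel``.
    """

    polylines: list[np.ndarray]
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    source: TracingSource = TracingSource.MANUAL

    def __post_init__(self) -> None:
        clean = []
        for p in self.polylines:
            arr = np.asarray(p, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(
                    "each polyline must be an (n>=2, 2) array of (x, y) points"
                )
            clean.append(arr)
        self.polylines = clean
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")

    def total_length_um(self) -> float:
        total = 0.0
        for p in self.polylines:
            steps = np.diff(p, axis=0)
            total += float(np.hypot(steps[:, 0], steps[:, 1]).sum())
        return total * self.microns_per_pixel

    def total_length_mm(self) -> float:
        return self.total_length_um() / 1000.0


@dataclass
class EyeRecord:
    """One row of the dataset key table: a single eye's largest mosaic
    and the clinical fields attached to it.  Missing values are kept as
    ``None`` — absence of esthesiometry or a density is meaningful and is
    never silently coerced to zero."""

    subject_id: int
    eye: str  # "OD" | "OS"
    mosaic_number: str
    mosaic_area_mm2: float | None = None
    esthesiometry_cm: float | None = None
    mcnfl_manual: float | None = None
    mcnfl_auto: float | None = None
    wcnfl_manual: float | None = None
    wcnfl_auto: float | None = None
    group: Group | None = None
    diabetes_duration_years: float | str | None = None

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be OD or OS, got {self.eye!r}")
        for name in ("mcnfl_manual", "mcnfl_auto", "wcnfl_manual", "wcnfl_auto",
                     "mosaic_area_mm2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.group in (Group.NGT, Group.IGT) and self.diabetes_duration_years is not None:
            raise ValueError("non-diabetic groups (NGT/IGT) cannot carry a diabetes duration")


def _natural_key(name: str) -> list:
    return [int(t) if t.isdigit() else t.lower() for t in re.split(r"(\d+)", name)]


def read_frame_sequence(
    directory: str | Path,
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL,
) -> list[Frame]:
    """Load every TIFF in *directory* as a Frame, ordered by natural sort
    of filename, with acquisition indices 1..N."""
    directory = Path(directory)
    paths = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
        key=lambda p: _natural_key(p.name),
    )
    if not paths:
        raise FileNotFoundError(f"no frames: no TIFF files found in {directory}")
    frames = []
    for i, path in enumerate(paths, start=1):
        try:
            pixels = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - depends on corrupt input
            raise IOError(f"unreadable TIFF file {path.name}: {exc}") from exc
        if np.ndim(pixels) != 2:
            raise ValueError(f"file {path.name} is not a single-channel grayscale image")
        frames.append(Frame(pixels=pixels, index=i,
                            microns_per_pixel=microns_per_pixel,
                            source_id=path.stem))
    return frames


def write_frame_sequence(frames: Iterable[Frame], directory: str | Path) -> list[Path]:
    """Write frames as ``frame_###.tif`` (16-bit if float input)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in frames:
        px = frame.pixels
        if px.dtype.kind == "f":
            px = np.clip(px, 0.0, 1.0)
            px = (px * 65535.0 + 0.5).astype(np.uint16)
        path = directory / f"frame_{frame.index:03d}.tif"
        tifffile.imwrite(path, px)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# NeuronJ .ndf tracing files
# ---------------------------------------------------------------------------

def parse_ndf(path: str | Path, microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL) -> Tracing:
    """Parse a NeuronJ ``.ndf`` tracing file (v1.4.x text dialect).

    Each "Tracing" block becomes one polyline; multiple segments of one
    tracing are concatenated (a segment's duplicated junction point is
    dropped).  Cluster/type metadata is ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith(NDF_HEADER):
        raise ValueError(f"{path.name}: not an ndf file (missing NeuronJ header)")

    polylines: list[np.ndarray] = []
    current: list[tuple[float, float]] = []
    coords: list[float] = []
    coords_start_line = 0

    def flush_coords(lineno: int) -> None:
        nonlocal coords
        if not coords:
            return
        if len(coords) % 2:
            raise ValueError(
                f"{path.name}: odd coordinate count in block starting at line "
                f"{coords_start_line}"
            )
        pts = [(coords[k], coords[k + 1]) for k in range(0, len(coords), 2)]
        if current and pts and current[-1] == pts[0]:
            pts = pts[1:]  # segments share their junction point
        current.extend(pts)
        coords = []

    def flush_tracing(lineno: int) -> None:
        flush_coords(lineno)
        if current:
            if len(current) < 2:
                raise ValueError(
                    f"{path.name}: tracing ending before line {lineno} has < 2 points"
                )
            polylines.append(np.asarray(current, dtype=float))
            current.clear()

    in_segment = False
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if line.startswith("//"):
            if line.startswith("// Tracing"):
                flush_tracing(lineno)
                in_segment = False
            elif line.startswith("// Segment"):
                flush_coords(lineno)
                in_segment = True
                coords_start_line = lineno + 1
            else:  # End / Parameters / Type names / Cluster names sections
                flush_tracing(lineno)
                in_segment = False
            continue
        if not in_segment or not line:
            continue  # tracing metadata (id/type/cluster/label) or blank
        try:
            coords.append(float(line))
        except ValueError:
            raise ValueError(
                f"{path.name}: non-numeric line {lineno} inside coordinate block"
            )
    flush_tracing(len(lines) + 1)
    return Tracing(polylines=polylines, microns_per_pixel=microns_per_pixel,
                   source=TracingSource.MANUAL)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_ndf(tracing: Tracing, path: str | Path) -> Path:
    """Write a Tracing as a NeuronJ-dialect ``.ndf`` file.

    One segment per polyline; type/cluster metadata written as NeuronJ
    defaults.  ``parse_ndf(write_ndf(t))`` reproduces *t* exactly.
    """
    if not tracing.polylines:
        raise ValueError("cannot write an empty tracing")
    path = Path(path)
    out = [f"{NDF_HEADER} - DO NOT CHANGE", _NDF_VERSION]
    out += ["// Parameters", "8", "1", "2", "1.0", "15", "15", "5", "1.0", "true"]
    out += ["// Type names and colors", "Default", "4"]
    out += ["// Cluster names", "Default"]
    for k, poly in enumerate(tracing.polylines, start=1):
        out += [f"// Tracing N{k}", str(k), "0", "0", "Default"]
        out.append(f"// Segment 1 of Tracing N{k}")
        for x, y in poly:
            out.append(_fmt(x))
            out.append(_fmt(y))
    out.append("// End of NeuronJ Data File")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Key table (CSV export of the dataset's Excel key)
# ---------------------------------------------------------------------------

KEY_COLUMNS = {
    "subject_id": ("subject id", "subject_id", "subjectid", "id"),
    "eye": ("eye",),
    "mosaic_number": ("mosaic number", "mosaic_number", "mosaic"),
    "mosaic_area_mm2": ("mosaic area", "mosaic_area_mm2", "mosaic area (mm2)",
                        "mosaic area mm2"),
    "esthesiometry_cm": ("esthesiometry", "esthesiometry_cm", "esthesiometry (cm)"),
    "mcnfl_manual": ("mcnfl manual", "mcnfl_manual", "mcnfl (manual)"),
    "mcnfl_auto": ("mcnfl auto", "mcnfl_auto", "mcnfl (auto)"),
    "wcnfl_manual": ("wcnfl manual", "wcnfl_manual", "wcnfl (manual)"),
    "wcnfl_auto": ("wcnfl auto", "wcnfl_auto", "wcnfl (auto)"),
    "group": ("group", "diabetes status", "status"),
    "diabetes_duration_years": ("diabetes duration", "diabetes_duration_years",
                                "duration", "years since diagnosis"),
}

_GROUP_ALIASES = {
    "ngt": Group.NGT,
    "igt": Group.IGT,
    "<10": Group.LT10, "lt10": Group.LT10, "t2dm<10": Group.LT10,
    "10+": Group.GE10, ">=10": Group.GE10, "ge10": Group.GE10, "t2dm10+": Group.GE10,
}


def _norm(s: str) -> str:
    return re.sub(r"\s+", " ", s.strip().lower())


def _maybe_float(cell: str) -> float | None:
    cell = cell.strip()
    if not cell or cell.lower() in ("na", "nan", "n/a", "-", "missing"):
        return None
    return float(cell)


def read_key_table(path: str | Path) -> list[EyeRecord]:
    """Read a CSV key table into EyeRecords.

    Header matching is case/space-insensitive; blank cells become
    ``None``; group labels are normalized (``<10`` → lt10, ``10+`` → ge10).
    """
    path = Path(path)
    records: list[EyeRecord] = []
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path.name}: empty file, expected a header row")
        colmap: dict[str, int] = {}
        for j, name in enumerate(header):
            n = _norm(name)
            for field_name, aliases in KEY_COLUMNS.items():
                if n in aliases and field_name not in colmap:
                    colmap[field_name] = j
        for required in ("subject_id", "eye", "mosaic_number"):
            if required not in colmap:
                raise ValueError(f"{path.name}: missing required column {required!r}")

        def cell(row: Sequence[str], field_name: str) -> str:
            j = colmap.get(field_name)
            return row[j].strip() if j is not None and j < len(row) else ""

        for rownum, row in enumerate(reader, start=2):
            if not any(c.strip() for c in row):
                continue
            group_raw = cell(row, "group")
            group = None
            if group_raw:
                group = _GROUP_ALIASES.get(_norm(group_raw).replace(" ", ""))
                if group is None:
                    raise ValueError(
                        f"{path.name} row {rownum}: unknown group label {group_raw!r}"
                    )
            dur_raw = cell(row, "diabetes_duration_years")
            duration: float | str | None
            if not dur_raw or dur_raw.lower() in ("na", "nan", "n/a", "-"):
                duration = None
            elif _norm(dur_raw) in ("newly diagnosed", "new"):
                duration = "newly diagnosed"
            else:
                duration = float(dur_raw)
            records.append(EyeRecord(
                subject_id=int(cell(row, "subject_id")),
                eye=cell(row, "eye").upper(),
                mosaic_number=cell(row, "mosaic_number"),
                mosaic_area_mm2=_maybe_float(cell(row, "mosaic_area_mm2")),
                esthesiometry_cm=_maybe_float(cell(row, "esthesiometry_cm")),
                mcnfl_manual=_maybe_float(cell(row, "mcnfl_manual")),
                mcnfl_auto=_maybe_float(cell(row, "mcnfl_auto")),
                wcnfl_manual=_maybe_float(cell(row, "wcnfl_manual")),
                wcnfl_auto=_maybe_float(cell(row, "wcnfl_auto")),
                group=group,
                diabetes_duration_years=duration,
            ))
    return records


def write_key_table(records: Iterable[EyeRecord], path: str | Path) -> Path:
    path = Path(path)
    header = list(KEY_COLUMNS)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = []
            for name in header:
                v = getattr(r, name)
                if v is None:
                    row.append("")
                elif isinstance(v, Group):
                    row.append(v.value)
                else:
                    row.append(v)
            writer.writerow(row)
    return path
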