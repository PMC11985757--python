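"""Data model, coordinate conventions and file I/O.

Coordinate conventions
----------------------
Raw mark tables come from image analysis software, whose pixel frame has
row 0 at the top while anatomical dorsal is up.  Ingest therefore converts
once, early, into a single internal *anatomical frame*:

- ``+y`` = dorsal: ``y_anat = H - y_px`` when the image height ``H`` is
  known, otherwise the y coordinate is mirrored about the ROI bounding box
  (``y_anat = ymin + ymax - y_px``).
- ``+x`` = lateral: marks and ROIs from left hemispheres are mirrored in x
  about the ROI bounding box, and a provenance flag is recorded.

Everything downstream (normalization, binning, profiles) assumes this
frame, so no further flips are applied there.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from shapely.geometry import Point, Polygon

logger = logging.getLogger("glioquant")

NUCLEI = ("MNTB", "MSO", "LSO", "dLSO", "control", "other")

MARKS_COLUMNS = ["section_id", "nucleus", "x", "y", "markers", "soma_diameter_um"]


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class GeometryError(ValueError):
    """Invalid geometry: self-intersecting polygon, degenerate bounding box, ..."""


@dataclass(frozen=True)
class CellMark:
    """One manually marked soma center.

    Coordinates are pixels in the frame declared by ``frame``/ingest
    (anatomical after ingest).  ``markers`` is the set of fluorescence
    markers the soma was positive for (e.g. ``{"Olig2", "SOX10"}``).
    """

    section_id: str
    nucleus: str
    x_px: float
    y_px: float
    markers: frozenset[str]
    soma_diameter_um: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_px) and np.isfinite(self.y_px)):
            raise ValueError("mark coordinates must be finite")
        if self.x_px < 0 or self.y_px < 0:
            raise ValueError("mark coordinates must be >= 0")
        if not self.markers:
            raise ValueError("mark must carry at least one marker")
        object.__setattr__(self, "markers", frozenset(self.markers))


@dataclass(frozen=True)
class NucleusROI:
    """Closed polygon delimiting one nucleus in one section.

    ``axis_spec`` names the tonotopic profile axis for this nucleus:
    ``"medio-lateral"`` (MNTB, control), ``"dorso-ventral"`` (MSO, dLSO) or
    ``"curved-path"`` (LSO, dorsomedial-to-ventral-to-dorsolateral).
    """

    section_id: str
    nucleus: str
    vertices: tuple[tuple[float, float], ...]
    axis_spec: str = "medio-lateral"
    hemisphere: str = "right"
    mirrored: bool = False  # provenance: left-hemisphere x-mirror applied

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise GeometryError("ROI polygon needs at least 3 vertices")
        poly = Polygon(verts)
        if not poly.is_simple or poly.area <= 0:
            raise GeometryError(
                f"ROI {self.nucleus}/{self.section_id}: polygon must be simple with area > 0"
            )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the vertex set."""
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return min(xs), min(ys), max(xs), max(ys)


@dataclass(frozen=True)
class SectionFrame:
    """Acquisition metadata for one section."""

    section_id: str
    pixel_size_um: float
    age_group: str = ""
    species: str = "gerbil"

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")


def px_to_um(value_px: float, frame_or_pixel_size: "SectionFrame | float") -> float:
    """Convert a pixel length to micrometres using the section's pixel size."""
    ps = (
        frame_or_pixel_size.pixel_size_um
        if isinstance(frame_or_pixel_size, SectionFrame)
        else float(frame_or_pixel_size)
    )
    return value_px * ps


def um_to_px(value_um: float, frame_or_pixel_size: "SectionFrame | float") -> float:
    ps = (
        frame_or_pixel_size.pixel_size_um
        if isinstance(frame_or_pixel_size, SectionFrame)
        else float(frame_or_pixel_size)
    )
    return value_um / ps


# ---------------------------------------------------------------------------
# mark tables


def _parse_markers(cell: str) -> frozenset[str]:
    return frozenset(m.strip() for m in cell.split(";") if m.strip())


def read_marks(path: str | Path, frame: SectionFrame | None = None) -> list[CellMark]:
    """Read a cell-mark CSV.

    Expected columns: ``section_id, nucleus, x, y, markers`` and optionally
    ``soma_diameter_um``; markers are semicolon-delimited.  Rows with
    non-numeric coordinates are skipped and logged with their line number;
    a missing required column raises :class:`FormatError`.
    """
    path = Path(path)
    marks: list[CellMark] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header")
        required = {"section_id", "nucleus", "x", "y", "markers"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                x = float(row["x"])
                y = float(row["y"])
            except (TypeError, ValueError):
                logger.warning("%s:%d: non-numeric coordinate, row skipped", path, lineno)
                continue
            dia = row.get("soma_diameter_um")
            dia_f = float(dia) if dia not in (None, "", "NA") else None
            try:
                marks.append(
                    CellMark(
                        section_id=row["section_id"],
                        nucleus=row["nucleus"],
                        x_px=x,
                        y_px=y,
                        markers=_parse_markers(row["markers"]),
                        soma_diameter_um=dia_f,
                    )
                )
            except ValueError as exc:
                logger.warning("%s:%d: invalid mark (%s), row skipped", path, lineno, exc)
    return marks


def write_marks(marks: Iterable[CellMark], path: str | Path) -> None:
    """Write marks to CSV; ``read_marks`` round-trips coordinates exactly.

    Coordinates are written with :func:`repr`, which is exact for floats.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MARKS_COLUMNS)
        for m in marks:
            writer.writerow(
                [
                    m.section_id,
                    m.nucleus,
                    repr(m.x_px),
                    repr(m.y_px),
                    ";".join(sorted(m.markers)),
                    "" if m.soma_diameter_um is None else repr(m.soma_diameter_um),
                ]
            )


def read_fiji_results(
    path: str | Path,
    section_id: str,
    nucleus: str,
    marker: str,
    pixel_size_um: float | None = None,
) -> list[CellMark]:
    """Import an ImageJ/Fiji "Results"-style table (columns ``X``, ``Y``
    and optionally ``Area``) of point-tool marks as :class:`CellMark` s.

    ``Area`` (if present, in um^2) is converted to an equivalent disc
    diameter and stored as ``soma_diameter_um``.
    """
    path = Path(path)
    marks: list[CellMark] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"X", "Y"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: Fiji Results table needs X and Y columns")
        for lineno, row in enumerate(reader, start=2):
            try:
                x, y = float(row["X"]), float(row["Y"])
            except (TypeError, ValueError):
                logger.warning("%s:%d: non-numeric coordinate, row skipped", path, lineno)
                continue
            dia = None
            if row.get("Area") not in (None, ""):
                dia = 2.0 * float(np.sqrt(float(row["Area"]) / np.pi))
            marks.append(
                CellMark(section_id, nucleus, x, y, frozenset({marker}), soma_diameter_um=dia)
            )
    return marks


# ---------------------------------------------------------------------------
# ROI files


def read_rois(
    vertices_path: str | Path, metadata_path: str | Path | None = None
) -> list[NucleusROI]:
    """Read ROI polygons.

    CSV dialect: ``section_id, nucleus, vertex_index, x, y`` rows, ordered
    by vertex_index within each (section, nucleus); the optional sidecar
    metadata table has ``section_id, nucleus, hemisphere, axis_spec``.
    A ``.json`` path is read as the JSON dialect: a list of objects with
    the same fields (``vertices`` as a list of ``[x, y]`` pairs).
    """
    vertices_path = Path(vertices_path)
    meta: dict[tuple[str, str], dict[str, str]] = {}
    if metadata_path is not None:
        with Path(metadata_path).open(newline="") as fh:
            for row in csv.DictReader(fh):
                meta[(row["section_id"], row["nucleus"])] = row

    if vertices_path.suffix.lower() == ".json":
        records = json.loads(vertices_path.read_text())
        rois = []
        for rec in records:
            key = (rec["section_id"], rec["nucleus"])
            m = meta.get(key, {})
            rois.append(
                NucleusROI(
                    section_id=rec["section_id"],
                    nucleus=rec["nucleus"],
                    vertices=tuple((float(x), float(y)) for x, y in rec["vertices"]),
                    axis_spec=rec.get("axis_spec", m.get("axis_spec", "medio-lateral")),
                    hemisphere=rec.get("hemisphere", m.get("hemisphere", "right")),
                )
            )
        return rois

    groups: dict[tuple[str, str], list[tuple[int, float, float]]] = {}
    with vertices_path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"section_id", "nucleus", "vertex_index", "x", "y"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{vertices_path}: missing required ROI columns")
        for row in reader:
            key = (row["section_id"], row["nucleus"])
            groups.setdefault(key, []).append(
                (int(row["vertex_index"]), float(row["x"]), float(row["y"]))
            )
    rois = []
    for (section_id, nucleus), pts in groups.items():
        pts.sort()
        m = meta.get((section_id, nucleus), {})
        rois.append(
            NucleusROI(
                section_id=section_id,
                nucleus=nucleus,
                vertices=tuple((x, y) for _, x, y in pts),
                axis_spec=m.get("axis_spec", "medio-lateral"),
                hemisphere=m.get("hemisphere", "right"),
            )
        )
    return rois


def write_rois(rois: Iterable[NucleusROI], vertices_path: str | Path) -> None:
    with Path(vertices_path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["section_id", "nucleus", "vertex_index", "x", "y"])
        for roi in rois:
            for i, (x, y) in enumerate(roi.vertices):
                writer.writerow([roi.section_id, roi.nucleus, i, repr(x), repr(y)])


# ---------------------------------------------------------------------------
# ingest frame conversion


def to_anatomical(
    marks: Sequence[CellMark],
    roi: NucleusROI,
    image_height_px: float | None = None,
) -> tuple[list[CellMark], NucleusROI]:
    """Convert image-frame marks + ROI into the anatomical frame.

    Flips y so +y = dorsal (about the image height when known, else about
    the ROI bounding box) and mirrors x for left hemispheres so +x =
    lateral.  Applied exactly once at ingest.
    """
    xmin, ymin, xmax, ymax = roi.bbox()

    def fy(y: float) -> float:
        if image_height_px is not None:
            return image_height_px - y
        return (ymin + ymax) - y

    mirror = roi.hemisphere == "left" and not roi.mirrored

    def fx(x: float) -> float:
        return (xmin + xmax) - x if mirror else x

    new_vertices = tuple((fx(x), fy(y)) for x, y in roi.vertices)
    new_roi = replace(roi, vertices=new_vertices, mirrored=roi.mirrored or mirror)
    new_marks = [replace(m, x_px=fx(m.x_px), y_px=fy(m.y_px)) for m in marks]
    return new_marks, new_roi


# ---------------------------------------------------------------------------
# polygon geometry


def polygon_area(roi: NucleusROI, frame: SectionFrame) -> tuple[float, float]:
    """Area of the ROI polygon as ``(area_um2, area_mm2)``.

    Shoelace value in pixel^2 scaled by ``pixel_size_um ** 2``.
    """
    area_px2 = roi.polygon.area
    area_um2 = area_px2 * frame.pixel_size_um**2
    return area_um2, area_um2 * 1e-6


def point_in_roi(mark: CellMark, roi: NucleusROI) -> bool:
    """True iff the mark lies inside or on the boundary of the ROI polygon.

    Boundary points count as inside: manual marks at faint borders are kept.
    """
    return roi.polygon.covers(Point(mark.x_px, mark.y_px))


def normalize_coordinates(
    marks: Sequence[CellMark], roi: NucleusROI
) -> np.ndarray:
    """Map marks into the ROI's normalized frame: both bounding-box axes
    span 0-100 %.

    Returns an ``(n, 2)`` array of ``(rx, ry)``.  In the anatomical frame
    ``ry`` increases dorsally and ``rx`` laterally; no flip happens here
    (ingest already established the frame).
    """
    xmin, ymin, xmax, ymax = roi.bbox()
    w, h = xmax - xmin, ymax - ymin
    if w <= 0 or h <= 0:
        raise GeometryError("degenerate ROI bounding box (zero extent)")
    out = np.empty((len(marks), 2), dtype=float)
    for i, m in enumerate(marks):
        out[i, 0] = 100.0 * (m.x_px - xmin) / w
        out[i, 1] = 100.0 * (m.y_px - ymin) / h
    return out


# ---------------------------------------------------------------------------
# images and config


def read_image(path: str | Path) -> np.ndarray:
    """Read a single- or multi-channel 2-D TIFF as a numpy array.

    Multi-channel images are returned channel-first ``(C, H, W)``; the
    channel order is declared in the run config, not in the file.
    """
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim == 3 and arr.shape[-1] <= 4 and arr.shape[0] > 4:
        arr = np.moveaxis(arr, -1, 0)  # (H, W, C) -> (C, H, W)
    return arr


def write_image(arr: np.ndarray, path: str | Path) -> None:
    import tifffile

    kwargs = {}
    if arr.ndim == 3:  # channel-first stack: one page per channel
        kwargs = {"photometric": "minisblack", "planarconfig": "separate"}
    tifffile.imwrite(str(path), arr, **kwargs)


@dataclass
class RunConfig:
    """Run configuration (one YAML file per analysis run)."""

    pixel_size_um: float = 0.6
    hemisphere: str = "right"
    age_group: str = ""
    channel_map: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    match_tolerance_um: float = 5.0
    axon_tolerance_um: float = 1.0
    default_soma_diameter_um: float = 17.0
    center_shift_percent: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))
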