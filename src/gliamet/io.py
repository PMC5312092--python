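"""Readers and writers for the package's plain-text and TIFF dialects.

Contour CSV (one row per vertex):
    cell_id, genotype, frame_min, vertex_index, x_um, y_um
Frames must be strictly increasing per cell and uniformly sampled (1-min
default) unless ``allow_gaps`` is set.

ROI CSV reuses the same columns plus a leading ``label`` column; closure
scenes reuse the contour dialect with the bounding region flagged by
cell_id ``REGION``.  Calibration CSV: genotype, age_h, mean_segment_width_um.
Images travel as single-channel TIFF (pixel size supplied by the caller).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import Contour, ContourSeries, GeometryError, validate_contour
from .imaging import IntensityImage, RoiSpec

CONTOUR_COLUMNS = ["cell_id", "genotype", "frame_min", "vertex_index", "x_um", "y_um"]
REGION_ID = "REGION"


class ParseError(ValueError):
    """Malformed input table (message carries file and row context)."""


def write_contour_table(series_list: list[ContourSeries], path) -> None:
    """Write contour series to the vertex-per-row CSV dialect."""
    rows = []
    for series in series_list:
        for c in series:
            for k, (x, y) in enumerate(c.vertices):
                rows.append((c.cell_id, series.genotype, c.t, k, x, y))
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


def _contours_from_frame(df: pd.DataFrame, path, label_col: str = "cell_id"):
    for required in CONTOUR_COLUMNS:
        if required not in df.columns:
            raise ParseError(f"{path}: missing column {required!r}")
    bad = df[["frame_min", "vertex_index", "x_um", "y_um"]].isna().any(axis=1)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header + 1-based
        raise ParseError(f"{path}: malformed row at line {row}")


def read_contour_table(path, allow_gaps: bool = False) -> list[ContourSeries]:
    """Read and validate a contour CSV into per-cell series.

    Raises :class:`ParseError` for malformed rows or invalid polygons and
    a sampling error for non-uniform frame spacing (unless ``allow_gaps``).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _contours_from_frame(df, path)
    out = []
    for cell_id, cell_df in df.groupby("cell_id", sort=True):
        genotypes = cell_df["genotype"].astype(str).unique()
        if len(genotypes) > 1:
            raise ParseError(
                f"{path}: cell {cell_id!r} has multiple genotypes {list(genotypes)}"
            )
        contours = []
        for t, frame_df in cell_df.groupby("frame_min", sort=True):
            frame_df = frame_df.sort_values("vertex_index")
            verts = frame_df[["x_um", "y_um"]].to_numpy(dtype=float)
            try:
                contours.append(validate_contour(verts, cell_id=str(cell_id), t=float(t)))
            except GeometryError as exc:
                line = int(frame_df.index[0]) + 2
                raise ParseError(
                    f"{path}: invalid contour for cell {cell_id!r} at "
                    f"frame {t} (line {line}): {exc}"
                ) from exc
        out.append(ContourSeries(contours, genotype=str(genotypes[0]),
                                 allow_gaps=allow_gaps))
    if not out:
        raise ParseError(f"{path}: no contours found")
    return out


def write_roi_table(rois: list[RoiSpec], path) -> None:
    rows = []
    for roi in rois:
        for k, (x, y) in enumerate(np.asarray(roi.polygon, dtype=float)):
            rows.append((roi.label, "", 0.0, k, x, y))
    pd.DataFrame(rows, columns=["label"] + CONTOUR_COLUMNS[1:]).to_csv(path, index=False)


def read_roi_table(path) -> dict[str, RoiSpec]:
    """Read labelled ROIs from the contour-CSV dialect with a label column."""
    path = Path(path)
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ParseError(f"{path}: missing column 'label'")
    rois = {}
    for label, roi_df in df.groupby("label", sort=True):
        roi_df = roi_df.sort_values("vertex_index")
        verts = roi_df[["x_um", "y_um"]].to_numpy(dtype=float)
        rois[str(label)] = RoiSpec.from_vertices(str(label), verts)
    return rois


def write_scene(cells: list[Contour], region: Contour, path,
                genotype: str = "") -> None:
    """Write a closure scene: contour dialect with a REGION-flagged row set."""
    rows = []
    for c in [region] + list(cells):
        cid = REGION_ID if c is region else c.cell_id
        for k, (x, y) in enumerate(c.vertices):
            rows.append((cid, genotype, c.t, k, x, y))
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


def read_scene(path) -> tuple[list[Contour], Contour]:
    """Read a closure scene; returns (cells, region)."""
    series = read_contour_table(path)
    region = None
    cells = []
    for s in series:
        if s.cell_id == REGION_ID:
            region = s[0]
        else:
            cells.extend(s.contours)
    if region is None:
        raise ParseError(f"{path}: no {REGION_ID!r} row set found")
    return cells, region


def write_calibration_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_calibration_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("genotype", "age_h", "mean_segment_width_um"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def write_image(img: IntensityImage, path) -> None:
    tifffile.imwrite(path, np.asarray(img.pixels))


def read_image(path, pixel_size: float) -> IntensityImage:
    """Read a single-channel TIFF; the pixel size (um/px) is caller-supplied."""
    return IntensityImage(tifffile.imread(path), pixel_size)
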