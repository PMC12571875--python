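"""Protein-image integration: in-polygon pixel summation and positivity.

Protein channels arrive as registered single-channel images in the same µm
frame as the cells; each cell's intensity is the sum of the pixels whose
centres fall inside (or on the boundary of) its polygon.  Positivity along
the crescent trajectory uses an Otsu split of the per-cell mean intensity
(or a fixed quantile) and a quadratic trend of per-ROI positive fractions
against PC1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .exceptions import ParameterError, ValidationError
from .pathways import QuadraticTrend, quadratic_trend


@dataclass
class ProteinImage:
    """Single-channel intensity grid with its µm frame."""

    grid: np.ndarray           # (ny, nx), non-negative
    pixel_size_um: float
    channel: str = "protein"
    origin_um: tuple[float, float] = (0.0, 0.0)   # µm position of pixel (0, 0)'s corner

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValidationError("image grid contains non-finite values")

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y µm coordinates of pixel centres (1-D each)."""
        ny, nx = self.grid.shape
        x0, y0 = self.origin_um
        xs = x0 + (np.arange(nx) + 0.5) * self.pixel_size_um
        ys = y0 + (np.arange(ny) + 0.5) * self.pixel_size_um
        return xs, ys

    # -- disk round trip (array + JSON sidecar, or TIFF) --------------------
    def save(self, path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.grid)
        meta = dict(pixel_size_um=self.pixel_size_um, channel=self.channel,
                    origin_um=list(self.origin_um))
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "ProteinImage":
        path = Path(path)
        if path.suffix in (".tif", ".tiff"):
            import tifffile

            grid = np.asarray(tifffile.imread(path), dtype=float)
            sidecar = path.with_suffix(".json")
        else:
            grid = np.load(path.with_suffix(".npy"))
            sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(grid=grid, pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
                   channel=meta.get("channel", "protein"),
                   origin_um=tuple(meta.get("origin_um", (0.0, 0.0))))


def rasterize_polygon(polygon_vertices, origin, pixel_size: float,
                      shape) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (row, col) indices whose centres lie inside or on the polygon.

    ``origin`` is the µm position of the grid's (0, 0) pixel corner.
    """
    poly = shapely.Polygon(np.asarray(polygon_vertices, dtype=float))
    if not poly.is_valid:
        raise ValidationError("polygon is not simple (self-intersecting)")
    x0, y0 = origin
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor((minx - x0) / pixel_size - 0.5)), 0)
    c1 = min(int(np.ceil((maxx - x0) / pixel_size + 0.5)), shape[1] - 1)
    r0 = max(int(np.floor((miny - y0) / pixel_size - 0.5)), 0)
    r1 = min(int(np.ceil((maxy - y0) / pixel_size + 0.5)), shape[0] - 1)
    if c1 < c0 or r1 < r0:
        return np.array([], dtype=int), np.array([], dtype=int)
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    cx = x0 + (cols + 0.5) * pixel_size
    cy = y0 + (rows + 0.5) * pixel_size
    CX, CY = np.meshgrid(cx, cy)
    inside = shapely.intersects_xy(poly, CX.ravel(), CY.ravel()).reshape(CX.shape)
    rr, cc = np.nonzero(inside)
    return rows[rr], cols[cc]


def aggregate_protein(image: ProteinImage, polygons: dict) -> pd.DataFrame:
    """Sum in-polygon pixel intensities per cell.

    Pixels shared by overlapping polygons are counted for each polygon.
    Cells whose polygon covers no pixel centre (including polygons entirely
    outside the image) get sum 0 and are flagged.
    """
    rows = []
    for cid, verts in polygons.items():
        rr, cc = rasterize_polygon(verts, image.origin_um, image.pixel_size_um,
                                   image.grid.shape)
        total = float(image.grid[rr, cc].sum()) if len(rr) else 0.0
        rows.append(dict(cell_id=cid, intensity=total, pixel_count=int(len(rr)),
                         flag="" if len(rr) else "no_pixels"))
    out = pd.DataFrame(rows, columns=["cell_id", "intensity", "pixel_count", "flag"])
    return out.set_index("cell_id")


def positivity_threshold(mean_intensities, method: str = "otsu",
                         quantile: float | None = None) -> float:
    """Positivity cut on per-cell mean intensity: Otsu split (default) or a
    fixed quantile."""
    vals = np.asarray(mean_intensities, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("no intensities to threshold")
    if method == "quantile":
        if quantile is None:
            raise ParameterError("quantile method requires a quantile")
        return float(np.quantile(vals, quantile))
    if method != "otsu":
        raise ParameterError(f"unknown threshold method {method!r}")
    if np.ptp(vals) == 0:
        return float(vals[0])
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(vals))


def positivity_along_trajectory(protein_table: pd.DataFrame, cell_types,
                                roi_ids, pc1_per_roi: pd.Series,
                                target_type: str = "PEC",
                                threshold: float | None = None,
                                threshold_method: str = "otsu",
                                threshold_quantile: float | None = None
                                ) -> tuple[pd.DataFrame, QuadraticTrend, float]:
    """Per-ROI positive fraction of a cell type and its quadratic PC1 trend.

    A cell is positive when its mean in-polygon intensity exceeds the
    threshold (default: Otsu split over the target type's mean intensities).
    Returns ``(per_roi, trend, threshold)``; ROIs without target-type cells
    are flagged and excluded from the trend.
    """
    cell_types = np.asarray(cell_types, dtype=object)
    roi_ids = np.asarray(roi_ids)
    mean_int = protein_table["intensity"] / protein_table["pixel_count"].replace(0, np.nan)
    sel = cell_types == target_type
    if threshold is None:
        threshold = positivity_threshold(mean_int[sel].dropna(),
                                         method=threshold_method,
                                         quantile=threshold_quantile)
    positive = mean_int > threshold

    rows = []
    for roi in np.unique(roi_ids[roi_ids >= 0]):
        in_roi = (roi_ids == roi) & sel
        n = int(in_roi.sum())
        frac = float(positive[in_roi].mean()) if n else np.nan
        rows.append(dict(roi_id=int(roi), n_cells=n, positive_fraction=frac,
                         flag="" if n else "no_target_cells"))
    per_roi = pd.DataFrame(rows).set_index("roi_id")
    per_roi["pc1"] = per_roi.index.map(pc1_per_roi)
    ok = per_roi["positive_fraction"].notna() & per_roi["pc1"].notna()
    trend = quadratic_trend(per_roi.loc[ok, "pc1"], per_roi.loc[ok, "positive_fraction"])
    return per_roi, trend, float(threshold)
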