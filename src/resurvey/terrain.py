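"""Ruggedness from an elevation raster and the block-ordination comparison.

Ruggedness is the standard deviation of elevation within a fixed window
(default 100 × 100 m) around a plot — a terrain-complexity descriptor.  For
the block comparison, plot parameters (surface-type covers, elevation,
slope, ruggedness, aspect decomposed into northness/eastness) are min–max
rescaled and ordinated with non-metric multidimensional scaling; the first
axis is then contrasted among blocks with a linear mixed model (block fixed,
transect random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import MDS
from scipy.spatial.distance import pdist, squareform

from .errors import SchemaError, UndefinedResultError, ValidationError
from .inference import ModelSpec, ContrastResult, fit_and_contrast

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElevationGrid:
    """A rectangular elevation raster in a projected metric system.

    ``origin`` is the (x, y) of the *lower-left corner* of the lower-left
    cell (ESRI convention); ``values`` row 0 is the northernmost row.
    """

    origin: tuple
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be > 0")
        if np.asarray(self.values).ndim != 2:
            raise ValidationError("values must be a rectangular 2-D array")

    @property
    def extent(self) -> tuple:
        """(xmin, ymin, xmax, ymax)."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.cell_size, y0 + ny * self.cell_size)

    def cell_centres(self):
        """x-centres (nx,), y-centres (ny,) with y descending to match rows."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = y0 + (np.arange(ny)[::-1] + 0.5) * self.cell_size
        return xs, ys


def read_esri_ascii(path) -> ElevationGrid:
    """Read an ESRI ASCII grid (.asc): 5–6 header lines then rows of values."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise SchemaError(f"ESRI ASCII grid missing header field {req!r}")
    values = np.array(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(
            f"grid body shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    cell = header["cellsize"]
    if "xllcorner" in header:
        origin = (header["xllcorner"], header["yllcorner"])
    else:  # centre-registered header
        origin = (header["xllcenter"] - cell / 2, header["yllcenter"] - cell / 2)
    return ElevationGrid(
        origin=origin,
        cell_size=cell,
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


def ruggedness(
    grid: ElevationGrid, plot_location, window: float = 100.0, ddof: int = 1
) -> float:
    """Standard deviation of elevation in a window × window square.

    Includes every non-nodata cell whose centre falls in the square centred
    on ``plot_location``; sample (n−1) standard deviation by default.
    Raises if the plot lies outside the grid; returns an undefined-result
    error if fewer than two valid cells fall in the window.
    """
    if window <= 0:
        raise ValidationError("window must be > 0")
    x, y = plot_location
    xmin, ymin, xmax, ymax = grid.extent
    if not (xmin <= x <= xmax and ymin <= y <= ymax):
        raise ValidationError(f"plot location {plot_location} outside grid extent")
    xs, ys = grid.cell_centres()
    half = window / 2.0
    xi = np.nonzero(np.abs(xs - x) <= half)[0]
    yi = np.nonzero(np.abs(ys - y) <= half)[0]
    vals = grid.values[np.ix_(yi, xi)].ravel()
    vals = vals[vals != grid.nodata]
    if vals.size < 2:
        raise UndefinedResultError(
            "fewer than two valid elevation cells in the window"
        )
    return float(np.std(vals, ddof=ddof))


ORDINATION_PARAMS = [
    "rock_pct", "scree_pct", "soil_pct", "veg_pct",
    "elevation_m", "slope_deg", "ruggedness_m",
]


def ordination_matrix(attrs: pd.DataFrame):
    """Min–max rescaled plot × parameter matrix for ordination.

    Aspect is circular and is decomposed into northness = cos(aspect) and
    eastness = sin(aspect) before rescaling.  Constant columns are dropped
    with a warning.  Returns (matrix, report) where the report records the
    per-column min/max used and any dropped columns.
    """
    cols = {}
    report = {"scaling": {}, "dropped": [], "aspect_decomposed": True}
    source = attrs.copy()
    if "aspect_deg" not in source.columns:
        raise SchemaError("plot attributes missing column 'aspect_deg'")
    rad = np.deg2rad(source["aspect_deg"].to_numpy(float))
    source["northness"] = np.cos(rad)
    source["eastness"] = np.sin(rad)
    for col in ORDINATION_PARAMS + ["northness", "eastness"]:
        if col not in source.columns:
            raise SchemaError(f"plot attributes missing column {col!r}")
        v = source[col].to_numpy(float)
        if np.isnan(v).all():
            raise SchemaError(f"column {col!r} is entirely missing")
        lo, hi = np.nanmin(v), np.nanmax(v)
        if hi == lo:
            logger.warning("dropping constant column %r from ordination matrix", col)
            report["dropped"].append(col)
            continue
        cols[col] = (v - lo) / (hi - lo)
        report["scaling"][col] = (float(lo), float(hi))
    mat = pd.DataFrame(cols, index=attrs.index).sort_index()
    return mat, report


def nmds_axes(
    matrix: pd.DataFrame,
    n_components: int = 2,
    metric: str = "euclidean",
    seed: int = 0,
) -> pd.DataFrame:
    """Non-metric multidimensional scaling of the rescaled parameter matrix.

    Delegated to scikit-learn's SMACOF-based MDS with ``metric=False``;
    axis 1 is oriented to correlate positively with (rescaled) elevation
    when present, so downstream contrasts are invariant to the backend's
    arbitrary sign.
    """
    dist = squareform(pdist(matrix.to_numpy(), metric=metric))
    common = dict(
        n_components=n_components,
        random_state=seed,
        n_init=4,
        max_iter=300,
        normalized_stress=True,
    )
    try:  # scikit-learn ≥ 1.9 parameter names
        mds = MDS(metric="precomputed", metric_mds=False, init="random", **common)
        coords = mds.fit_transform(dist)
    except TypeError:
        mds = MDS(metric=False, dissimilarity="precomputed", **common)
        coords = mds.fit_transform(dist)
    axes = pd.DataFrame(
        coords,
        index=matrix.index,
        columns=[f"NMDS{i + 1}" for i in range(n_components)],
    )
    axes.attrs["stress"] = float(mds.stress_)
    if "elevation_m" in matrix.columns:
        r = np.corrcoef(axes["NMDS1"], matrix["elevation_m"])[0, 1]
        if r < 0:
            axes["NMDS1"] = -axes["NMDS1"]
    return axes


def block_axis_contrast(
    matrix: pd.DataFrame,
    blocks: pd.Series,
    transects: pd.Series,
    seed: int = 0,
    alpha: float = 0.05,
) -> ContrastResult:
    """Compare blocks on NMDS axis 1 with an LMM (block fixed, transect random)."""
    axes = nmds_axes(matrix, seed=seed)
    data = pd.DataFrame(
        {
            "nmds1": axes["NMDS1"],
            "block_id": blocks.reindex(axes.index),
            "transect_id": transects.reindex(axes.index),
        }
    ).reset_index(drop=True)
    spec = ModelSpec(
        response="nmds1",
        fixed="block_id",
        random_nesting=("transect_id",),
        family="gaussian",
    )
    result = fit_and_contrast(data, spec, alpha=alpha)
    result.metadata["nmds_stress"] = axes.attrs["stress"]
    result.metadata["ordination"] = "sklearn.MDS(metric=False) on Euclidean distances"
    return result
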