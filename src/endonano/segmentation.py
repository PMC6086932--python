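"""Cell and endocytic-site segmentation on reconstructed images.

Cells are seeded from peaks of a heavily blurred rendering; the flat
cell-bottom region is the iteratively peeled convex hull of in-mask
localizations, shrunk about its centroid; candidate sites are peaks of a
100 nm rendering inside that region, with oversized connected components
flagged as juxtaposed double sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon
from skimage.measure import label, regionprops

from endonano import loc_ops, tables


@dataclass
class CellRegion:
    """Flat-bottom analysis region of one segmented cell."""

    hull_vertices: np.ndarray  # (k, 2) nm, peeled hull
    shrunk_polygon: np.ndarray  # (k, 2) nm
    localization_indices: np.ndarray  # indices into the source table

    def contains(self, point) -> bool:
        return Polygon(self.shrunk_polygon).buffer(1e-6).contains(Point(*point))


@dataclass
class SitePick:
    """One candidate endocytic site."""

    center_estimate: tuple[float, float]  # nm
    peak_value: float
    excluded_reason: str = "none"  # none | too_large | manual


def segment_cells(
    table: pd.DataFrame,
    blur_sigma_nm: float = 2000.0,
    threshold: float = 1e-4,
    pixel_size_nm: float = 500.0,
) -> list[tuple[float, float]]:
    """Seed one point per cell from peaks of a large-blur rendering.

    Returns peak coordinates (nm).  Minimum seed separation is
    ``2 * blur_sigma_nm``; ``threshold`` is in rendered-density units
    (localizations per pixel after blurring).
    """
    tables.validate_table(table, require=["x_nm", "y_nm"])
    if len(table) == 0:
        return []
    pad = 2 * blur_sigma_nm
    extent = (
        table["x_nm"].min() - pad,
        table["x_nm"].max() + pad,
        table["y_nm"].min() - pad,
        table["y_nm"].max() + pad,
    )
    img = loc_ops.histogram_image(table, pixel_size_nm, extent)
    blurred = ndimage.gaussian_filter(img, blur_sigma_nm / pixel_size_nm)
    if blurred.max() <= threshold:
        return []
    size = max(int(2 * blur_sigma_nm / pixel_size_nm), 1)
    is_peak = (blurred == ndimage.maximum_filter(blurred, size=size)) & (
        blurred > threshold
    )
    rows, cols = np.nonzero(is_peak)
    order = np.argsort(-blurred[rows, cols])
    seeds: list[tuple[float, float]] = []
    min_sep_px = 2 * blur_sigma_nm / pixel_size_nm
    for idx in order:
        r, c = rows[idx], cols[idx]
        if all(np.hypot(r - sr, c - sc) >= min_sep_px for sr, sc in
               [((s[1] - extent[2]) / pixel_size_nm - 0.5, (s[0] - extent[0]) / pixel_size_nm - 0.5) for s in seeds]):
            # refine to the intensity centroid within one blur sigma
            rad = max(int(blur_sigma_nm / pixel_size_nm), 1)
            r0, r1 = max(r - rad, 0), min(r + rad + 1, blurred.shape[0])
            c0, c1 = max(c - rad, 0), min(c + rad + 1, blurred.shape[1])
            patch = blurred[r0:r1, c0:c1]
            rr, cc = np.mgrid[r0:r1, c0:c1]
            w = patch.sum()
            rc = float((rr * patch).sum() / w)
            ccen = float((cc * patch).sum() / w)
            seeds.append(
                (extent[0] + (ccen + 0.5) * pixel_size_nm, extent[2] + (rc + 0.5) * pixel_size_nm)
            )
    return seeds


def _peel_hull(points: np.ndarray, iterations: int) -> np.ndarray:
    """Remove current hull vertices and recompute, ``iterations`` times."""
    pts = np.asarray(points, float)
    for _ in range(iterations):
        try:
            hull = ConvexHull(pts)
        except QhullError as err:
            raise ValueError("fewer than 3 non-collinear points while peeling") from err
        keep = np.ones(len(pts), bool)
        keep[hull.vertices] = False
        remaining = pts[keep]
        if len(remaining) < 3:
            raise ValueError("fewer than 3 points remain after peeling the hull")
        pts = remaining
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise ValueError("fewer than 3 non-collinear points after peeling") from err
    return pts[hull.vertices]


def cell_bottom_region(
    table: pd.DataFrame,
    mask_pixel_nm: float = 200.0,
    mask_threshold: float = 1.0,
    hull_peel: int = 3,
    shrink_fraction: float = 0.30,
) -> CellRegion:
    """Delimit the flat center-bottom of a cell from its localizations.

    The table is rendered at ``mask_pixel_nm`` and thresholded to a rough
    cell mask; the convex hull of in-mask localizations is peeled
    ``hull_peel`` times (dropping the current hull vertices each round) and
    the resulting polygon scaled about its centroid so that its area
    shrinks by at least ``shrink_fraction``.
    """
    tables.validate_table(table, require=["x_nm", "y_nm"])
    if len(table) < 10:
        raise ValueError("at least 10 localizations are required")
    pad = 2 * mask_pixel_nm
    extent = (
        table["x_nm"].min() - pad,
        table["x_nm"].max() + pad,
        table["y_nm"].min() - pad,
        table["y_nm"].max() + pad,
    )
    img = loc_ops.histogram_image(table, mask_pixel_nm, extent)
    mask = img >= mask_threshold
    col = ((table["x_nm"] - extent[0]) / mask_pixel_nm).astype(int).clip(0, img.shape[1] - 1)
    row = ((table["y_nm"] - extent[2]) / mask_pixel_nm).astype(int).clip(0, img.shape[0] - 1)
    in_mask = np.asarray(mask[row, col])
    pts = table.loc[in_mask, ["x_nm", "y_nm"]].to_numpy()
    indices = np.nonzero(in_mask)[0]
    hull_vertices = _peel_hull(pts, hull_peel)
    centroid = Polygon(hull_vertices).centroid
    scale = np.sqrt(1.0 - shrink_fraction)
    shrunk = centroid.coords[0] + scale * (hull_vertices - centroid.coords[0])
    return CellRegion(
        hull_vertices=hull_vertices,
        shrunk_polygon=shrunk,
        localization_indices=indices,
    )


def segment_sites(
    table: pd.DataFrame,
    region: CellRegion,
    site_pixel_nm: float = 100.0,
    threshold: float = 5.0,
    max_extent_nm: float = 600.0,
) -> list[SitePick]:
    """Pick candidate endocytic sites inside a cell-bottom region.

    Peaks of the ``site_pixel_nm`` rendering above ``threshold``
    (localization-equivalents per pixel) that fall inside the shrunk
    polygon become picks; the connected above-threshold component around
    each peak is measured and components whose maximum Feret diameter
    exceeds ``max_extent_nm`` are flagged ``too_large`` (juxtaposed double
    sites).  Centers are refined to the component's intensity centroid.
    """
    tables.validate_table(table, require=["x_nm", "y_nm"])
    if len(table) == 0:
        return []
    poly = Polygon(region.shrunk_polygon)
    pad = 2 * site_pixel_nm
    extent = (
        table["x_nm"].min() - pad,
        table["x_nm"].max() + pad,
        table["y_nm"].min() - pad,
        table["y_nm"].max() + pad,
    )
    img = loc_ops.histogram_image(table, site_pixel_nm, extent)
    smoothed = ndimage.gaussian_filter(img, 0.8)
    above = smoothed > threshold
    if not above.any():
        return []
    labels = label(above, connectivity=2)
    picks: list[SitePick] = []
    for prop in regionprops(labels, intensity_image=smoothed):
        r, c = prop.centroid_weighted
        center = (extent[0] + (c + 0.5) * site_pixel_nm, extent[2] + (r + 0.5) * site_pixel_nm)
        if not poly.buffer(1e-6).contains(Point(*center)):
            continue
        feret = prop.feret_diameter_max * site_pixel_nm
        picks.append(
            SitePick(
                center_estimate=center,
                peak_value=float(prop.intensity_max),
                excluded_reason="too_large" if feret > max_extent_nm else "none",
            )
        )
    picks.sort(key=lambda s: -s.peak_value)
    return picks


def site_localizations(
    table: pd.DataFrame, center: tuple[float, float], radius_nm: float = 250.0
) -> pd.DataFrame:
    """Extract the localizations within ``radius_nm`` of a site center."""
    d = np.hypot(table["x_nm"] - center[0], table["y_nm"] - center[1])
    return table[d <= radius_nm].reset_index(drop=True)


def acquisition_report(table: pd.DataFrame) -> dict:
    """The four quality-control metrics of one experiment."""
    tables.validate_table(table)
    return {
        "median_precision_nm": float(table["precision_nm"].median()) if len(table) else float("nan"),
        "median_background": float(table["bg"].median()) if len(table) else float("nan"),
        "total_localizations": int(len(table)),
        "n_frames": int(table["frame"].max() + 1) if len(table) else 0,
    }
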