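"""Pseudo-time staging by diffraction-limited marker intensity, and
side-view temporal reconstruction.

A site's marker (GFP) intensity is measured on a max projection of the 7
z-slices around focus with wavelet background subtraction and a
triple-Gaussian fit that absorbs overlapping neighbor spots.  Sites are
binned by normalized intensity (no / low / medium / high), and dual-color
side views are ordered by the second channel's axial centroid and averaged
in a sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from endonano import loc_ops, localizer
from endonano.loc_ops import ProjectiveTransform
from endonano.synthetic_data import GfpStack

BINS = ("no", "low", "med", "high")


@dataclass
class StagedSite:
    site_id: int
    gfp_intensity: float
    bin: str = ""
    excluded_overlap: bool = False


@dataclass
class GfpIntensityResult:
    amplitude: float
    fit_ok: bool
    neighbor_amplitudes: tuple[float, float] = (0.0, 0.0)


@dataclass
class SideViewSite:
    """One manually rotated dual-color side-view site (local nm coords)."""

    ch1: pd.DataFrame  # base channel (defines the bottom alignment)
    ch2: pd.DataFrame  # timing channel (defines the pseudo-time order)
    rotation_angle: float  # radians, applied about the joint centroid
    ch1_base: float = float("nan")  # 5th percentile along the axis, filled in
    ch2_centroid: float = float("nan")


# --------------------------------------------------------------------------
# GFP intensity via constrained triple-Gaussian fit


def _triple_gaussian(params, xx, yy, cx, cy):
    a1, a2, x2, y2, a3, x3, y3, s = params
    g1 = a1 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s**2))
    g2 = a2 * np.exp(-((xx - x2) ** 2 + (yy - y2) ** 2) / (2 * s**2))
    g3 = a3 * np.exp(-((xx - x3) ** 2 + (yy - y3) ** 2) / (2 * s**2))
    return g1 + g2 + g3


def gfp_site_intensity(
    stack: GfpStack,
    site_center: tuple[float, float],
    transform: ProjectiveTransform | None = None,
    min_separation_nm: float = 350.0,
    psf_sigma_nm: float = 150.0,
    wavelet_level: int = 3,
    n_projection_slices: int = 7,
) -> GfpIntensityResult:
    """Marker-spot amplitude at one site from a diffraction-limited stack.

    Max-projects the central slices, subtracts the level-``wavelet_level``
    wavelet background, then fits a sum of three isotropic Gaussians with a
    shared width: the first fixed at the (optionally transformed) site
    center, the second and third free but kept at least
    ``min_separation_nm`` from the first and from each other.  The first
    Gaussian's amplitude is returned; on optimizer failure the simple
    background-subtracted value at the center pixel is returned with
    ``fit_ok=False``.
    """
    proj = stack.central_slices(n_projection_slices).max(axis=0)
    image = proj - localizer.wavelet_background(proj, wavelet_level)
    p = stack.pixel_size_nm
    center = np.asarray(site_center, float)
    if transform is not None:
        center = transform.apply(center[None, :])[0]
    cx, cy = center
    ny, nx = image.shape
    xx, yy = np.meshgrid((np.arange(nx) + 0.5) * p, (np.arange(ny) + 0.5) * p)

    ci = int(np.clip(cy / p, 0, ny - 1))
    cj = int(np.clip(cx / p, 0, nx - 1))
    a1_init = max(float(image[ci, cj]), 1e-3)
    # initialize neighbors at the brightest pixels far enough from the center
    far = np.hypot(xx - cx, yy - cy) >= min_separation_nm
    masked = np.where(far, image, -np.inf)
    k2 = np.unravel_index(np.argmax(masked), masked.shape)
    n2 = (xx[k2], yy[k2])
    masked2 = np.where(far & (np.hypot(xx - n2[0], yy - n2[1]) >= min_separation_nm),
                       image, -np.inf)
    k3 = np.unravel_index(np.argmax(masked2), masked2.shape)
    n3 = (xx[k3], yy[k3])

    def residuals(params):
        a1, a2, x2, y2, a3, x3, y3, s = params
        model = _triple_gaussian(params, xx, yy, cx, cy)
        # apply the same (linear) wavelet high-pass the data went through, so
        # the spot energy the background estimate absorbs cancels exactly
        filtered = model - localizer.wavelet_background(model, wavelet_level)
        r = (filtered - image).ravel()
        # soft distance constraints, steeply penalized
        pen = []
        for (xa, ya), (xb, yb) in (((x2, y2), (cx, cy)), ((x3, y3), (cx, cy)),
                                   ((x2, y2), (x3, y3))):
            short = min_separation_nm - np.hypot(xa - xb, ya - yb)
            pen.append(100.0 * max(short, 0.0))
        return np.concatenate([r, pen])

    p0 = np.array([
        a1_init, max(float(image[k2]), 1e-3), n2[0], n2[1],
        max(float(image[k3]), 1e-3), n3[0], n3[1], psf_sigma_nm,
    ])
    lo = [0, 0, -np.inf, -np.inf, 0, -np.inf, -np.inf, 0.3 * psf_sigma_nm]
    hi = [np.inf] * 7 + [3.0 * psf_sigma_nm]
    try:
        sol = optimize.least_squares(residuals, p0, bounds=(lo, hi), max_nfev=2000)
        if not sol.success:
            raise RuntimeError("no convergence")
        return GfpIntensityResult(
            amplitude=float(sol.x[0]),
            fit_ok=True,
            neighbor_amplitudes=(float(sol.x[1]), float(sol.x[4])),
        )
    except Exception:
        return GfpIntensityResult(amplitude=float(image[ci, cj]), fit_ok=False)


# --------------------------------------------------------------------------
# binning


def stage_sites(
    intensities,
    exclusion_factor: float = 1.5,
    no_gfp_factor: float = 0.1,
) -> list[StagedSite]:
    """Bin sites into pseudo-time classes by marker intensity.

    Sites brighter than ``exclusion_factor`` times the 80th percentile of
    all intensities are excluded as unresolvable multi-site overlaps.  The
    80th percentile is then recomputed on the survivors (post-exclusion
    normalization); survivors below ``no_gfp_factor`` times it form the
    "no" bin, and the rest are sorted by intensity and split into three
    contiguous equal-count bins (remainders assigned to the lower bins).
    Percentiles use linear interpolation.
    """
    vals = np.asarray(intensities, float)
    if vals.size < 4:
        raise ValueError("staging requires at least 4 sites")
    p80_all = np.percentile(vals, 80)
    excluded = vals > exclusion_factor * p80_all
    if excluded.all():
        raise ValueError("all sites excluded by the overlap rule")
    survivors = vals[~excluded]
    p80 = np.percentile(survivors, 80)

    sites = [StagedSite(site_id=i, gfp_intensity=float(v)) for i, v in enumerate(vals)]
    for i in np.nonzero(excluded)[0]:
        sites[i].excluded_overlap = True

    surv_idx = np.nonzero(~excluded)[0]
    if p80 <= 0:
        for i in surv_idx:
            sites[i].bin = "no"
        return sites
    no_mask = vals[surv_idx] < no_gfp_factor * p80
    for i in surv_idx[no_mask]:
        sites[i].bin = "no"
    rest = surv_idx[~no_mask]
    order = rest[np.argsort(vals[rest], kind="stable")]
    m = len(order)
    base, rem = divmod(m, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]
    start = 0
    for size, name in zip(sizes, ("low", "med", "high")):
        for i in order[start : start + size]:
            sites[i].bin = name
        start += size
    return sites


def bin_counts(sites: list[StagedSite]) -> dict[str, int]:
    counts = {b: 0 for b in BINS}
    for s in sites:
        if not s.excluded_overlap and s.bin:
            counts[s.bin] += 1
    return counts


# --------------------------------------------------------------------------
# side-view temporal reconstruction


def _rotate_table(table: pd.DataFrame, angle: float, origin: tuple[float, float]) -> pd.DataFrame:
    out = table.copy()
    c, s = np.cos(angle), np.sin(angle)
    x = out["x_nm"].to_numpy(float) - origin[0]
    y = out["y_nm"].to_numpy(float) - origin[1]
    out["x_nm"] = c * x - s * y + origin[0]
    out["y_nm"] = s * x + c * y + origin[1]
    return out


def prepare_sideview_site(site: SideViewSite) -> SideViewSite:
    """Rotate a site, align its base, and compute the timing centroid.

    The supplied rotation (about the joint centroid of both channels) puts
    the direction of membrane invagination along +y.  The base is the 5th
    percentile of channel-1 y positions, subtracted from both channels;
    the timing coordinate is the channel-2 centroid after alignment.
    """
    joint = pd.concat([site.ch1, site.ch2], ignore_index=True)
    origin = (float(joint["x_nm"].mean()), float(joint["y_nm"].mean()))
    ch1 = _rotate_table(site.ch1, site.rotation_angle, origin)
    ch2 = _rotate_table(site.ch2, site.rotation_angle, origin)
    base = float(np.percentile(ch1["y_nm"], 5))
    ch1["y_nm"] -= base
    ch2["y_nm"] -= base
    ch1["x_nm"] -= origin[0]
    ch2["x_nm"] -= origin[0]
    return SideViewSite(
        ch1=ch1,
        ch2=ch2,
        rotation_angle=0.0,
        ch1_base=base,
        ch2_centroid=float(ch2["y_nm"].mean()),
    )


def sideview_reconstruct(
    sites: list[SideViewSite],
    window: int = 7,
    render_pixel_nm: float = 5.0,
    extent_nm: tuple[float, float, float, float] = (-200.0, 200.0, -100.0, 300.0),
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[int]]:
    """Sliding-window (stride 1) averages of sorted side-view sites.

    Sites are prepared (:func:`prepare_sideview_site`), sorted by
    increasing channel-2 centroid, rendered per channel on a common
    window, and averaged over ``window`` consecutive sites.  Returns the
    list of ``(ch1_avg, ch2_avg)`` images and the sort order.
    """
    if len(sites) < window:
        raise ValueError(f"at least {window} sites are required")
    prepared = [prepare_sideview_site(s) for s in sites]
    order = sorted(range(len(prepared)), key=lambda i: prepared[i].ch2_centroid)
    settings = loc_ops.RenderSettings(pixel_size_nm=render_pixel_nm, min_sigma_nm=6.0)
    rendered = [
        (
            loc_ops.render_image(prepared[i].ch1, settings, extent_nm=extent_nm),
            loc_ops.render_image(prepared[i].ch2, settings, extent_nm=extent_nm),
        )
        for i in order
    ]
    averages = []
    for start in range(len(rendered) - window + 1):
        block = rendered[start : start + window]
        averages.append(
            (
                np.mean([b[0] for b in block], axis=0),
                np.mean([b[1] for b in block], axis=0),
            )
        )
    return averages, order
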