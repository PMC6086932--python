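"""Post-processing of localization tables.

Grouping of multi-frame blinks, quality filtering, Gaussian rendering,
drift correction by redundant cross-correlation of time-window images, and
dual-channel projective registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.interpolate import CubicSpline

from endonano import tables


@dataclass
class RenderSettings:
    """How localizations are splatted into a superresolution image."""

    pixel_size_nm: float = 5.0
    min_sigma_nm: float = 6.0
    saturation_quantile: float = 0.999

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.min_sigma_nm < 0:
            raise ValueError("min_sigma_nm must be >= 0")


# --------------------------------------------------------------------------
# grouping and filtering


def group_localizations(
    table: pd.DataFrame, radius: float = 75.0, max_gap: int = 1
) -> pd.DataFrame:
    """Merge blink chains detected in consecutive frames into single records.

    Records in frames separated by at most ``max_gap + 1`` (i.e. up to
    ``max_gap`` dark frames) and within ``radius`` nm are linked greedily
    (nearest neighbor per frame, ties by distance then record order) and
    merged: photon-weighted mean position, summed photons, first frame, and
    inverse-variance recombined precision ``(sum 1/s_i^2)^(-1/2)``.
    """
    tables.validate_table(table)
    if len(table) == 0:
        return table.copy()
    df = table.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = df["frame"].to_numpy()
    x = df["x_nm"].to_numpy()
    y = df["y_nm"].to_numpy()

    # active chains: list of dicts with accumulators
    chains: list[dict] = []
    closed: list[dict] = []
    for f in np.unique(frames):
        still_open = []
        for ch in chains:
            if f - ch["last_frame"] > max_gap + 1:
                closed.append(ch)
            else:
                still_open.append(ch)
        chains = still_open
        idx = np.nonzero(frames == f)[0]
        # candidate links sorted by distance, then record order
        pairs = []
        for ci, ch in enumerate(chains):
            d = np.hypot(x[idx] - ch["x"], y[idx] - ch["y"])
            for k, dist in enumerate(d):
                if dist <= radius:
                    pairs.append((dist, k, ci))
        pairs.sort()
        used_rec: set[int] = set()
        used_chain: set[int] = set()
        for dist, k, ci in pairs:
            if k in used_rec or ci in used_chain:
                continue
            used_rec.add(k)
            used_chain.add(ci)
            chains[ci]["members"].append(idx[k])
            chains[ci]["last_frame"] = f
            chains[ci]["x"] = x[idx[k]]
            chains[ci]["y"] = y[idx[k]]
        for k, i in enumerate(idx):
            if k not in used_rec:
                chains.append(
                    {"members": [i], "last_frame": f, "x": x[i], "y": y[i]}
                )
    closed.extend(chains)

    rows = []
    for ch in closed:
        members = df.iloc[ch["members"]]
        w = members["photons"].to_numpy()
        w = np.where(w > 0, w, 1.0)
        prec = members["precision_nm"].to_numpy()
        inv_var = np.sum(1.0 / np.maximum(prec, 1e-12) ** 2)
        rows.append(
            {
                "frame": int(members["frame"].min()),
                "x_nm": float(np.average(members["x_nm"], weights=w)),
                "y_nm": float(np.average(members["y_nm"], weights=w)),
                "photons": float(members["photons"].sum()),
                "bg": float(members["bg"].mean()),
                "sigma_nm": float(np.average(members["sigma_nm"], weights=w)),
                "precision_nm": float(inv_var**-0.5),
                "channel": int(members["channel"].iloc[0]),
            }
        )
    out = pd.DataFrame(rows, columns=tables.COLUMNS)
    return out.sort_values("frame", kind="stable").reset_index(drop=True)


def filter_localizations(
    table: pd.DataFrame, max_precision: float = 30.0, max_sigma: float = 175.0
) -> pd.DataFrame:
    """Discard records with precision worse than ``max_precision`` nm or PSF
    width above ``max_sigma`` nm; boundary values are kept."""
    tables.validate_table(table, require=["precision_nm", "sigma_nm"])
    keep = (table["precision_nm"] <= max_precision) & (table["sigma_nm"] <= max_sigma)
    return table[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# rendering


def render_image(
    table: pd.DataFrame,
    settings: RenderSettings,
    extent_nm: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Render localizations as unit-integral pixel-integrated Gaussians.

    Each record contributes a Gaussian of standard deviation
    ``max(precision_nm, min_sigma_nm)``; the image sum therefore equals the
    record count up to edge truncation.  ``extent_nm`` is
    ``(x_min, x_max, y_min, y_max)``; by default it is the data bounding box
    padded by 4 maximal sigmas.  Saturation applies only to display export
    (:func:`export_display`), never to the returned array.
    """
    tables.validate_table(table, require=["x_nm", "y_nm", "precision_nm"])
    sigmas = np.maximum(table["precision_nm"].to_numpy(float), settings.min_sigma_nm)
    x = table["x_nm"].to_numpy(float)
    y = table["y_nm"].to_numpy(float)
    p = settings.pixel_size_nm
    if extent_nm is None:
        if len(table) == 0:
            return np.zeros((1, 1))
        pad = 4.0 * (sigmas.max() if len(sigmas) else p)
        extent_nm = (x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)
    x0, x1, y0, y1 = extent_nm
    nx = max(int(np.ceil((x1 - x0) / p)), 1)
    ny = max(int(np.ceil((y1 - y0) / p)), 1)
    image = np.zeros((ny, nx))
    if len(table) == 0:
        return image
    sq2 = np.sqrt(2.0)
    for xi, yi, si in zip(x, y, sigmas):
        half = 6.0 * si  # keeps truncated mass < 1e-8 per record
        cx0 = max(int((xi - half - x0) / p), 0)
        cx1 = min(int((xi + half - x0) / p) + 1, nx)
        cy0 = max(int((yi - half - y0) / p), 0)
        cy1 = min(int((yi + half - y0) / p) + 1, ny)
        if cx0 >= cx1 or cy0 >= cy1:
            continue
        ex = np.arange(cx0, cx1 + 1) * p + x0
        ey = np.arange(cy0, cy1 + 1) * p + y0
        gx = np.diff(0.5 * (1.0 + special.erf((ex - xi) / (sq2 * si))))
        gy = np.diff(0.5 * (1.0 + special.erf((ey - yi) / (sq2 * si))))
        image[cy0:cy1, cx0:cx1] += np.outer(gy, gx)
    return image


def export_display(image: np.ndarray, saturation_quantile: float = 0.999) -> np.ndarray:
    """Contrast-stretch for display: clip at the given brightness quantile."""
    if image.size == 0 or image.max() <= 0:
        return np.zeros_like(image)
    top = np.quantile(image[image > 0], saturation_quantile)
    return np.clip(image / max(top, 1e-12), 0.0, 1.0)


def histogram_image(
    table: pd.DataFrame,
    pixel_size_nm: float,
    extent_nm: tuple[float, float, float, float],
) -> np.ndarray:
    """Fast 2D-histogram rendering (used for drift-correction windows)."""
    x0, x1, y0, y1 = extent_nm
    nx = max(int(np.ceil((x1 - x0) / pixel_size_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / pixel_size_nm)), 1)
    img, _, _ = np.histogram2d(
        table["y_nm"], table["x_nm"], bins=(ny, nx), range=((y0, y1), (x0, x1))
    )
    return img


# --------------------------------------------------------------------------
# drift correction


@dataclass
class DriftResult:
    table: pd.DataFrame
    trajectory: np.ndarray  # (n_frames, 2) estimated drift, nm
    skipped: bool
    reason: str = ""


def _xcorr_shift(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Sub-pixel shift of ``b`` relative to ``a`` by FFT cross-correlation.

    A 3-point quadratic fit around the (wrapped) correlation peak refines
    each axis independently.
    """
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    corr = np.fft.ifft2(fb * np.conj(fa)).real
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = []
    for axis, idx in enumerate(peak):
        n = corr.shape[axis]
        sl = [peak[0], peak[1]]
        vals = []
        for off in (-1, 0, 1):
            sl[axis] = (idx + off) % n
            vals.append(corr[tuple(sl)])
        c_m, c_0, c_p = vals
        denom = c_m - 2.0 * c_0 + c_p
        delta = 0.0 if abs(denom) < 1e-30 else 0.5 * (c_m - c_p) / denom
        pos = idx + np.clip(delta, -0.5, 0.5)
        if pos > n / 2:
            pos -= n
        shift.append(pos)
    # shift[0] is along rows (y), shift[1] along columns (x)
    return shift[1], shift[0]


def drift_correct(
    table: pd.DataFrame,
    n_windows: int = 10,
    min_frames: int = 5000,
    min_drift_nm: float = 10.0,
    render_pixel_nm: float = 10.0,
) -> DriftResult:
    """Estimate and subtract lateral drift via redundant cross-correlation.

    Localizations are binned into ``n_windows`` time windows; all pairwise
    window-image shifts are estimated by FFT cross-correlation with 3-point
    quadratic sub-pixel refinement, the redundant system is solved by least
    squares (window 0 as reference), and the per-frame trajectory is
    obtained by cubic-spline interpolation through the window centers.
    Short movies (< ``min_frames`` frames) and drifts below ``min_drift_nm``
    are skipped: the table is returned unchanged with ``skipped=True``.
    """
    tables.validate_table(table)
    frames = table["frame"].to_numpy()
    if len(table) == 0 or frames.max() == frames.min():
        raise ValueError("drift correction requires localizations in >= 2 frames")
    n_frames = int(frames.max()) + 1
    zero = np.zeros((n_frames, 2))
    if n_frames < min_frames:
        return DriftResult(table.copy(), zero, True, "fewer than min_frames frames")

    edges = np.linspace(frames.min(), frames.max() + 1, n_windows + 1)
    window_of = np.clip(np.searchsorted(edges, frames, side="right") - 1, 0, n_windows - 1)
    pad = 5 * render_pixel_nm
    extent = (
        table["x_nm"].min() - pad,
        table["x_nm"].max() + pad,
        table["y_nm"].min() - pad,
        table["y_nm"].max() + pad,
    )
    images, centers = [], []
    for w in range(n_windows):
        sub = table[window_of == w]
        if len(sub) == 0:
            raise ValueError(f"time window {w} contains no localizations")
        from scipy import ndimage

        # light smoothing stabilizes the sub-pixel quadratic peak fit on
        # sparse histograms
        images.append(ndimage.gaussian_filter(histogram_image(sub, render_pixel_nm, extent), 1.0))
        centers.append(0.5 * (edges[w] + edges[w + 1]))

    # redundant pairwise shifts; unknowns d_1..d_{K-1} with d_0 = 0
    rows_a, rhs_x, rhs_y = [], [], []
    for i in range(n_windows):
        for j in range(i + 1, n_windows):
            sx, sy = _xcorr_shift(images[i], images[j])
            row = np.zeros(n_windows - 1)
            if j > 0:
                row[j - 1] = 1.0
            if i > 0:
                row[i - 1] = -1.0
            rows_a.append(row)
            rhs_x.append(sx * render_pixel_nm)
            rhs_y.append(sy * render_pixel_nm)
    A = np.array(rows_a)
    dx = np.concatenate([[0.0], np.linalg.lstsq(A, np.array(rhs_x), rcond=None)[0]])
    dy = np.concatenate([[0.0], np.linalg.lstsq(A, np.array(rhs_y), rcond=None)[0]])

    spline_x = CubicSpline(centers, dx, bc_type="natural")
    spline_y = CubicSpline(centers, dy, bc_type="natural")
    t = np.arange(n_frames)
    traj = np.column_stack([spline_x(t), spline_y(t)])
    if np.abs(traj).max() < min_drift_nm:
        return DriftResult(table.copy(), zero, True, "estimated drift below min_drift")

    out = table.copy()
    out["x_nm"] = out["x_nm"] - traj[frames, 0]
    out["y_nm"] = out["y_nm"] - traj[frames, 1]
    return DriftResult(out, traj, False)


# --------------------------------------------------------------------------
# channel registration


@dataclass
class ProjectiveTransform:
    """Homography mapping the moving channel onto the reference channel."""

    matrix: np.ndarray  # 3x3
    rms_error: float
    n_control_points: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        h = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return h[:, :2] / h[:, 2:3]

    def inverse(self) -> "ProjectiveTransform":
        return ProjectiveTransform(
            np.linalg.inv(self.matrix), self.rms_error, self.n_control_points
        )


def _collinear(points: np.ndarray) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] < 1e-9 * max(s[0], 1.0)


def estimate_channel_transform(
    ref_points: np.ndarray, moving_points: np.ndarray
) -> ProjectiveTransform:
    """Least-squares projective transform taking moving points to reference.

    Requires at least 5 non-collinear point pairs (one more than the
    homography's 4-point minimum, so the fit is overdetermined and an RMS
    residual is meaningful).
    """
    ref = np.asarray(ref_points, float)
    mov = np.asarray(moving_points, float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("point sets must be matching (n, 2) arrays")
    if len(ref) < 5:
        raise ValueError("at least 5 point pairs are required")
    if _collinear(ref) or _collinear(mov):
        raise ValueError("control points are collinear")
    matrix = _dlt_homography(mov, ref)
    out = ProjectiveTransform(matrix=matrix, rms_error=0.0, n_control_points=len(ref))
    mapped = out.apply(mov)
    out.rms_error = float(np.sqrt(np.mean(np.sum((mapped - ref) ** 2, axis=1))))
    return out


def _normalization(points: np.ndarray) -> np.ndarray:
    mean = points.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.hypot(*(points - mean).T)), 1e-12)
    return np.array([
        [scale, 0.0, -scale * mean[0]],
        [0.0, scale, -scale * mean[1]],
        [0.0, 0.0, 1.0],
    ])


def _dlt_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized direct linear transform for the homography src -> dst."""
    t_src = _normalization(src)
    t_dst = _normalization(dst)
    s = (np.column_stack([src, np.ones(len(src))]) @ t_src.T)[:, :2]
    d = (np.column_stack([dst, np.ones(len(dst))]) @ t_dst.T)[:, :2]
    n = len(s)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = s
    A[0::2, 2] = 1.0
    A[0::2, 6:8] = -d[:, 0:1] * s
    A[0::2, 8] = -d[:, 0]
    A[1::2, 3:5] = s
    A[1::2, 5] = 1.0
    A[1::2, 6:8] = -d[:, 1:2] * s
    A[1::2, 8] = -d[:, 1]
    _, _, vt = np.linalg.svd(A)
    h = vt[-1].reshape(3, 3)
    matrix = np.linalg.inv(t_dst) @ h @ t_src
    return matrix / matrix[2, 2]


def apply_transform(table: pd.DataFrame, transform: ProjectiveTransform) -> pd.DataFrame:
    """Map a localization table's coordinates through a channel transform."""
    tables.validate_table(table, require=["x_nm", "y_nm"])
    out = table.copy()
    mapped = transform.apply(out[["x_nm", "y_nm"]].to_numpy())
    out["x_nm"] = mapped[:, 0]
    out["y_nm"] = mapped[:, 1]
    return out
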