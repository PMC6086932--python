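"""Single-emitter detection and fitting in raw camera frames.

Peaks are found on a smoothed, wavelet-background-subtracted image with
non-maximum suppression, then each candidate ROI is fitted with a
pixel-integrated 2D Gaussian under a Poisson noise model by a damped
per-coordinate Newton iteration.  Localization precision is reported as the
square root of the Cramér–Rao lower bound diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special

from endonano import tables

# B3-spline scaling kernel of the à-trous transform
_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class DetectionParams:
    """Tunable knobs of the peak detector."""

    wavelet_level: int = 3
    nms_radius: int = 3  # pixels
    threshold_factor: float = 5.0  # multiples of robust noise SD
    roi_size: int = 13  # pixels, odd

    def __post_init__(self) -> None:
        if self.roi_size < 5 or self.roi_size % 2 == 0:
            raise ValueError("roi_size must be odd and >= 5")
        if self.wavelet_level < 1:
            raise ValueError("wavelet_level must be >= 1")


@dataclass
class FitResult:
    """One fitted emitter; positions in pixels relative to the ROI origin."""

    x: float
    y: float
    photons: float
    background: float
    sigma: float
    precision: float  # per-axis CRLB sqrt, pixels
    log_likelihood: float
    converged: bool


def wavelet_background(image: np.ndarray, level: int = 3) -> np.ndarray:
    """Smooth background via the à-trous B3-spline approximation at ``level``.

    The transform convolves repeatedly with the B3 kernel dilated by 2^j
    (mirror boundary), so the operation is linear and shift-equivariant.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    support = 4 * 2 ** (level - 1) + 1
    if min(image.shape) < support:
        raise ValueError(
            f"image smaller than the level-{level} kernel support ({support} px)"
        )
    approx = image
    for j in range(level):
        holes = 2**j
        kernel = np.zeros(4 * holes + 1)
        kernel[::holes] = _B3
        approx = ndimage.convolve1d(approx, kernel, axis=0, mode="mirror")
        approx = ndimage.convolve1d(approx, kernel, axis=1, mode="mirror")
    return approx


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_peaks(image: np.ndarray, params: DetectionParams) -> list[tuple[int, int]]:
    """Candidate emitter pixels as (row, col), brightest first.

    Local maxima of the smoothed, background-subtracted image that exceed
    ``threshold_factor`` times the robust noise SD (1.4826 x MAD) survive
    non-maximum suppression within ``nms_radius``.  Ties break by intensity,
    then row-major order.
    """
    image = np.asarray(image, float)
    bg = wavelet_background(image, params.wavelet_level)
    smoothed = ndimage.gaussian_filter(image - bg, sigma=1.0, mode="mirror")
    noise_sd = _robust_sd(smoothed)
    # epsilon floor keeps exactly-flat (or noiseless) images from yielding
    # spurious peaks at the float rounding level
    threshold = params.threshold_factor * noise_sd + 1e-9 * (np.ptp(image) + 1.0)
    size = 2 * params.nms_radius + 1
    local_max = smoothed == ndimage.maximum_filter(smoothed, size=size, mode="mirror")
    rows, cols = np.nonzero(local_max & (smoothed > threshold))
    order = np.lexsort((cols, rows, -smoothed[rows, cols]))
    kept: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        if all(max(abs(r - kr), abs(c - kc)) > params.nms_radius for kr, kc in kept):
            kept.append((r, c))
    return kept


# --------------------------------------------------------------------------
# pixelated-Gaussian Poisson MLE (batched)


def _pixel_profiles(n: int, mu: np.ndarray, sigma: np.ndarray):
    """Integrated 1D Gaussian per pixel plus d/dmu, d/dsigma; shapes (B, n)."""
    edges = np.arange(n + 1, dtype=float)[None, :]  # (1, n+1)
    mu = mu[:, None]
    sigma = sigma[:, None]
    z = (edges - mu) / (np.sqrt(2.0) * sigma)
    cdf = 0.5 * (1.0 + special.erf(z))
    pdf = np.exp(-(z**2)) / (np.sqrt(2.0 * np.pi) * sigma)
    e = np.diff(cdf, axis=1)
    de_dmu = -np.diff(pdf, axis=1)
    de_dsigma = -np.diff(pdf * (edges - mu) / sigma, axis=1)
    return e, de_dmu, de_dsigma


def _model_and_derivs(theta: np.ndarray, n: int, fit_sigma: bool):
    """Poisson means and parameter derivatives for a batch of ROIs.

    ``theta`` has columns (x, y, N, b[, sigma]); returns mean (B, n, n) and a
    list of derivative images per parameter.
    """
    x, y, N, b = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
    sigma = theta[:, 4]
    ex, dex_dx, dex_ds = _pixel_profiles(n, x, sigma)
    ey, dey_dy, dey_ds = _pixel_profiles(n, y, sigma)
    outer = ey[:, :, None] * ex[:, None, :]
    mu = N[:, None, None] * outer + b[:, None, None]
    d_x = N[:, None, None] * ey[:, :, None] * dex_dx[:, None, :]
    d_y = N[:, None, None] * dey_dy[:, :, None] * ex[:, None, :]
    d_N = outer
    d_b = np.ones_like(mu)
    derivs = [d_x, d_y, d_N, d_b]
    if fit_sigma:
        d_s = N[:, None, None] * (
            dey_ds[:, :, None] * ex[:, None, :] + ey[:, :, None] * dex_ds[:, None, :]
        )
        derivs.append(d_s)
    return mu, derivs


def _crlb(theta: np.ndarray, n: int, fit_sigma: bool) -> np.ndarray:
    """CRLB sqrt of the x coordinate, per batch element (pixels)."""
    mu, derivs = _model_and_derivs(theta, n, fit_sigma)
    k = len(derivs)
    fisher = np.empty((theta.shape[0], k, k))
    inv_mu = 1.0 / np.maximum(mu, 1e-12)
    for i in range(k):
        for j in range(i, k):
            fisher[:, i, j] = fisher[:, j, i] = np.sum(
                derivs[i] * derivs[j] * inv_mu, axis=(1, 2)
            )
    out = np.full(theta.shape[0], np.nan)
    for b in range(theta.shape[0]):
        try:
            cov = np.linalg.inv(fisher[b])
            out[b] = np.sqrt(max(cov[0, 0], 0.0))
        except np.linalg.LinAlgError:
            pass
    return out


def fit_mle_batch(
    rois: np.ndarray,
    psf_sigma_px: float = 1.2,
    fit_sigma: bool = True,
    max_iter: int = 50,
    tol: float = 1e-3,
):
    """Fit a batch of square ROIs; returns (theta, precision_px, ll, converged).

    The estimator maximizes the Poisson log-likelihood of the pixel-integrated
    Gaussian model by damped per-parameter Newton steps (second derivative
    along each coordinate, off-diagonal terms dropped), at most ``max_iter``
    iterations, declaring convergence when every parameter step drops below
    ``tol`` in its own units.
    """
    rois = np.asarray(rois, float)
    if rois.ndim == 2:
        rois = rois[None]
    B, n, n2 = rois.shape
    if n != n2:
        raise ValueError("ROIs must be square")
    if (rois < 0).any():
        raise ValueError("ROIs must be nonnegative")

    # init: background from the border, position from center of mass
    border = np.concatenate(
        [rois[:, 0, :], rois[:, -1, :], rois[:, :, 0], rois[:, :, -1]], axis=1
    )
    b0 = np.median(border, axis=1)
    resid = np.clip(rois - b0[:, None, None], 0.0, None)
    total = resid.sum(axis=(1, 2))
    safe = np.maximum(total, 1e-9)
    idx = np.arange(n) + 0.5
    x0 = (resid.sum(axis=1) * idx).sum(axis=1) / safe
    y0 = (resid.sum(axis=2) * idx).sum(axis=1) / safe
    x0 = np.where(total > 0, x0, n / 2.0)
    y0 = np.where(total > 0, y0, n / 2.0)
    theta = np.column_stack(
        [x0, y0, np.maximum(total, 1e-6), np.maximum(b0, 1e-6), np.full(B, psf_sigma_px)]
    )
    k = 5 if fit_sigma else 4
    lo = np.array([0.0, 0.0, 1e-9, 1e-9, 0.3][:k])
    hi = np.array([float(n), float(n), 1e9, 1e9, n / 2.0][:k])

    converged = np.zeros(B, bool)
    for _ in range(max_iter):
        mu, derivs = _model_and_derivs(theta, n, fit_sigma)
        mu = np.maximum(mu, 1e-12)
        ratio = rois / mu
        max_step = np.zeros(B)
        for i in range(k):
            d1 = np.sum((1.0 - ratio) * derivs[i], axis=(1, 2))
            d2 = np.sum(ratio / mu * derivs[i] ** 2, axis=(1, 2))
            step = d1 / np.maximum(d2, 1e-12)
            # clamp: position moves at most 1 px, scale params at most 50 %
            if i < 2:
                step = np.clip(step, -1.0, 1.0)
            else:
                step = np.clip(step, -0.5 * np.abs(theta[:, i]) - 1.0,
                                0.5 * np.abs(theta[:, i]) + 1.0)
            new = np.clip(theta[:, i] - step, lo[i], hi[i])
            max_step = np.maximum(max_step, np.abs(new - theta[:, i]))
            theta[:, i] = new
        newly = max_step < tol
        converged |= newly
        if converged.all():
            break

    mu, _ = _model_and_derivs(theta, n, fit_sigma)
    mu = np.maximum(mu, 1e-12)
    ll = np.sum(rois * np.log(mu) - mu - special.gammaln(rois + 1.0), axis=(1, 2))
    precision = _crlb(theta, n, fit_sigma)
    return theta, precision, ll, converged


def fit_mle_gaussian(
    roi: np.ndarray,
    psf_sigma_px: float = 1.2,
    fit_sigma: bool = True,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> FitResult:
    """Fit one ROI; see :func:`fit_mle_batch` for the algorithm."""
    theta, precision, ll, converged = fit_mle_batch(
        roi, psf_sigma_px=psf_sigma_px, fit_sigma=fit_sigma, max_iter=max_iter, tol=tol
    )
    t = theta[0]
    return FitResult(
        x=float(t[0]),
        y=float(t[1]),
        photons=float(t[2]),
        background=float(t[3]),
        sigma=float(t[4]),
        precision=float(precision[0]),
        log_likelihood=float(ll[0]),
        converged=bool(converged[0]),
    )


def localize_frames(
    stack: np.ndarray,
    pixel_size_nm: float,
    params: DetectionParams | None = None,
    psf_sigma_px: float = 1.2,
    camera_baseline: float = 0.0,
) -> pd.DataFrame:
    """Detect and fit emitters in every frame; returns a localization table."""
    if params is None:
        params = DetectionParams()
    stack = np.asarray(stack, float) - camera_baseline
    half = params.roi_size // 2
    rois, meta = [], []
    for f, frame in enumerate(stack):
        for r, c in detect_peaks(frame, params):
            if r - half < 0 or c - half < 0 or r + half + 1 > frame.shape[0] or c + half + 1 > frame.shape[1]:
                continue
            rois.append(frame[r - half : r + half + 1, c - half : c + half + 1])
            meta.append((f, r, c))
    if not rois:
        return tables.empty_table()
    theta, precision, ll, converged = fit_mle_batch(
        np.array(rois), psf_sigma_px=psf_sigma_px
    )
    frames = np.array([m[0] for m in meta])
    rows = np.array([m[1] for m in meta], float)
    cols = np.array([m[2] for m in meta], float)
    x_nm = (cols - half + theta[:, 0]) * pixel_size_nm
    y_nm = (rows - half + theta[:, 1]) * pixel_size_nm
    table = tables.make_table(
        frame=frames,
        x_nm=x_nm,
        y_nm=y_nm,
        photons=theta[:, 2],
        bg=theta[:, 3],
        sigma_nm=theta[:, 4] * pixel_size_nm,
        precision_nm=precision * pixel_size_nm,
        channel=np.zeros(len(meta), int),
    )
    return table[converged & np.isfinite(precision)].reset_index(drop=True)
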