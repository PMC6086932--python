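"""Geometric ring/patch analysis of endocytic sites.

The central model describes a site's localization density as a blurred
annulus: an amplitude-scaled difference of error functions of the distance
to the center, parameterized by outer radius ``r_out`` and rim thickness
``dr`` with a fixed 15 nm blur.  Rings have ``dr < r_out`` (a central
hole); patches have ``dr >= r_out``.  This module fits that model to
rendered single-site images, computes radial density profiles, aligns and
averages sites, classifies the average shape, and provides the summary
statistics and rank-sum test used throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from endonano import loc_ops, tables

#: fixed model blur approximating the localization precision, nm
MODEL_SIGMA = 15.0

EXCLUSION_POLICIES = ("general", "coat_scission")


@dataclass
class GeometricModel:
    """Parameters of the blurred-annulus density."""

    x0: float
    y0: float
    r_out: float
    dr: float
    A: float = 1.0
    sigma: float = MODEL_SIGMA

    def __post_init__(self) -> None:
        if not self.r_out > 0:
            raise ValueError("r_out must be > 0")
        if not self.dr > 0:
            raise ValueError("dr must be > 0")
        if self.A < 0:
            raise ValueError("A must be >= 0")

    @property
    def is_ring(self) -> bool:
        return self.dr < self.r_out


@dataclass
class SiteFit:
    """Fit outcome and exclusion status for one site."""

    model: GeometricModel
    n_localizations: int
    residual_ss: float
    excluded: bool = False
    exclusion_reason: str = "none"  # none | small_radius | few_locs | fit_failure


@dataclass
class RadialProfile:
    """Binned localization density versus distance from the site center."""

    bin_edges: np.ndarray  # (k+1,) nm
    counts: np.ndarray  # (k,)
    density: np.ndarray  # (k,) counts / nm^2, annulus-area normalized
    normalization: str = "counts"  # counts | area | peak

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ModuleSummary:
    """Aggregate description of one protein's site population."""

    mean_r_out: float
    sd_r_out: float
    sem_r_out: float
    n_sites: int
    ring_fraction: float
    mean_dr: float = float("nan")
    hwhm_nm: float = float("nan")
    shape_class: str = ""


# --------------------------------------------------------------------------
# model evaluation and image fitting


def model_density(model: GeometricModel, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Blurred-annulus density evaluated on congruent coordinate grids (nm)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError("X and Y grids must be congruent")
    R = np.hypot(X - model.x0, Y - model.y0)
    s = np.sqrt(2.0) * model.sigma
    return model.A * (
        special.erf((model.r_out - R) / s) - special.erf((model.r_out - model.dr - R) / s)
    )


_BOUNDS = {"r_out": (5.0, 300.0), "dr": (5.0, 600.0)}


def _profiled_objective(params, image, X, Y, sigma):
    """Residual sum of squares with the amplitude solved linearly."""
    x0, y0, r_out, dr = params
    lo_r, hi_r = _BOUNDS["r_out"]
    lo_d, hi_d = _BOUNDS["dr"]
    penalty = 0.0
    if not (lo_r <= r_out <= hi_r) or not (lo_d <= dr <= hi_d):
        penalty = 1e6 * (
            max(0.0, lo_r - r_out) + max(0.0, r_out - hi_r)
            + max(0.0, lo_d - dr) + max(0.0, dr - hi_d)
        )
        r_out = np.clip(r_out, lo_r, hi_r)
        dr = np.clip(dr, lo_d, hi_d)
    g = model_density(GeometricModel(x0, y0, r_out, dr, A=1.0, sigma=sigma), X, Y)
    gg = float(np.sum(g * g))
    A = max(0.0, float(np.sum(image * g)) / gg) if gg > 0 else 0.0
    resid = image - A * g
    return float(np.sum(resid * resid)) * (1.0 + penalty)


def fit_density_image(
    image: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    init: GeometricModel | None = None,
    sigma: float = MODEL_SIGMA,
    n_restarts: int = 2,
    seed: int = 0,
    xatol: float = 1e-3,
) -> tuple[GeometricModel, float]:
    """Least-squares fit of the blurred-annulus model to a rendered image.

    The amplitude is profiled out analytically at every objective
    evaluation; the four shape parameters are optimized by bounded
    Nelder-Mead simplex with ``n_restarts`` perturbed restarts, keeping the
    lowest residual.  Returns the fitted model and its residual sum of
    squares.
    """
    if init is None:
        total = image.sum()
        if total <= 0:
            raise ValueError("image has no signal to initialize from")
        cx = float(np.sum(X * image) / total)
        cy = float(np.sum(Y * image) / total)
        rms = float(np.sqrt(np.sum(((X - cx) ** 2 + (Y - cy) ** 2) * image) / total))
        init = GeometricModel(cx, cy, max(rms * 1.2, 10.0), max(rms, 10.0), sigma=sigma)
    rng = np.random.default_rng(seed)
    p0 = np.array([init.x0, init.y0, init.r_out, init.dr])
    best = None
    for attempt in range(1 + n_restarts):
        start = p0 if attempt == 0 else p0 + rng.normal(0.0, [10.0, 10.0, 15.0, 15.0])
        start[2] = np.clip(start[2], *_BOUNDS["r_out"])
        start[3] = np.clip(start[3], *_BOUNDS["dr"])
        res = optimize.minimize(
            _profiled_objective,
            start,
            args=(image, X, Y, sigma),
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": 1e-14, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    x0, y0, r_out, dr = best.x
    r_out = float(np.clip(r_out, *_BOUNDS["r_out"]))
    dr = float(np.clip(dr, *_BOUNDS["dr"]))
    g = model_density(GeometricModel(x0, y0, r_out, dr, A=1.0, sigma=sigma), X, Y)
    gg = float(np.sum(g * g))
    A = max(0.0, float(np.sum(image * g)) / gg) if gg > 0 else 0.0
    model = GeometricModel(float(x0), float(y0), r_out, dr, A=A, sigma=sigma)
    return model, float(best.fun)


def pixel_center_grids(
    extent_nm: tuple[float, float, float, float], pixel_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinate grids matching :func:`loc_ops.render_image`."""
    x0, x1, y0, y1 = extent_nm
    nx = max(int(np.ceil((x1 - x0) / pixel_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / pixel_nm)), 1)
    xc = x0 + (np.arange(nx) + 0.5) * pixel_nm
    yc = y0 + (np.arange(ny) + 0.5) * pixel_nm
    return np.meshgrid(xc, yc)


def fit_site(
    site_table: pd.DataFrame,
    render_pixel_nm: float = 3.0,
    init: GeometricModel | None = None,
    policy: str = "general",
    min_localizations: int = 30,
    min_r_out: float = 30.0,
    half_size_nm: float = 200.0,
    model_sigma: float | None = None,
    seed: int = 0,
) -> SiteFit:
    """Render one site at 3 nm pixels and fit the blurred-annulus model.

    The render window is centered on the localization centroid (so the fit
    is exactly translation-equivariant) with half-width ``half_size_nm``.
    ``model_sigma`` is the blur of the fitted density; by default it is
    derived from the data as the median of
    ``sqrt(precision^2 + render_sigma^2)`` — the rendered image is blurred
    both by the localization scatter (~precision) and by the Gaussian
    rendering kernel, and an unbiased radius estimate requires the model
    blur to match that combined width.  Pass ``model_sigma=MODEL_SIGMA``
    to force the fixed 15 nm convention instead.
    Exclusion rules are applied per ``policy``: ``"general"`` excludes
    sites with fewer than ``min_localizations`` records or fitted
    ``r_out < min_r_out``; ``"coat_scission"`` applies the count rule only.
    """
    if policy not in EXCLUSION_POLICIES:
        raise ValueError(f"unknown exclusion policy {policy!r}")
    tables.validate_table(site_table, require=["x_nm", "y_nm", "precision_nm"])
    n = len(site_table)
    if n < 5:
        raise ValueError("at least 5 localizations are required to fit a site")
    cx = float(site_table["x_nm"].mean())
    cy = float(site_table["y_nm"].mean())
    extent = (cx - half_size_nm, cx + half_size_nm, cy - half_size_nm, cy + half_size_nm)
    settings = loc_ops.RenderSettings(pixel_size_nm=render_pixel_nm, min_sigma_nm=6.0)
    image = loc_ops.render_image(site_table, settings, extent_nm=extent)
    X, Y = pixel_center_grids(extent, render_pixel_nm)
    if model_sigma is None:
        scatter = site_table["precision_nm"].to_numpy(float)
        render_s = np.maximum(scatter, settings.min_sigma_nm)
        model_sigma = float(np.median(np.sqrt(scatter**2 + render_s**2)))
    try:
        model, rss = fit_density_image(image, X, Y, init=init, sigma=model_sigma, seed=seed)
    except ValueError:
        fallback = init or GeometricModel(cx, cy, 50.0, 50.0, A=0.0)
        return SiteFit(fallback, n, float("inf"), excluded=True, exclusion_reason="fit_failure")
    fit = SiteFit(model, n, rss)
    if n < min_localizations:
        fit.excluded = True
        fit.exclusion_reason = "few_locs"
    elif policy == "general" and model.r_out < min_r_out:
        fit.excluded = True
        fit.exclusion_reason = "small_radius"
    return fit


# --------------------------------------------------------------------------
# radial profiles, averaging, classification


def radial_profile(
    site_table: pd.DataFrame,
    center: tuple[float, float],
    bin_width_nm: float = 5.0,
    max_r_nm: float = 250.0,
) -> RadialProfile:
    """Histogram of localization distances from ``center``.

    Half-open bins ``[k*w, (k+1)*w)``; density is counts divided by the
    annulus area of each bin.
    """
    tables.validate_table(site_table, require=["x_nm", "y_nm"])
    r = np.hypot(
        site_table["x_nm"].to_numpy(float) - center[0],
        site_table["y_nm"].to_numpy(float) - center[1],
    )
    edges = np.arange(0.0, max_r_nm + bin_width_nm, bin_width_nm)
    counts, _ = np.histogram(r, bins=edges)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return RadialProfile(bin_edges=edges, counts=counts, density=counts / areas)


def profile_hwhm(profile: RadialProfile) -> float:
    """Half width at half maximum of a radial density profile.

    Measured outward from the density maximum to the radius where the
    linearly interpolated density first crosses half the maximum.
    """
    d = np.asarray(profile.density, float)
    if d.max() <= 0:
        return float("nan")
    centers = profile.bin_centers
    k = int(np.argmax(d))
    half = d[k] / 2.0
    for i in range(k, len(d) - 1):
        if d[i] >= half >= d[i + 1]:
            frac = (d[i] - half) / max(d[i] - d[i + 1], 1e-30)
            return float(centers[i] + frac * (centers[i + 1] - centers[i]) - centers[k])
    return float(centers[-1] - centers[k])


def summary_stats(values) -> tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator), and SEM = SD / sqrt(n)."""
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("summary_stats requires at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd, sd / np.sqrt(arr.size)


def sem_from_sd(sd: float, n: int) -> float:
    """Standard error of the mean from a known SD and sample size."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sd / np.sqrt(n)


def align_and_average(
    fits: list[SiteFit],
    site_tables: list[pd.DataFrame],
    render_pixel_nm: float = 3.0,
    half_size_nm: float = 250.0,
    bin_width_nm: float = 5.0,
) -> tuple[np.ndarray, RadialProfile, ModuleSummary]:
    """Align sites by their fitted centers; average images and profiles.

    Only non-excluded sites contribute.  The average image is the mean of
    center-translated renderings on a common ``[-half, half]^2`` window;
    the average profile carries summed counts and mean density.  The
    summary holds mean/SD/SEM of ``r_out``, the ring fraction
    (``dr < r_out``), the mean ``dr``, the HWHM of the average profile, and
    the shape class.
    """
    kept = [(f, t) for f, t in zip(fits, site_tables) if not f.excluded]
    if not kept:
        raise ValueError("all sites are excluded; nothing to average")
    settings = loc_ops.RenderSettings(pixel_size_nm=render_pixel_nm, min_sigma_nm=6.0)
    extent = (-half_size_nm, half_size_nm, -half_size_nm, half_size_nm)
    image_sum = None
    profiles = []
    for f, t in kept:
        centered = t.copy()
        centered["x_nm"] = centered["x_nm"] - f.model.x0
        centered["y_nm"] = centered["y_nm"] - f.model.y0
        img = loc_ops.render_image(centered, settings, extent_nm=extent)
        image_sum = img if image_sum is None else image_sum + img
        profiles.append(radial_profile(centered, (0.0, 0.0), bin_width_nm, half_size_nm))
    avg_image = image_sum / len(kept)
    counts = np.sum([p.counts for p in profiles], axis=0)
    density = np.mean([p.density for p in profiles], axis=0)
    avg_profile = RadialProfile(profiles[0].bin_edges, counts, density)

    r_outs = [f.model.r_out for f, _ in kept]
    mean, sd, sem = summary_stats(r_outs)
    ring_fraction = float(np.mean([f.model.is_ring for f, _ in kept]))
    summary = ModuleSummary(
        mean_r_out=mean,
        sd_r_out=sd,
        sem_r_out=sem,
        n_sites=len(kept),
        ring_fraction=ring_fraction,
        mean_dr=float(np.mean([f.model.dr for f, _ in kept])),
        hwhm_nm=profile_hwhm(avg_profile),
    )
    summary.shape_class = classify_shape(summary, avg_profile)
    return avg_image, avg_profile, summary


def classify_shape(summary: ModuleSummary, profile: RadialProfile) -> str:
    """Dome / ring / patch decision for an averaged site population.

    Dome: mean outer radius above 80 nm with only a slight central minimum
    (central density more than 80 % of the profile maximum).  Otherwise a
    ring if the average rim is thinner than the outer radius, else a patch
    (``dr >= r_out``, no hole).
    """
    d = np.asarray(profile.density, float)
    if summary.mean_r_out > 80.0 and d.max() > 0 and d[0] > 0.8 * d.max():
        return "dome"
    if summary.mean_dr < summary.mean_r_out:
        return "ring"
    return "patch"


# --------------------------------------------------------------------------
# rank-sum test


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _u_statistic(ranks: np.ndarray, idx_a: tuple, n_a: int) -> float:
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def rank_sum_test(sample_a, sample_b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    For ``min(n_a, n_b) <= exact_max_n`` the null distribution of U is
    enumerated over all group assignments of the observed midranks; the
    two-sided p is twice the smaller tail (capped at 1).  Otherwise a
    normal approximation with tie correction and continuity correction is
    used.  Returns ``(U, p)`` with U taken for the first sample.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    u_obs = _u_statistic(ranks, tuple(range(n_a)), n_a)

    if min(n_a, n_b) <= exact_max_n:
        n = n_a + n_b
        lo = hi = 0
        total = 0
        for idx in itertools.combinations(range(n), n_a):
            u = _u_statistic(ranks, idx, n_a)
            lo += u <= u_obs + 1e-12
            hi += u >= u_obs - 1e-12
            total += 1
        p = min(1.0, 2.0 * min(lo / total, hi / total))
        return u_obs, p

    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = max(abs(u_obs - mu) - 0.5, 0.0) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(z)
    return u_obs, min(1.0, p)
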