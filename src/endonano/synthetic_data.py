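"""Synthetic ground truth, localization tables, raw frames, and GFP stacks.

Every input the pipeline consumes can be generated here with known
parameters, so each downstream stage is testable by parameter recovery.
Molecule positions are drawn from the same annular density the geometric
model fits (with the blur set to zero — blur enters through the emission
model), domes are uniform-on-hemisphere points projected to the plane, and
blinking follows a geometric blink-count model with truncated-Gaussian
per-blink precision.

Units: nanometres everywhere, origin at the field corner.  Pixel ``(i, j)``
of a camera with pixel size ``p`` covers ``[i*p, (i+1)*p)`` per axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from endonano import tables

SHAPES = ("ring", "patch", "dome")

# --------------------------------------------------------------------------
# domain types


@dataclass
class StructureSpec:
    """Ground-truth geometry of one site.

    ``r_out`` is the outer radius and ``dr`` the rim thickness; a patch is
    the degenerate case ``dr >= r_out`` (no central hole).  ``dome_height``
    is only meaningful for ``shape == "dome"``.
    """

    shape: str
    center: tuple[float, float]
    r_out: float
    dr: float
    n_molecules: int
    dome_height: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(
                f"invalid value for field 'shape': {self.shape!r}; "
                f"expected one of {SHAPES}"
            )
        if not self.r_out > 0:
            raise ValueError("r_out must be > 0")
        if not self.dr > 0:
            raise ValueError("dr must be > 0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    @property
    def is_patch(self) -> bool:
        return self.dr >= self.r_out


@dataclass
class EmissionModel:
    """Photoswitching / detection statistics used to turn molecules into blinks.

    ``background_rate`` is a spurious-localization density in events/µm²
    (per whole acquisition, not per frame).
    """

    mean_blinks: float = 3.0
    blink_gap_prob: float = 0.2
    precision_mean: float = 15.0
    precision_sd: float = 4.0
    psf_sigma: float = 120.0
    photons_mean: float = 1000.0
    background_rate: float = 0.0

    #: hard floor on a drawn per-blink precision, nm
    precision_floor: float = 1.0

    def __post_init__(self) -> None:
        if not self.precision_mean >= 0:
            raise ValueError("precision_mean must be >= 0")
        for name in ("mean_blinks", "photons_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("precision_sd", "background_rate", "blink_gap_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CameraModel:
    """Pixel grid and photon-background description for frame rendering."""

    pixel_size_nm: float
    width_px: int
    height_px: int
    background: float = 0.0  # photons / pixel / frame
    baseline: float = 0.0  # camera offset, counts

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("frame geometry must be at least 1x1 pixels")

    @property
    def fov_nm(self) -> tuple[float, float]:
        return (self.width_px * self.pixel_size_nm, self.height_px * self.pixel_size_nm)


@dataclass
class GfpLayout:
    """Geometry of a diffraction-limited z-stack."""

    n_slices: int = 81
    z_step_nm: float = 50.0
    psf_sigma_nm: float = 150.0
    pixel_size_nm: float = 100.0
    width_px: int = 64
    height_px: int = 64
    background: float = 0.0
    z_sigma_nm: float = 600.0  # axial amplitude decay scale
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @property
    def focus_index(self) -> int:
        return self.n_slices // 2


@dataclass
class GfpStack:
    """Diffraction-limited z-stack with its geometry."""

    data: np.ndarray  # (n_slices, height, width)
    pixel_size_nm: float
    z_step_nm: float
    focus_index: int

    def central_slices(self, n: int = 7) -> np.ndarray:
        """Return the ``n`` slices centered on the focal plane."""
        half = n // 2
        lo = self.focus_index - half
        hi = lo + n
        if lo < 0 or hi > self.data.shape[0]:
            raise ValueError(f"stack has too few slices for a {n}-slice window")
        return self.data[lo:hi]


@dataclass
class GroundTruthManifest:
    """Everything the generator knows, for parameter-recovery tests."""

    sites: list[StructureSpec]
    molecule_positions: list[np.ndarray]  # per site, (n_molecules, 2) nm
    drift_trajectory: np.ndarray | None = None  # (n_frames, 2) nm
    gfp_true_amplitudes: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.molecule_positions):
            raise ValueError("one molecule-position array per site required")
        for spec, pos in zip(self.sites, self.molecule_positions):
            if len(pos) != spec.n_molecules:
                raise ValueError("molecule_positions counts must match n_molecules")

    def to_json(self, path) -> None:
        payload = {
            "sites": [
                {
                    "shape": s.shape,
                    "center": list(s.center),
                    "r_out": s.r_out,
                    "dr": s.dr,
                    "n_molecules": s.n_molecules,
                    "dome_height": s.dome_height,
                }
                for s in self.sites
            ],
            "molecule_positions": [p.tolist() for p in self.molecule_positions],
            "drift_trajectory": (
                None if self.drift_trajectory is None else self.drift_trajectory.tolist()
            ),
            "gfp_true_amplitudes": list(self.gfp_true_amplitudes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        sites = [StructureSpec(center=tuple(d.pop("center")), **d) for d in payload["sites"]]
        drift = payload["drift_trajectory"]
        return cls(
            sites=sites,
            molecule_positions=[np.asarray(p, float) for p in payload["molecule_positions"]],
            drift_trajectory=None if drift is None else np.asarray(drift, float),
            gfp_true_amplitudes=payload["gfp_true_amplitudes"],
        )


# --------------------------------------------------------------------------
# sampling


def annulus_density(r: np.ndarray, r_out: float, dr: float, sigma: float) -> np.ndarray:
    """Radial density profile of the blurred annulus model (unnormalized).

    With ``sigma -> 0`` this is the indicator of ``max(0, r_out-dr) <= r <= r_out``.
    """
    r = np.asarray(r, float)
    if sigma <= 0:
        inner = max(0.0, r_out - dr)
        return ((r >= inner) & (r <= r_out)).astype(float)
    s = np.sqrt(2.0) * sigma
    return 0.5 * (special.erf((r_out - r) / s) - special.erf((r_out - dr - r) / s))


def sample_structure(spec: StructureSpec, seed: int) -> np.ndarray:
    """Draw ``spec.n_molecules`` true molecule positions (nm), shape (n, 2).

    Rings and patches are uniform on the annulus ``[max(0, r_out - dr), r_out]``
    (the zero-blur limit of the fitted density); domes are uniform on a
    hemisphere of radius ``r_out`` orthographically projected to the plane.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_molecules
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    if spec.shape in ("ring", "patch"):
        r_in = max(0.0, spec.r_out - spec.dr)
        # uniform over annulus area: r = sqrt(U*(R^2 - r^2) + r^2)
        u = rng.uniform(0.0, 1.0, n)
        r = np.sqrt(u * (spec.r_out**2 - r_in**2) + r_in**2)
    else:  # dome: uniform on the hemisphere surface, z >= 0
        cos_polar = rng.uniform(0.0, 1.0, n)
        sin_polar = np.sqrt(1.0 - cos_polar**2)
        r = spec.r_out * sin_polar
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return xy + np.asarray(spec.center, float)


def _truncated_precisions(rng, n: int, model: EmissionModel) -> np.ndarray:
    vals = rng.normal(model.precision_mean, model.precision_sd, n)
    return np.maximum(vals, model.precision_floor)


def linear_drift(n_frames: int, total_nm: tuple[float, float]) -> np.ndarray:
    """Linear drift trajectory from (0, 0) to ``total_nm`` over the movie."""
    t = np.linspace(0.0, 1.0, n_frames)
    return np.column_stack([t * total_nm[0], t * total_nm[1]])


def smooth_drift(n_frames: int, scale_nm: float, seed: int, n_knots: int = 6) -> np.ndarray:
    """Smooth random drift: cubic interpolation through random knots."""
    from scipy.interpolate import CubicSpline

    rng = np.random.default_rng(seed)
    knots_t = np.linspace(0, n_frames - 1, max(n_knots, 2))
    knots = rng.normal(0.0, scale_nm, (len(knots_t), 2))
    knots -= knots[0]
    spline = CubicSpline(knots_t, knots)
    return spline(np.arange(n_frames))


def emit_localizations(
    manifest: GroundTruthManifest,
    model: EmissionModel,
    n_frames: int,
    seed: int,
    fov_nm: tuple[float, float] = (10_000.0, 10_000.0),
) -> pd.DataFrame:
    """Turn true molecules into a blink-level localization table.

    Each molecule emits a geometric number of blinks (mean ``mean_blinks``)
    in a run starting at a uniformly random frame; a 1-frame dark gap is
    inserted between successive blinks with probability ``blink_gap_prob``
    (runs are clipped at the movie end).  Each blink is displaced by an
    isotropic Gaussian with per-blink precision drawn from a truncated
    Gaussian (floor :attr:`EmissionModel.precision_floor`); drift, when
    present in the manifest, is added per frame.  Uniform background
    localizations over ``fov_nm`` are appended at ``background_rate``
    events/µm².  Record count is exactly (sum of blinks) + background count.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    drift = manifest.drift_trajectory
    if drift is not None and len(drift) != n_frames:
        raise ValueError("drift_trajectory length must equal n_frames")

    frames_all, xs, ys, precisions = [], [], [], []
    for positions in manifest.molecule_positions:
        for pos in positions:
            n_blinks = rng.geometric(min(1.0, 1.0 / model.mean_blinks))
            start = rng.integers(0, n_frames)
            gaps = rng.random(n_blinks) < model.blink_gap_prob
            steps = 1 + gaps.astype(int)
            steps[0] = 0
            blink_frames = start + np.cumsum(steps)
            blink_frames = blink_frames[blink_frames < n_frames]
            if blink_frames.size == 0:  # clipped entirely: keep the first blink
                blink_frames = np.array([min(start, n_frames - 1)])
            k = blink_frames.size
            prec = _truncated_precisions(rng, k, model)
            xy = pos[None, :] + rng.normal(0.0, 1.0, (k, 2)) * prec[:, None]
            frames_all.append(blink_frames)
            xs.append(xy[:, 0])
            ys.append(xy[:, 1])
            precisions.append(prec)

    area_um2 = (fov_nm[0] / 1000.0) * (fov_nm[1] / 1000.0)
    n_bg = rng.poisson(model.background_rate * area_um2)
    if n_bg > 0:
        frames_all.append(rng.integers(0, n_frames, n_bg))
        xs.append(rng.uniform(0.0, fov_nm[0], n_bg))
        ys.append(rng.uniform(0.0, fov_nm[1], n_bg))
        precisions.append(_truncated_precisions(rng, n_bg, model))

    if not frames_all:
        return tables.empty_table()
    frame = np.concatenate(frames_all).astype(int)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    prec = np.concatenate(precisions)
    if drift is not None:
        x = x + drift[frame, 0]
        y = y + drift[frame, 1]
    photons = rng.poisson(model.photons_mean, frame.size).astype(float)
    table = tables.make_table(
        frame=frame,
        x_nm=x,
        y_nm=y,
        photons=photons,
        bg=np.zeros(frame.size),
        sigma_nm=np.full(frame.size, model.psf_sigma),
        precision_nm=prec,
        channel=np.zeros(frame.size, int),
    )
    return table.sort_values(["frame"], kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# rendering raw frames and GFP stacks


def _integrated_1d(edges_px: np.ndarray, mu_px: float, sigma_px: float) -> np.ndarray:
    """Integral of a unit Gaussian over each pixel, from edge array (n+1,)."""
    s = np.sqrt(2.0) * sigma_px
    cdf = 0.5 * (1.0 + special.erf((edges_px - mu_px) / s))
    return np.diff(cdf)


def render_frames(
    table: pd.DataFrame,
    camera: CameraModel,
    seed: int = 0,
    noiseless: bool = False,
) -> np.ndarray:
    """Render a localization table into a raw camera stack (counts).

    Each record contributes a pixel-integrated 2D Gaussian of width
    ``sigma_nm`` scaled to its photon count; a constant photon background is
    added and Poisson noise applied per pixel (unless ``noiseless``), then
    the camera baseline is added.
    """
    tables.validate_table(table)
    fov_x, fov_y = camera.fov_nm
    if len(table) and (
        (table["x_nm"] < 0).any()
        or (table["y_nm"] < 0).any()
        or (table["x_nm"] >= fov_x).any()
        or (table["y_nm"] >= fov_y).any()
    ):
        raise ValueError("all localizations must lie inside the frame bounds")
    n_frames = int(table["frame"].max()) + 1 if len(table) else 1
    p = camera.pixel_size_nm
    edges = np.arange(camera.width_px + 1, dtype=float)
    edges_y = np.arange(camera.height_px + 1, dtype=float)
    stack = np.full((n_frames, camera.height_px, camera.width_px), camera.background, float)
    for frame, x, y, photons, sigma in table[
        ["frame", "x_nm", "y_nm", "photons", "sigma_nm"]
    ].itertuples(index=False):
        gx = _integrated_1d(edges, x / p, sigma / p)
        gy = _integrated_1d(edges_y, y / p, sigma / p)
        stack[int(frame)] += photons * np.outer(gy, gx)
    if not noiseless:
        rng = np.random.default_rng(seed)
        stack = rng.poisson(stack).astype(float)
    return stack + camera.baseline


def gen_gfp_stack(
    sites: list[tuple[tuple[float, float], float]],
    layout: GfpLayout,
    seed: int = 0,
) -> GfpStack:
    """Render GFP spots into a diffraction-limited z-stack.

    Each ``((x_nm, y_nm), amplitude)`` site renders as an isotropic 2D
    Gaussian whose peak amplitude is maximal at the focal slice and decays
    as a Gaussian of scale ``z_sigma_nm`` with defocus.  Overlapping
    neighbors sum linearly.
    """
    ny, nx = layout.height_px, layout.width_px
    p = layout.pixel_size_nm
    xc = (np.arange(nx) + 0.5) * p
    yc = (np.arange(ny) + 0.5) * p
    xx, yy = np.meshgrid(xc, yc)
    z_offsets = (np.arange(layout.n_slices) - layout.focus_index) * layout.z_step_nm
    stack = np.full((layout.n_slices, ny, nx), layout.background, float)
    for (x0, y0), amp in sites:
        spot = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * layout.psf_sigma_nm**2))
        axial = amp * np.exp(-(z_offsets**2) / (2.0 * layout.z_sigma_nm**2))
        stack += axial[:, None, None] * spot[None, :, :]
    if layout.poisson_noise:
        rng = np.random.default_rng(seed)
        stack = rng.poisson(stack).astype(float)
    return GfpStack(
        data=stack,
        pixel_size_nm=p,
        z_step_nm=layout.z_step_nm,
        focus_index=layout.focus_index,
    )
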