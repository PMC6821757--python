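"""Synthetic microscopy and table generators with recorded ground truth.

Every generator emulates one class of input used by the downstream
quantification stages and returns, alongside the artifact, a truth object
holding the exact parameters and placements it used.  Downstream recovery
tests consume the truth only in assertions, never in computation.

Conventions: photon counts as intensity units (camera gain 1), pixel pitch
0.1 um by default, isotropic 2-D Gaussian point-spread function, Poisson
photon noise, z-stacks of 10 sections spaced 1 um starting at the basal
side, movie frames every 50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erf

from .containers import (
    ImagePlane,
    LineProfile,
    MultiChannelImage,
    TimeSeries,
    Trajectory,
    ZStack,
)

__all__ = [
    "CellImageTruth",
    "ZStackTruth",
    "MotionTruth",
    "ExpressionTruth",
    "make_cell_image",
    "make_ratio_cell",
    "make_line_profile",
    "make_zstack",
    "simulate_brownian_paths",
    "make_brownian_movie",
    "make_expression_table",
    "make_phenotype_counts",
]

DEFAULT_PIXEL_SIZE_UM = 0.1
DEFAULT_PSF_SIGMA_UM = 0.2
N_SECTIONS = 10


# ---------------------------------------------------------------------------
# truth records


@dataclass
class CellImageTruth:
    """Ground truth for a two-channel cell image (membrane ring + clusters)."""

    membrane_mask: np.ndarray
    cluster_positions: list[tuple[float, float]]
    cluster_on_membrane: list[bool]
    membrane_fraction: float
    background_level: float
    channel_gains: dict[str, float]


@dataclass
class ZStackTruth:
    z_weights: np.ndarray
    spot_records: list[tuple[float, float, int, float]]  # (x_um, y_um, z_plane, photons)


@dataclass
class MotionTruth:
    """Ground truth for a two-channel Brownian movie.

    ``trajectories`` holds, per channel, the positions actually rendered into
    the frames (shared underlying path plus per-channel localization jitter
    for comigrating pairs); ``paths`` holds the jitter-free underlying paths.
    """

    trajectories: dict[str, list[Trajectory]]
    paths: dict[str, np.ndarray]  # (n_particles, n_frames, 2)
    diffusion_coefficient: float
    frame_interval_s: float
    comigrating_pairs: list[tuple[int, int]]
    photon_rate: float
    localization_sigma_um: float
    fov_um: float


@dataclass
class ExpressionTruth:
    gene_ids: list[str]
    true_fold_changes: np.ndarray  # linear scale, condition/control
    regulated_flags: np.ndarray
    replicate_noise_sd: float


# ---------------------------------------------------------------------------
# low-level raster helpers


def _splat_gaussian(img: np.ndarray, x_px: float, y_px: float, photons: float,
                    sigma_px: float) -> None:
    """Add an integrated 2-D Gaussian spot to ``img`` in place.

    Pixel values receive the exact integral of the Gaussian over the pixel
    area (via the error function), so the spot's summed intensity equals
    ``photons`` up to the 5-sigma window truncation (<1e-5 relative).
    """
    half = int(np.ceil(5 * sigma_px)) + 1
    r0 = max(int(np.floor(y_px)) - half, 0)
    r1 = min(int(np.floor(y_px)) + half + 1, img.shape[0])
    c0 = max(int(np.floor(x_px)) - half, 0)
    c1 = min(int(np.floor(x_px)) + half + 1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    s = sigma_px * np.sqrt(2.0)
    cols = np.arange(c0, c1 + 1, dtype=float)
    rows = np.arange(r0, r1 + 1, dtype=float)
    fx = 0.5 * erf((cols - x_px) / s)
    fy = 0.5 * erf((rows - y_px) / s)
    img[r0:r1, c0:c1] += photons * np.outer(np.diff(fy), np.diff(fx))


def _boundary_radius(theta: np.ndarray, r0_um: float, perturb: np.ndarray) -> np.ndarray:
    """Radius of an ellipse-perturbed polygon-like cell outline at angle theta."""
    a2, p2, a3, p3, ecc = perturb
    return r0_um * (1.0 + ecc * np.cos(2 * theta)
                    + a2 * np.cos(2 * theta + p2)
                    + a3 * np.cos(3 * theta + p3))


def _cell_geometry(shape: tuple[int, int], pixel_size_um: float,
                   rng: np.random.Generator):
    """Random closed cell outline fitting the field of view.

    Returns (center_um, r0_um, perturbation params, rho map, theta map,
    boundary radius map) where the maps are per-pixel values at pixel
    centres.
    """
    h, w = shape
    cx = 0.5 * w * pixel_size_um
    cy = 0.5 * h * pixel_size_um
    r0 = 0.33 * min(w, h) * pixel_size_um
    perturb = np.array([
        rng.uniform(0.03, 0.08),
        rng.uniform(0, 2 * np.pi),
        rng.uniform(0.02, 0.05),
        rng.uniform(0, 2 * np.pi),
        rng.uniform(0.0, 0.06),
    ])
    ys = (np.arange(h) + 0.5) * pixel_size_um - cy
    xs = (np.arange(w) + 0.5) * pixel_size_um - cx
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    rho = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    rb = _boundary_radius(theta, r0, perturb)
    return (cx, cy), r0, perturb, rho, theta, rb


# ---------------------------------------------------------------------------
# cell images (membrane ring + punctate clusters)


def make_cell_image(
    width_px: int = 256,
    height_px: int = 256,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    n_clusters: int = 50,
    membrane_fraction: float = 0.8,
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    background: float = 10.0,
    seed: int | None = 0,
    *,
    cluster_photons: float = 5000.0,
    membrane_peak: float = 200.0,
    band_half_width_um: float | None = None,
    poisson_noise: bool = True,
) -> tuple[MultiChannelImage, CellImageTruth]:
    """Two-channel image of one cell: membrane-marker ring plus clusters.

    Channel ``"membrane"`` carries a closed ring (the cell outline convolved
    with the PSF); channel ``"clusters"`` carries ``n_clusters`` Gaussian
    spots of ``cluster_photons`` integrated photons each, with exactly
    ``round(n_clusters * membrane_fraction)`` of them centred on the
    membrane band and the rest placed in the cytoplasm.  The default 80%
    membrane fraction matches the regime where most receptor clusters sit at
    the plasma membrane.
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError("image dimensions must be positive")
    if not 0.0 <= membrane_fraction <= 1.0:
        raise ValueError("membrane_fraction must lie in [0, 1]")
    if psf_sigma_um <= 0:
        raise ValueError("psf_sigma_um must be positive")
    if n_clusters < 0:
        raise ValueError("n_clusters must be non-negative")

    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    (cx, cy), r0, perturb, rho, theta, rb = _cell_geometry(shape, pixel_size_um, rng)

    if band_half_width_um is None:
        band_half_width_um = psf_sigma_um
    d = rho - rb
    membrane_img = background + membrane_peak * np.exp(-d**2 / (2 * psf_sigma_um**2))
    membrane_mask = np.abs(d) <= band_half_width_um

    n_mem = int(round(n_clusters * membrane_fraction))
    n_cyt = n_clusters - n_mem
    positions: list[tuple[float, float]] = []
    on_membrane: list[bool] = []

    # membrane clusters: evenly spread angles with jitter, on the ridge
    if n_mem > 0:
        base = rng.uniform(0, 2 * np.pi)
        angles = base + 2 * np.pi * (np.arange(n_mem) + rng.uniform(-0.2, 0.2, n_mem)) / n_mem
        radii = _boundary_radius(angles, r0, perturb)
        for ang, r in zip(angles, radii):
            positions.append((cx + r * np.cos(ang), cy + r * np.sin(ang)))
            on_membrane.append(True)
    # cytoplasmic clusters: rejection-sampled inside, clear of the band
    placed = 0
    attempts = 0
    min_sep = 4 * psf_sigma_um
    while placed < n_cyt and attempts < 10000 * max(n_cyt, 1):
        attempts += 1
        ang = rng.uniform(0, 2 * np.pi)
        rr = np.sqrt(rng.uniform(0, 1)) * 0.7 * _boundary_radius(np.array([ang]), r0, perturb)[0]
        x, y = cx + rr * np.cos(ang), cy + rr * np.sin(ang)
        if any((x - px) ** 2 + (y - py) ** 2 < min_sep**2
               for px, py in positions[n_mem:]):
            continue
        positions.append((x, y))
        on_membrane.append(False)
        placed += 1
    if placed < n_cyt:
        raise RuntimeError("could not place cytoplasmic clusters; reduce n_clusters")

    cluster_img = np.full(shape, background, dtype=float)
    sigma_px = psf_sigma_um / pixel_size_um
    for x, y in positions:
        _splat_gaussian(cluster_img, x / pixel_size_um, y / pixel_size_um,
                        cluster_photons, sigma_px)

    if poisson_noise:
        membrane_img = rng.poisson(membrane_img).astype(float)
        cluster_img = rng.poisson(cluster_img).astype(float)

    image = MultiChannelImage(
        {"membrane": membrane_img, "clusters": cluster_img}, pixel_size_um
    )
    truth = CellImageTruth(
        membrane_mask=membrane_mask,
        cluster_positions=positions,
        cluster_on_membrane=on_membrane,
        membrane_fraction=(n_mem / n_clusters) if n_clusters else 0.0,
        background_level=background,
        channel_gains={"membrane": 1.0, "clusters": 1.0},
    )
    return image, truth


def make_ratio_cell(
    ratio: float,
    width_px: int = 200,
    height_px: int = 200,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    i_inside: float = 100.0,
    i_outside: float = 50.0,
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    poisson_noise: bool = True,
    seed: int | None = 0,
) -> tuple[ImagePlane, dict]:
    """Single-channel cell image with a configured membrane/cytoplasm ratio.

    A circular cell of intensity ``i_inside`` on a background ``i_outside``
    with a membrane ridge whose peak intensity is
    ``i_outside + ratio * (i_inside - i_outside)``, so a radial line profile
    analysed with the membrane/cytoplasm formula recovers ``ratio``.
    Returns the image and a truth dict (center_um, radius_um, ratio).
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = height_px, width_px
    cx = 0.5 * w * pixel_size_um
    cy = 0.5 * h * pixel_size_um
    radius = 0.3 * min(w, h) * pixel_size_um
    ys = (np.arange(h) + 0.5) * pixel_size_um - cy
    xs = (np.arange(w) + 0.5) * pixel_size_um - cx
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    rho = np.hypot(xx, yy)
    # smooth step (PSF-width transition) from outside to inside level
    def intensity(r, amp):
        edge = 0.5 * (1 - erf((r - radius) / (psf_sigma_um * np.sqrt(2))))
        ridge = np.exp(-((r - radius) ** 2) / (2 * psf_sigma_um**2))
        return i_outside + (i_inside - i_outside) * edge + amp * ridge

    # ridge amplitude solved so the radial maximum equals the target peak
    # (the step and the ridge overlap, so the max sits off-centre for small
    # amplitudes and a closed-form amplitude would overshoot)
    peak_target = i_outside + ratio * (i_inside - i_outside)
    r_grid = np.linspace(radius - 1.5, radius + 1.5, 601)
    lo, hi = 0.0, peak_target - i_outside
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if intensity(r_grid, mid).max() > peak_target:
            hi = mid
        else:
            lo = mid
    img = np.clip(intensity(rho, 0.5 * (lo + hi)), 0, None)
    if poisson_noise:
        img = rng.poisson(img).astype(float)
    truth = {"center_um": (cx, cy), "radius_um": radius, "ratio": float(ratio),
             "i_inside": i_inside, "i_outside": i_outside}
    return ImagePlane(img, pixel_size_um), truth


def make_line_profile(
    ratio: float,
    n_samples: int = 41,
    length_um: float = 4.0,
    i_inside: float = 100.0,
    i_outside: float = 50.0,
    peak_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    noise_sd: float = 0.0,
    zone_fractions: tuple[float, float, float] = (0.25, 0.5, 0.25),
    seed: int | None = None,
) -> tuple[LineProfile, float]:
    """Synthetic outside-to-inside boundary-crossing intensity profile.

    The outer zone is flat at ``i_outside``, the inner zone flat at
    ``i_inside``, and the middle zone ramps between them with a Gaussian
    membrane peak whose maximum sample equals exactly
    ``i_outside + ratio * (i_inside - i_outside)``; with ``noise_sd = 0``
    the membrane/cytoplasm formula therefore recovers ``ratio`` to floating
    point precision.  Returns (profile, configured ratio).
    """
    from .profiles import _zone_slices  # shared zone convention

    if n_samples < 9:
        raise ValueError("need at least 9 samples")
    if ratio < 1.0:
        raise ValueError("membrane-peak profile requires ratio >= 1")
    positions = np.linspace(0.0, length_um, n_samples)
    out_sl, mid_sl, in_sl = _zone_slices(n_samples, zone_fractions)
    vals = np.empty(n_samples)
    vals[out_sl] = i_outside
    vals[in_sl] = i_inside
    mid_idx = np.arange(mid_sl.start, mid_sl.stop)
    ramp = np.linspace(i_outside, i_inside, mid_idx.size)
    center = mid_idx[mid_idx.size // 2]
    pc = positions[center]
    peak_target = i_outside + ratio * (i_inside - i_outside)
    bump = np.exp(-((positions[mid_idx] - pc) ** 2) / (2 * peak_sigma_um**2))
    # renormalize so the bump vanishes at the zone edges and is 1 at centre;
    # the centre sample then equals peak_target exactly and is the zone max
    edge = max(bump[0], bump[-1])
    bump = np.clip((bump - edge) / (1.0 - edge), 0.0, None)
    amp = peak_target - ramp[mid_idx.size // 2]
    vals[mid_sl] = ramp + amp * bump
    vals[center] = peak_target
    if np.max(vals[mid_sl]) > peak_target + 1e-9:
        raise ValueError("peak_sigma_um too broad for the requested ratio")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0, noise_sd, n_samples)
    return LineProfile(positions, vals, outside_to_inside=True), float(ratio)


# ---------------------------------------------------------------------------
# z-stacks


def make_zstack(
    n_spots: int,
    z_weights: Sequence[float],
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    z_spread_sections: float = 0.0,
    background: float = 10.0,
    seed: int | None = 0,
    *,
    width_px: int = 280,
    height_px: int = 280,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    z_spacing_um: float = 1.0,
    spot_photons: float = 5000.0,
    channel: str = "spots",
    poisson_noise: bool = True,
) -> tuple[ZStack, ZStackTruth]:
    """Polarized-cell z-stack with spots drawn from a basal-to-apical weight
    vector.

    Home sections realize ``z_weights`` (index 0 = basal) with exact
    per-plane counts (largest-remainder apportionment, randomly permuted
    over spots), so the recorded truth distribution is controlled up to
    rounding rather than subject to multinomial noise.  With
    ``z_spread_sections > 0`` a spot's intensity bleeds into neighbouring
    sections with Gaussian attenuation
    ``exp(-(k - home)^2 / (2 z_spread^2))``.  Spots are laid out on a
    jittered grid so they stay well separated in xy.
    """
    z_weights = np.asarray(z_weights, dtype=float)
    if np.any(z_weights < 0):
        raise ValueError("z_weights must be non-negative")
    if abs(z_weights.sum() - 1.0) > 1e-9:
        raise ValueError("z_weights must sum to 1 within 1e-9")
    if n_spots < 0:
        raise ValueError("n_spots must be non-negative")
    if z_spread_sections < 0:
        raise ValueError("z_spread_sections must be non-negative")

    rng = np.random.default_rng(seed)
    n_planes = z_weights.size
    shape = (height_px, width_px)
    sigma_px = psf_sigma_um / pixel_size_um

    # jittered-grid xy placement: separation >= pitch - 2*jitter, kept
    # wide enough that no neighbour's PSF mass leaks into another spot's
    # 4-sigma analysis window
    margin = int(np.ceil(6 * sigma_px)) + 2
    pitch = max(int(np.ceil(10 * sigma_px)), 8)
    gx = np.arange(margin, width_px - margin, pitch)
    gy = np.arange(margin, height_px - margin, pitch)
    cells = [(x, y) for y in gy for x in gx]
    if n_spots > len(cells):
        raise ValueError(
            f"cannot place {n_spots} separated spots in a "
            f"{width_px}x{height_px} field (max {len(cells)})"
        )
    order = rng.permutation(len(cells))[:n_spots]
    jitter = 0.15 * pitch

    # exact-count apportionment of spots to planes (largest remainder)
    ideal = z_weights * n_spots
    counts = np.floor(ideal).astype(int)
    remainder = n_spots - counts.sum()
    if remainder > 0:
        top = np.argsort(-(ideal - counts), kind="stable")[:remainder]
        counts[top] += 1
    homes = rng.permutation(np.repeat(np.arange(n_planes), counts))
    stack = np.full((n_planes, *shape), float(background))
    records: list[tuple[float, float, int, float]] = []
    for idx, home in zip(order, homes):
        x_px = cells[idx][0] + rng.uniform(-jitter, jitter)
        y_px = cells[idx][1] + rng.uniform(-jitter, jitter)
        x_um, y_um = x_px * pixel_size_um, y_px * pixel_size_um
        records.append((x_um, y_um, int(home), spot_photons))
        for k in range(n_planes):
            if z_spread_sections == 0:
                if k != home:
                    continue
                atten = 1.0
            else:
                atten = np.exp(-((k - home) ** 2) / (2 * z_spread_sections**2))
                if atten < 1e-4:
                    continue
            _splat_gaussian(stack[k], x_px, y_px, spot_photons * atten, sigma_px)

    if poisson_noise:
        stack = rng.poisson(stack).astype(float)
    zstack = ZStack({channel: stack}, pixel_size_um, z_spacing_um)
    return zstack, ZStackTruth(z_weights=z_weights, spot_records=records)


# ---------------------------------------------------------------------------
# Brownian movies


def simulate_brownian_paths(
    n_particles: int,
    n_frames: int,
    D_um2_s: float,
    frame_interval_s: float = 0.05,
    n_comigrating_pairs: int = 0,
    fov_um: float = 20.0,
    localization_sigma_um: float = 0.02,
    photon_rate: float = 5000.0,
    seed: int | None = 0,
    channel_names: tuple[str, str] = ("green", "red"),
) -> MotionTruth:
    """Two channels of reflected 2-D Brownian paths with comigrating pairs.

    Per-axis steps are i.i.d. N(0, 2*D*dt); paths reflect at the field
    edges.  The first ``n_comigrating_pairs`` particles of the second
    channel share the underlying path of the same-index particle in the
    first channel; every observed trajectory adds independent Gaussian
    localization jitter.
    """
    if D_um2_s < 0 or photon_rate < 0 or n_particles < 0 or n_frames < 1:
        raise ValueError("negative rates or counts")
    if n_comigrating_pairs > n_particles:
        raise ValueError("n_comigrating_pairs cannot exceed n_particles")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(2.0 * D_um2_s * frame_interval_s)

    def _paths() -> np.ndarray:
        start = rng.uniform(0.05 * fov_um, 0.95 * fov_um, size=(n_particles, 1, 2))
        steps = rng.normal(0.0, step_sd, size=(n_particles, n_frames - 1, 2))
        raw = np.concatenate([start, start + np.cumsum(steps, axis=1)], axis=1)
        # reflecting boundaries via the folded coordinate
        period = 2.0 * fov_um
        folded = np.mod(raw, period)
        return np.where(folded > fov_um, period - folded, folded)

    paths_a = _paths()
    paths_b = _paths()
    pairs = [(i, i) for i in range(n_comigrating_pairs)]
    for i, j in pairs:
        paths_b[j] = paths_a[i]

    ch_a, ch_b = channel_names
    trajectories: dict[str, list[Trajectory]] = {ch_a: [], ch_b: []}
    paths = {ch_a: paths_a, ch_b: paths_b}
    frames = np.arange(n_frames)
    for ch in channel_names:
        for i in range(n_particles):
            obs = paths[ch][i] + rng.normal(0, localization_sigma_um, (n_frames, 2))
            trajectories[ch].append(
                Trajectory(
                    id=i, channel=ch, frames=frames,
                    x_um=obs[:, 0], y_um=obs[:, 1],
                    photons=np.full(n_frames, photon_rate),
                )
            )
    return MotionTruth(
        trajectories=trajectories,
        paths=paths,
        diffusion_coefficient=D_um2_s,
        frame_interval_s=frame_interval_s,
        comigrating_pairs=pairs,
        photon_rate=photon_rate,
        localization_sigma_um=localization_sigma_um,
        fov_um=fov_um,
    )


def make_brownian_movie(
    n_particles: int = 10,
    n_frames: int = 200,
    D_um2_s: float = 0.05,
    frame_interval_s: float = 0.05,
    photon_rate: float = 5000.0,
    n_comigrating_pairs: int = 0,
    fov_um: float = 20.0,
    seed: int | None = 0,
    *,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM,
    background: float = 10.0,
    localization_sigma_um: float = 0.02,
    channel_names: tuple[str, str] = ("green", "red"),
    poisson_noise: bool = True,
) -> tuple[TimeSeries, MotionTruth]:
    """Render a two-channel time-lapse movie of Brownian particles.

    Each frame splats every particle at its observed (jittered) position
    with ``photon_rate`` expected photons, adds the background, and draws
    per-pixel Poisson counts, so both the per-spot photon number and the
    per-pixel background statistics are Poisson.
    """
    truth = simulate_brownian_paths(
        n_particles, n_frames, D_um2_s, frame_interval_s, n_comigrating_pairs,
        fov_um, localization_sigma_um, photon_rate, seed, channel_names,
    )
    rng = np.random.default_rng(None if seed is None else seed + 1)
    n_px = int(round(fov_um / pixel_size_um))
    sigma_px = psf_sigma_um / pixel_size_um
    channels = {}
    for ch in channel_names:
        frames = np.full((n_frames, n_px, n_px), float(background))
        for traj in truth.trajectories[ch]:
            for t in range(n_frames):
                _splat_gaussian(frames[t], traj.x_um[t] / pixel_size_um,
                                traj.y_um[t] / pixel_size_um,
                                truth.photon_rate, sigma_px)
        if poisson_noise:
            frames = rng.poisson(frames).astype(float)
        channels[ch] = frames
    movie = TimeSeries(channels, pixel_size_um, frame_interval_s)
    return movie, truth


# ---------------------------------------------------------------------------
# expression and phenotype tables


def make_expression_table(
    n_genes: int = 2000,
    n_regulated: int = 100,
    fold_change: float = 4.0,
    n_replicates: int = 4,
    noise_sd: float = 0.1,
    seed: int | None = 0,
    condition_names: tuple[str, str] = ("control", "morphant"),
) -> tuple["pandas.DataFrame", ExpressionTruth]:
    """Two-condition replicate expression matrix with known regulated genes.

    Expression values are log-normal: per-gene baseline log2 level plus
    i.i.d. Gaussian replicate noise (``noise_sd`` in log2 units).  Regulated
    genes carry a shift of +/- log2(fold_change) in the second condition,
    alternating up- and down-regulation.
    """
    import pandas as pd

    if n_regulated > n_genes:
        raise ValueError("n_regulated cannot exceed n_genes")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    base = rng.normal(8.0, 2.0, n_genes)
    flags = np.zeros(n_genes, dtype=bool)
    reg_idx = rng.choice(n_genes, size=n_regulated, replace=False)
    flags[reg_idx] = True
    log2fc = np.zeros(n_genes)
    signs = np.where(np.arange(n_regulated) % 2 == 0, 1.0, -1.0)
    log2fc[reg_idx] = signs * np.log2(fold_change)

    cond_a, cond_b = condition_names
    data = {"gene_id": gene_ids}
    for r in range(n_replicates):
        noise = rng.normal(0, noise_sd, n_genes) if noise_sd > 0 else 0.0
        data[f"{cond_a}_{r + 1}"] = 2.0 ** (base + noise)
    for r in range(n_replicates):
        noise = rng.normal(0, noise_sd, n_genes) if noise_sd > 0 else 0.0
        data[f"{cond_b}_{r + 1}"] = 2.0 ** (base + log2fc + noise)
    table = pd.DataFrame(data)
    truth = ExpressionTruth(
        gene_ids=gene_ids,
        true_fold_changes=2.0**log2fc,
        regulated_flags=flags,
        replicate_noise_sd=noise_sd,
    )
    return table, truth


PHENOTYPE_CATEGORIES = ("wild_type", "mild", "severe")


def make_phenotype_counts(
    n_embryos: int,
    probs: Sequence[float],
    seed: int | None = 0,
    condition: str = "control",
) -> "pandas.DataFrame":
    """Multinomial embryo phenotype counts over (wild_type, mild, severe).

    Returns a one-row DataFrame indexed by condition; rows from repeated
    calls can be concatenated into a full contingency table.
    """
    import pandas as pd

    probs = np.asarray(probs, dtype=float)
    if probs.size != len(PHENOTYPE_CATEGORIES):
        raise ValueError("probs must have one entry per phenotype category")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be non-negative and sum to 1")
    if n_embryos < 0:
        raise ValueError("n_embryos must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_embryos, probs)
    return pd.DataFrame(
        [counts], index=pd.Index([condition], name="condition"),
        columns=list(PHENOTYPE_CATEGORIES),
    )
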