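"""Detection and sub-pixel localization of diffraction-limited spots.

Candidate maxima come from a band-pass (difference-of-Gaussians) filter,
positions are refined by an intensity-weighted centroid in a window of
radius 4 sigma, and the integrated, background-subtracted photon count of
each candidate is compared against a photon gate: only spots with more
than ``min_photons`` photons are kept (default gate 1000 photons per
frame).  Maxima closer than 2 sigma are merged, keeping the brighter one.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import ImagePlane, Spot, ZStack

__all__ = [
    "detect_spots",
    "max_projection",
    "spot_visible_in_section",
    "DEFAULT_MIN_PHOTONS",
    "DEFAULT_VISIBILITY_FACTOR",
]

DEFAULT_MIN_PHOTONS = 1000.0
DEFAULT_VISIBILITY_FACTOR = 5.0
_MAD_TO_SIGMA = 1.4826


def _background_stats(data: np.ndarray) -> tuple[float, float]:
    """Robust background level and noise scale (median and MAD-sigma)."""
    med = float(np.median(data))
    mad = float(np.median(np.abs(data - med)))
    return med, _MAD_TO_SIGMA * mad


def _integrate_window(data: np.ndarray, row: float, col: float, radius_px: int,
                      background: float) -> tuple[float, float, float, int]:
    """Background-subtracted sum and centroid in a square window.

    Returns (photons, centroid_row, centroid_col, n_pixels).  The centroid
    weights are the positive part of the background-subtracted intensities.
    """
    r0 = max(int(round(row)) - radius_px, 0)
    r1 = min(int(round(row)) + radius_px + 1, data.shape[0])
    c0 = max(int(round(col)) - radius_px, 0)
    c1 = min(int(round(col)) + radius_px + 1, data.shape[1])
    win = data[r0:r1, c0:c1] - background
    photons = float(win.sum())
    w = np.clip(win, 0, None)
    total = w.sum()
    if total <= 0:
        return photons, row, col, win.size
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return (
        photons,
        float((rr * w).sum() / total),
        float((cc * w).sum() / total),
        win.size,
    )


def detect_spots(
    plane: ImagePlane,
    min_photons: float = DEFAULT_MIN_PHOTONS,
    sigma_um: float = 0.2,
    *,
    channel: str | None = None,
    z_plane: int | None = None,
    frame: int | None = None,
) -> list[Spot]:
    """Detect diffraction-limited spots in a single plane.

    Applies the photon gate strictly: a candidate whose integrated,
    background-subtracted photon count is less than or equal to
    ``min_photons`` is discarded.  Spots are returned sorted by descending
    photon count.
    """
    if min_photons < 0:
        raise ValueError("min_photons must be non-negative")
    if sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    px = plane.pixel_size_um
    sigma_px = sigma_um / px
    data = plane.data
    if sigma_px >= min(data.shape):
        raise ValueError("sigma_um exceeds the image size")

    bg, noise = _background_stats(data)
    # band-pass: difference of Gaussians at sigma and 2*sigma
    lo = ndimage.gaussian_filter(data, sigma_px)
    hi = ndimage.gaussian_filter(data, 2.0 * sigma_px)
    dog = lo - hi
    # candidate maxima must stand out of the filtered noise floor
    dog_noise = noise / np.sqrt(4 * np.pi * sigma_px**2)  # DoG suppresses white noise
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (dog == ndimage.maximum_filter(dog, footprint=footprint))
    local_max &= dog > 3.0 * max(dog_noise, 1e-12)
    rows, cols = np.nonzero(local_max)
    if rows.size == 0:
        return []

    # photon sum over the full 4-sigma window; centroid over a tighter
    # 2-sigma core so a neighbouring spot at ~4 sigma cannot drag it
    photon_radius_px = max(int(np.ceil(4.0 * sigma_px)), 2)
    centroid_radius_px = max(int(np.ceil(2.0 * sigma_px)), 1)
    candidates: list[tuple[float, float, float]] = []  # (photons, row, col)
    for r, c in zip(rows, cols):
        _, cr, cc, _ = _integrate_window(data, float(r), float(c),
                                         centroid_radius_px, bg)
        _, cr, cc, _ = _integrate_window(data, cr, cc, centroid_radius_px, bg)
        photons, _, _, _ = _integrate_window(data, cr, cc, photon_radius_px, bg)
        candidates.append((photons, cr, cc))

    # merge duplicates closer than 2 sigma, keeping the brighter
    candidates.sort(key=lambda t: -t[0])
    kept: list[tuple[float, float, float]] = []
    min_sep2 = (2.0 * sigma_px) ** 2
    for ph, cr, cc in candidates:
        if any((cr - kr) ** 2 + (cc - kc) ** 2 < min_sep2 for _, kr, kc in kept):
            continue
        kept.append((ph, cr, cc))

    spots = [
        Spot(
            x_um=(cc + 0.5) * px,
            y_um=(cr + 0.5) * px,
            photons=ph,
            channel=channel or plane.channel,
            z_plane=z_plane,
            frame=frame,
        )
        for ph, cr, cc in kept
        if ph > min_photons
    ]
    spots.sort(key=lambda s: -s.photons)
    return spots


def max_projection(stack: ZStack, channel: str) -> ImagePlane:
    """Per-pixel maximum-intensity projection over all z-sections."""
    data = stack[channel]
    if data.shape[0] == 0:
        raise ValueError("empty stack")
    return ImagePlane(data.max(axis=0), stack.pixel_size_um, channel)


def spot_visible_in_section(
    spot: Spot,
    plane: ImagePlane,
    visibility_factor: float = DEFAULT_VISIBILITY_FACTOR,
    sigma_um: float = 0.2,
) -> bool:
    """Decide whether a spot is visible in one optical section.

    The background-subtracted integrated intensity in the spot's window
    must exceed ``visibility_factor`` times the expected noise of that sum
    (MAD-based background sigma times sqrt of the window pixel count).
    """
    px = plane.pixel_size_um
    col = spot.x_um / px - 0.5
    row = spot.y_um / px - 0.5
    if not (0 <= row < plane.shape[0] and 0 <= col < plane.shape[1]):
        raise ValueError("spot position outside the plane")
    bg, noise = _background_stats(plane.data)
    radius_px = max(int(np.ceil(4.0 * sigma_um / px)), 2)
    photons, _, _, n_pix = _integrate_window(plane.data, row, col, radius_px, bg)
    return photons > visibility_factor * noise * np.sqrt(n_pix)
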