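"""Colocalization with a membrane marker: Manders M2 and cluster classes.

M2 is the fraction of the signal channel's total intensity that falls on
pixels where the marker channel is above threshold — here the marker is a
membrane label, so M2 reads as the relative membrane localization of the
signal.  Individual clusters are additionally classified as membrane or
cytoplasmic by testing their position against a membrane band mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.morphology import disk, skeletonize

from .containers import ImagePlane, Spot

__all__ = [
    "MandersResult",
    "ClusterLocalization",
    "manders_m2",
    "membrane_mask",
    "classify_clusters",
    "UndefinedCoefficientError",
]

DEFAULT_BAND_WIDTH_UM = 0.4


class UndefinedCoefficientError(ValueError):
    """Raised when a coefficient has no defined value (e.g. zero total signal)."""


@dataclass
class MandersResult:
    m2: float
    threshold_membrane: float
    n_pixels_membrane: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.m2 <= 1.0 + 1e-12:
            raise ValueError("M2 must lie in [0, 1]")
        self.m2 = float(min(self.m2, 1.0))


@dataclass
class ClusterLocalization:
    n_membrane: int
    n_cytoplasm: int

    @property
    def n_total(self) -> int:
        return self.n_membrane + self.n_cytoplasm

    @property
    def fraction_membrane(self) -> float:
        """Membrane fraction; NaN when no clusters were counted."""
        if self.n_total == 0:
            return float("nan")
        return self.n_membrane / self.n_total


def _resolve_threshold(marker: np.ndarray, rule) -> float:
    if rule == "otsu" or rule is None:
        return float(threshold_otsu(marker))
    if isinstance(rule, (int, float)):
        return float(rule)
    raise ValueError(f"unknown marker_threshold_rule {rule!r}")


def manders_m2(
    signal: ImagePlane,
    marker: ImagePlane,
    marker_threshold_rule="otsu",
) -> MandersResult:
    """Manders M2 of ``signal`` against the thresholded ``marker`` channel.

    ``marker_threshold_rule`` is either ``"otsu"`` (default) or a fixed
    numeric threshold.  Raises :class:`UndefinedCoefficientError` when the
    signal channel has zero total intensity.
    """
    if signal.shape != marker.shape:
        raise ValueError("signal and marker must share geometry")
    sig = signal.data
    if np.any(sig < 0) or np.any(marker.data < 0):
        raise ValueError("intensities must be non-negative")
    total = sig.sum()
    if total <= 0:
        raise UndefinedCoefficientError("total signal intensity is zero")
    thr = _resolve_threshold(marker.data, marker_threshold_rule)
    mask = marker.data > thr
    return MandersResult(
        m2=float(sig[mask].sum() / total),
        threshold_membrane=thr,
        n_pixels_membrane=int(mask.sum()),
    )


def membrane_mask(
    marker: ImagePlane,
    band_width_um: float = DEFAULT_BAND_WIDTH_UM,
    marker_threshold_rule="otsu",
) -> np.ndarray:
    """Boolean band of total width ``band_width_um`` along the marker ridge.

    The marker is thresholded, reduced to its ridge by skeletonization, and
    the skeleton dilated to the requested band width.
    """
    if band_width_um <= 0:
        raise ValueError("band_width_um must be positive")
    data = marker.data
    if not np.any(data > 0):
        raise ValueError("marker channel is all zero")
    thr = _resolve_threshold(data, marker_threshold_rule)
    binary = data > thr
    if not binary.any():
        raise ValueError("no marker pixels above threshold")
    radius_px = band_width_um / (2.0 * marker.pixel_size_um)
    if band_width_um >= min(marker.extent_um):
        return binary  # band saturates the thresholded region
    skeleton = skeletonize(binary)
    return binary_dilation(skeleton, structure=disk(max(int(round(radius_px)), 1)))


def classify_clusters(
    spots: list[Spot],
    mask: np.ndarray,
    pixel_size_um: float,
) -> ClusterLocalization:
    """Count clusters on vs off the membrane band.

    A spot is a membrane cluster iff the pixel containing its position is
    inside ``mask``.  An empty spot list yields zero counts and an
    undefined (NaN) membrane fraction.
    """
    n_mem = 0
    for s in spots:
        col = int(s.x_um / pixel_size_um)
        row = int(s.y_um / pixel_size_um)
        if not (0 <= row < mask.shape[0] and 0 <= col < mask.shape[1]):
            raise ValueError("spot outside mask geometry")
        if mask[row, col]:
            n_mem += 1
    return ClusterLocalization(n_membrane=n_mem, n_cytoplasm=len(spots) - n_mem)
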