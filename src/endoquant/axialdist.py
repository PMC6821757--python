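"""Basal-to-apical distribution of fluorescence spots across z-sections.

Spots are selected once on the maximum-intensity projection of a stack,
then each optical section is scored for visibility of every spot.  The
per-plane fraction is the number of spots visible in that plane divided
by the total visibility count over all planes: a spot visible in k
sections contributes 1 to each of those sections and k to the
denominator (``mode="multi"``, default).  With ``mode="single"`` each
spot is instead assigned solely to its brightest section.  Plane 0 is
the basal section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ZStack
from .detection import DEFAULT_VISIBILITY_FACTOR, detect_spots, max_projection

__all__ = ["ZDistribution", "ZDistributionSummary", "z_fraction_per_cell", "aggregate_z"]


@dataclass
class ZDistribution:
    fractions: np.ndarray
    n_spots: int
    cell_id: str = ""
    explant_id: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.n_spots > 0 and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions of a non-empty cell must sum to 1")

    @property
    def empty(self) -> bool:
        return self.n_spots == 0


@dataclass
class ZDistributionSummary:
    mean_fractions: np.ndarray
    sd_fractions: np.ndarray
    n_explants: int


def z_fraction_per_cell(
    stack: ZStack,
    channel: str,
    min_photons: float = 1000.0,
    sigma_um: float = 0.2,
    visibility_factor: float = DEFAULT_VISIBILITY_FACTOR,
    mode: str = "multi",
    cell_id: str = "",
    explant_id: str = "",
) -> ZDistribution:
    """Per-plane spot fractions for one cell (one stack or ROI).

    Returns a flagged empty distribution (all-zero fractions, ``n_spots``
    0) when no spots pass the photon gate on the projection.
    """
    if mode not in ("multi", "single"):
        raise ValueError("mode must be 'multi' or 'single'")
    n_planes = stack.n_planes
    proj = max_projection(stack, channel)
    spots = detect_spots(proj, min_photons=min_photons, sigma_um=sigma_um)
    counts = np.zeros(n_planes)
    if not spots:
        return ZDistribution(counts, 0, cell_id, explant_id)

    data = stack[channel]
    # per-plane background stats computed once, not per spot
    from .detection import _background_stats, _integrate_window

    px = stack.pixel_size_um
    plane_stats = [_background_stats(data[z]) for z in range(n_planes)]
    radius_px = max(int(np.ceil(4.0 * sigma_um / px)), 2)
    for spot in spots:
        col = spot.x_um / px - 0.5
        row = spot.y_um / px - 0.5
        visible = np.empty(n_planes, dtype=bool)
        for z in range(n_planes):
            bg, noise = plane_stats[z]
            photons, _, _, n_pix = _integrate_window(data[z], row, col,
                                                     radius_px, bg)
            visible[z] = photons > visibility_factor * noise * np.sqrt(n_pix)
        if mode == "single":
            if visible.any():
                # brightest section wins
                px = stack.pixel_size_um
                col = int(spot.x_um / px)
                row = int(spot.y_um / px)
                vals = data[:, row, col]
                vals = np.where(visible, vals, -np.inf)
                counts[int(np.argmax(vals))] += 1
        else:
            counts += visible
    total = counts.sum()
    if total == 0:
        return ZDistribution(counts, 0, cell_id, explant_id)
    return ZDistribution(counts / total, len(spots), cell_id, explant_id)


def aggregate_z(cells: list[ZDistribution]) -> ZDistributionSummary:
    """Average cell distributions within explants, then across explants.

    Cells are grouped by their ``explant_id``; the summary's mean and SD
    per plane are taken over the explant means (SD is 0 for a single
    explant).  Empty cells are ignored.
    """
    cells = [c for c in cells if not c.empty]
    if not cells:
        raise ValueError("no non-empty cell distributions")
    n_planes = {c.fractions.size for c in cells}
    if len(n_planes) != 1:
        raise ValueError("all cells must share the number of sections")
    by_explant: dict[str, list[np.ndarray]] = {}
    for c in cells:
        by_explant.setdefault(c.explant_id, []).append(c.fractions)
    explant_means = np.array([np.mean(v, axis=0) for v in by_explant.values()])
    sd = (explant_means.std(axis=0, ddof=1) if len(by_explant) > 1
          else np.zeros(explant_means.shape[1]))
    return ZDistributionSummary(
        mean_fractions=explant_means.mean(axis=0),
        sd_fractions=sd,
        n_explants=len(by_explant),
    )


def summary_table(
    summaries: dict[str, ZDistributionSummary],
    z_spacing_um: float = 1.0,
) -> pd.DataFrame:
    """Long-format (condition, plane, z_um, mean, sd) table of summaries."""
    rows = []
    for condition, s in summaries.items():
        for plane, (m, sd) in enumerate(zip(s.mean_fractions, s.sd_fractions)):
            rows.append({
                "condition": condition,
                "plane": plane,
                "z_um": plane * z_spacing_um,
                "mean_fraction": m,
                "sd_fraction": sd,
                "n_explants": s.n_explants,
            })
    return pd.DataFrame(rows)
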