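"""Line-profile extraction and the membrane/cytoplasm intensity ratio.

A profile is sampled along a segment running from outside the cell,
across the membrane, into the cytoplasm.  The ratio is

    membrane/cytoplasm = (I_membrane - I_outside) / (I_inside - I_outside)

with I_outside the mean of the first (outer) zone, I_inside the mean of
the last (inner) zone, and I_membrane the maximum within the middle zone
(the membrane is a thin peak; a mean would dilute it).  Because both
numerator and denominator are intensity differences, the ratio is
invariant under affine intensity transforms a*I + b with a > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ImagePlane, LineProfile

__all__ = [
    "RatioResult",
    "DegenerateProfileError",
    "extract_profile",
    "membrane_cytoplasm_ratio",
    "radial_profiles",
    "aggregate_ratios",
    "DEFAULT_ZONE_FRACTIONS",
]

DEFAULT_ZONE_FRACTIONS = (0.25, 0.5, 0.25)


class DegenerateProfileError(ValueError):
    """Inside and outside intensities coincide; the ratio is undefined."""


@dataclass
class RatioResult:
    ratio: float
    i_membrane: float
    i_inside: float
    i_outside: float


def _zone_slices(n: int, zone_fractions=DEFAULT_ZONE_FRACTIONS) -> tuple[slice, slice, slice]:
    """Split n ordered samples into (outside, membrane, inside) zones."""
    f_out, f_mid, f_in = zone_fractions
    if min(f_out, f_mid, f_in) <= 0 or abs(f_out + f_mid + f_in - 1.0) > 1e-9:
        raise ValueError("zone_fractions must be positive and sum to 1")
    n_out = max(int(round(f_out * n)), 1)
    n_in = max(int(round(f_in * n)), 1)
    if n_out + n_in >= n:
        raise ValueError("profile too short for the requested zones")
    return slice(0, n_out), slice(n_out, n - n_in), slice(n - n_in, n)


def extract_profile(
    image: ImagePlane,
    p_start_um: tuple[float, float],
    p_end_um: tuple[float, float],
    sampling_um: float = 0.05,
    average_width_um: float = 0.0,
) -> LineProfile:
    """Bilinear intensity samples from ``p_start_um`` (outside the cell) to
    ``p_end_um`` (inside), equally spaced every ``sampling_um``.

    ``average_width_um`` emulates a profile drawn with a bar of finite
    width: intensities are averaged over parallel lines offset
    perpendicular to the segment across that width.  Averaging across the
    bar suppresses pixel noise without broadening the membrane peak along
    the profile direction.
    """
    if sampling_um <= 0:
        raise ValueError("sampling_um must be positive")
    if average_width_um < 0:
        raise ValueError("average_width_um must be non-negative")
    px = image.pixel_size_um
    w_um, h_um = image.extent_um
    for x, y in (p_start_um, p_end_um):
        if not (0 <= x <= w_um and 0 <= y <= h_um):
            raise ValueError("segment endpoint outside the image")
    x0, y0 = p_start_um
    x1, y1 = p_end_um
    length = math.hypot(x1 - x0, y1 - y0)
    n = max(int(math.floor(length / sampling_um)) + 1, 5)
    t = np.linspace(0.0, 1.0, n)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    if average_width_um > 0 and length > 0:
        # unit normal to the segment; one parallel line per half pixel
        nx, ny = -(y1 - y0) / length, (x1 - x0) / length
        n_lines = max(int(round(average_width_um / (0.5 * px))) | 1, 3)
        offsets = np.linspace(-average_width_um / 2, average_width_um / 2, n_lines)
    else:
        nx = ny = 0.0
        offsets = np.array([0.0])
    acc = np.zeros(n)
    for off in offsets:
        cols = (xs + off * nx) / px - 0.5
        rows = (ys + off * ny) / px - 0.5
        acc += ndimage.map_coordinates(image.data, [rows, cols], order=1,
                                       mode="nearest")
    return LineProfile(t * length, acc / offsets.size, outside_to_inside=True)


def membrane_cytoplasm_ratio(
    profile: LineProfile,
    zone_fractions=DEFAULT_ZONE_FRACTIONS,
    degeneracy_rtol: float = 1e-6,
) -> RatioResult:
    """Membrane/cytoplasm ratio of an outside-to-inside profile.

    Raises :class:`DegenerateProfileError` when the inside and outside
    levels differ by less than ``degeneracy_rtol`` times the profile's
    dynamic range.
    """
    if not profile.outside_to_inside:
        raise ValueError("profile must be oriented outside -> inside")
    vals = profile.intensities
    out_sl, mid_sl, in_sl = _zone_slices(len(profile), zone_fractions)
    i_outside = float(vals[out_sl].mean())
    i_inside = float(vals[in_sl].mean())
    i_membrane = float(vals[mid_sl].max())
    dynamic = float(vals.max() - vals.min())
    if abs(i_inside - i_outside) < degeneracy_rtol * max(dynamic, 1e-300):
        raise DegenerateProfileError("inside and outside intensities coincide")
    return RatioResult(
        ratio=(i_membrane - i_outside) / (i_inside - i_outside),
        i_membrane=i_membrane,
        i_inside=i_inside,
        i_outside=i_outside,
    )


def radial_profiles(
    image: ImagePlane,
    center_um: tuple[float, float],
    radius_um: float,
    n_angles: int = 8,
    margin_um: float = 1.5,
    sampling_um: float = 0.05,
    average_width_um: float = 0.4,
) -> list[LineProfile]:
    """Radial outside-to-inside profiles at evenly spaced angles.

    Each segment runs from ``radius_um + margin_um`` (outside) to
    ``radius_um - margin_um`` (inside) along a ray from the cell centre,
    averaged over a 0.4 um wide bar by default; rays leaving the image
    are skipped.
    """
    cx, cy = center_um
    w_um, h_um = image.extent_um
    profiles = []
    for k in range(n_angles):
        ang = 2 * np.pi * k / n_angles
        ux, uy = np.cos(ang), np.sin(ang)
        p_out = (cx + (radius_um + margin_um) * ux, cy + (radius_um + margin_um) * uy)
        p_in = (cx + (radius_um - margin_um) * ux, cy + (radius_um - margin_um) * uy)
        if not all(0 <= p[0] <= w_um and 0 <= p[1] <= h_um for p in (p_out, p_in)):
            continue
        profiles.append(extract_profile(image, p_out, p_in, sampling_um,
                                        average_width_um))
    return profiles


def aggregate_ratios(
    ratios: list[RatioResult],
    groups: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summary of ratios plus pairwise group comparisons.

    Returns (summary, pairwise) where ``summary`` has one row per group
    with n, mean, sem, median, q25, q75 and ``pairwise`` holds Welch
    t-test p-values for every pair of groups.
    """
    from .stats import t_test_two_sample

    if len(ratios) != len(groups):
        raise ValueError("ratios and groups must match in length")
    df = pd.DataFrame({"group": groups, "ratio": [r.ratio for r in ratios]})
    counts = df.groupby("group")["ratio"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 ratios: {bad}")
    summary = (
        df.groupby("group")["ratio"]
        .agg(
            n="count",
            mean="mean",
            sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
            median="median",
            q25=lambda v: v.quantile(0.25),
            q75=lambda v: v.quantile(0.75),
        )
        .reset_index()
    )
    rows = []
    names = summary["group"].tolist()
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            stat, p = t_test_two_sample(
                df.loc[df.group == ga, "ratio"].to_numpy(),
                df.loc[df.group == gb, "ratio"].to_numpy(),
            )
            rows.append({"group_a": ga, "group_b": gb, "t": stat, "p_value": p})
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p_value"])
    return summary, pairwise
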