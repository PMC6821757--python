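"""Frame-to-frame particle linking, trajectories, MSD and comigration.

Linking follows the radius-gated nearest-neighbour scheme of classical
single-particle tracking: spots in adjacent frames may be linked only if
their displacement is below ``max_disp_um`` (default 2.5 um), and among
all admissible one-to-one partial assignments the one minimizing

    sum of squared displacements + max_disp^2 * (number of unlinked spots)

is chosen (each admissible link is therefore always preferred over
leaving both spots unlinked).  A missed link terminates a trajectory; no
gap closing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import Spot, Trajectory

__all__ = [
    "ComigrationPair",
    "link_frames",
    "build_trajectories",
    "mean_squared_displacement",
    "estimate_diffusion",
    "find_comigration",
    "DEFAULT_MAX_DISP_UM",
]

DEFAULT_MAX_DISP_UM = 2.5
DEFAULT_SEP_THRESHOLD_UM = 0.3
DEFAULT_MIN_OVERLAP_FRAMES = 20


@dataclass
class ComigrationPair:
    id_a: int
    id_b: int
    overlap_frames: int
    mean_separation_um: float
    comigrating: bool


def _positions(spots: list[Spot]) -> np.ndarray:
    if not spots:
        return np.empty((0, 2))
    return np.array([[s.x_um, s.y_um] for s in spots])


def link_frames(
    spots_t: list[Spot],
    spots_t1: list[Spot],
    max_disp_um: float = DEFAULT_MAX_DISP_UM,
) -> list[tuple[int, int]]:
    """Optimal radius-gated assignment between two consecutive frames.

    Returns index pairs (i, j) linking ``spots_t[i]`` to ``spots_t1[j]``,
    sorted by i.  Spots further apart than ``max_disp_um`` are never
    linked; unassigned spots start or terminate trajectories.
    """
    n, m = len(spots_t), len(spots_t1)
    if n == 0 or m == 0:
        return []
    pa, pb = _positions(spots_t), _positions(spots_t1)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    gate2 = max_disp_um**2
    big = 1e12 * gate2
    # padded square matrix: dummies absorb unlinked spots at cost gate^2
    size = n + m
    cost = np.full((size, size), big)
    cost[:n, :m] = np.where(d2 < gate2, d2, big)
    cost[np.arange(n), m + np.arange(n)] = gate2
    cost[n + np.arange(m), np.arange(m)] = gate2
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    links = [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and d2[i, j] < gate2
    ]
    links.sort()
    return links


def build_trajectories(
    frames: list[list[Spot]],
    max_disp_um: float = DEFAULT_MAX_DISP_UM,
    min_length: int = 2,
    channel: str = "",
) -> list[Trajectory]:
    """Chain frame-pair assignments into trajectories.

    ``frames`` is an ordered list of per-frame spot lists (already photon
    gated).  Trajectories shorter than ``min_length`` frames are dropped.
    """
    if not frames:
        return []
    partial: list[list[tuple[int, Spot]]] = []  # growing chains
    finished: list[list[tuple[int, Spot]]] = []
    active: dict[int, list[tuple[int, Spot]]] = {}  # spot index -> chain
    for idx, spot in enumerate(frames[0]):
        chain = [(0, spot)]
        partial.append(chain)
        active[idx] = chain
    for t in range(1, len(frames)):
        links = link_frames(frames[t - 1], frames[t], max_disp_um)
        linked_prev = {i for i, _ in links}
        next_active: dict[int, list[tuple[int, Spot]]] = {}
        for i, j in links:
            chain = active.get(i)
            if chain is None:
                chain = [(t - 1, frames[t - 1][i])]
                partial.append(chain)
            chain.append((t, frames[t][j]))
            next_active[j] = chain
        for i, chain in active.items():
            if i not in linked_prev:
                finished.append(chain)
        for j, spot in enumerate(frames[t]):
            if j not in next_active:
                chain = [(t, spot)]
                partial.append(chain)
                next_active[j] = chain
        active = next_active
    finished.extend(active.values())

    trajs = []
    tid = 0
    for chain in finished:
        if len(chain) < min_length:
            continue
        ch = channel or chain[0][1].channel
        trajs.append(
            Trajectory(
                id=tid,
                channel=ch,
                frames=np.array([t for t, _ in chain]),
                x_um=np.array([s.x_um for _, s in chain]),
                y_um=np.array([s.y_um for _, s in chain]),
                photons=np.array([s.photons for _, s in chain]),
            )
        )
        tid += 1
    return trajs


def mean_squared_displacement(traj: Trajectory, max_lag: int) -> np.ndarray:
    """Time-averaged MSD (um^2) for lags 1..max_lag."""
    n = len(traj)
    if n < 2:
        raise ValueError("trajectory must span at least 2 frames")
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the trajectory length")
    pos = traj.positions
    msd = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        diffs = pos[lag:] - pos[:-lag]
        msd[lag - 1] = (diffs**2).sum(axis=1).mean()
    return msd


def estimate_diffusion(
    trajs: list[Trajectory],
    frame_interval_s: float,
    max_lag: int = 4,
) -> float:
    """Diffusion coefficient (um^2/s) from an ensemble MSD line fit.

    The per-lag MSDs of all trajectories are averaged weighted by the
    number of displacement pairs, then a straight line (with intercept,
    absorbing the localization-noise floor) is fitted over lags
    1..max_lag; D = slope / (4 * dt).
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    usable = [t for t in trajs if len(t) > max_lag]
    if not usable:
        raise ValueError("no trajectory longer than max_lag")
    lags = np.arange(1, max_lag + 1)
    num = np.zeros(max_lag)
    den = np.zeros(max_lag)
    for t in usable:
        msd = mean_squared_displacement(t, max_lag)
        weights = len(t) - lags
        num += msd * weights
        den += weights
    mean_msd = num / den
    slope, _ = np.polyfit(lags * frame_interval_s, mean_msd, 1)
    return float(slope / 4.0)


def _overlap(a: Trajectory, b: Trajectory) -> tuple[int, int]:
    start = max(a.frames[0], b.frames[0])
    stop = min(a.frames[-1], b.frames[-1])
    return int(start), int(stop)


def find_comigration(
    trajs_a: list[Trajectory],
    trajs_b: list[Trajectory],
    sep_threshold_um: float = DEFAULT_SEP_THRESHOLD_UM,
    min_overlap_frames: int = DEFAULT_MIN_OVERLAP_FRAMES,
) -> list[ComigrationPair]:
    """Cross-channel comigrating trajectory pairs.

    Every cross-channel pair overlapping for at least
    ``min_overlap_frames`` frames gets a record with its mean separation
    over the overlap; pairs below ``sep_threshold_um`` are resolved
    one-to-one greedily by ascending mean separation and flagged
    comigrating.
    """
    if trajs_a and trajs_b and trajs_a[0].channel == trajs_b[0].channel:
        raise ValueError("comigration requires two distinct channels")
    records: list[ComigrationPair] = []
    candidates: list[tuple[float, int, int, int]] = []
    for a in trajs_a:
        for b in trajs_b:
            start, stop = _overlap(a, b)
            overlap = stop - start + 1
            if overlap < min_overlap_frames:
                continue
            ia = slice(start - a.frames[0], stop - a.frames[0] + 1)
            ib = slice(start - b.frames[0], stop - b.frames[0] + 1)
            sep = np.hypot(
                a.x_um[ia] - b.x_um[ib], a.y_um[ia] - b.y_um[ib]
            ).mean()
            records.append(ComigrationPair(a.id, b.id, overlap, float(sep), False))
            if sep < sep_threshold_um:
                candidates.append((float(sep), a.id, b.id, len(records) - 1))
    used_a: set[int] = set()
    used_b: set[int] = set()
    for sep, ida, idb, ridx in sorted(candidates):
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        records[ridx].comigrating = True
    return records
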