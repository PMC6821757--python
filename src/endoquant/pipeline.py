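"""I/O, run configuration and end-to-end analysis orchestration.

Images travel as multi-page TIFF with a JSON description recording the
container kind, channel names, dimension order and calibration; spot,
profile and trajectory tables as CSV; results and run metadata as JSON.
Re-running an analysis with an identical configuration reproduces its
output tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .containers import MultiChannelImage, Spot, TimeSeries, Trajectory, ZStack

log = logging.getLogger("endoquant")

__all__ = [
    "write_stack",
    "read_stack",
    "spots_to_csv",
    "spots_from_csv",
    "trajectories_to_csv",
    "RunConfig",
    "run_analysis",
    "DEFAULTS",
]


# ---------------------------------------------------------------------------
# image containers <-> multi-page TIFF


def write_stack(path, container) -> None:
    """Write a channel container as multi-page TIFF (channel-major pages)."""
    path = Path(path)
    channels = container.channel_names
    arrays = [container[c] for c in channels]
    meta = {
        "channels": channels,
        "pixel_size_um": container.pixel_size_um,
    }
    if isinstance(container, MultiChannelImage):
        meta.update(kind="multichannel", order="c,y,x")
        pages = arrays
    elif isinstance(container, ZStack):
        meta.update(kind="zstack", order="c,z,y,x",
                    z_spacing_um=container.z_spacing_um,
                    n_planes=container.n_planes)
        pages = [p for a in arrays for p in a]
    elif isinstance(container, TimeSeries):
        meta.update(kind="timeseries", order="c,t,y,x",
                    frame_interval_s=container.frame_interval_s,
                    n_frames=container.n_frames)
        pages = [p for a in arrays for p in a]
    else:
        raise TypeError(f"cannot write {type(container).__name__}")
    tifffile.imwrite(path, np.stack(pages).astype(np.float64),
                     photometric="minisblack",
                     description=json.dumps(meta, sort_keys=True))


def read_stack(path, layout: dict | None = None):
    """Read a multi-page TIFF back into its calibrated container.

    ``layout`` overrides or supplies the description metadata (kind,
    channels, calibration) when the file carries none; missing calibration
    falls back to defaults with a logged warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if layout:
        meta.update(layout)
    if "kind" not in meta or "channels" not in meta:
        raise ValueError("layout must declare 'kind' and 'channels'")
    if pages.ndim == 2:
        pages = pages[None]
    channels = meta["channels"]
    n_ch = len(channels)
    if pages.shape[0] % n_ch:
        raise ValueError(
            f"page count {pages.shape[0]} not divisible by {n_ch} channels"
        )
    if "pixel_size_um" not in meta:
        log.warning("%s: no pixel size recorded, assuming 0.1 um", path.name)
    px = float(meta.get("pixel_size_um", 0.1))
    per = pages.shape[0] // n_ch
    split = {c: pages[i * per:(i + 1) * per].astype(float)
             for i, c in enumerate(channels)}
    kind = meta["kind"]
    if kind == "multichannel":
        if per != 1:
            raise ValueError("multichannel image must have one page per channel")
        return MultiChannelImage({c: a[0] for c, a in split.items()}, px)
    if kind == "zstack":
        return ZStack(split, px, float(meta.get("z_spacing_um", 1.0)))
    if kind == "timeseries":
        return TimeSeries(split, px, float(meta.get("frame_interval_s", 0.05)))
    raise ValueError(f"unknown container kind {kind!r}")


# ---------------------------------------------------------------------------
# tables


SPOT_COLUMNS = ["channel", "frame", "z_plane", "x_um", "y_um", "photons"]


def spots_to_csv(spots: list[Spot], path) -> None:
    rows = [
        {
            "channel": s.channel,
            "frame": -1 if s.frame is None else s.frame,
            "z_plane": -1 if s.z_plane is None else s.z_plane,
            "x_um": s.x_um,
            "y_um": s.y_um,
            "photons": s.photons,
        }
        for s in spots
    ]
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(path, index=False)


def spots_from_csv(path) -> list[Spot]:
    df = pd.read_csv(path)
    return [
        Spot(
            x_um=r.x_um, y_um=r.y_um, photons=r.photons, channel=str(r.channel),
            z_plane=None if r.z_plane < 0 else int(r.z_plane),
            frame=None if r.frame < 0 else int(r.frame),
        )
        for r in df.itertuples()
    ]


def trajectories_to_csv(trajs: list[Trajectory], path) -> None:
    rows = []
    for t in trajs:
        for k in range(len(t)):
            rows.append({
                "traj_id": t.id, "channel": t.channel, "frame": int(t.frames[k]),
                "x_um": t.x_um[k], "y_um": t.y_um[k], "photons": t.photons[k],
            })
    pd.DataFrame(
        rows, columns=["traj_id", "channel", "frame", "x_um", "y_um", "photons"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration

# Centralized analysis defaults.  Method-derived settings: 1000-photon
# detection gate, 2.5 um linking radius, 50 ms frame interval, 10 z-sections
# at 1 um starting basally, 3.8-fold screen threshold at alpha 0.05.
DEFAULTS: dict[str, dict] = {
    "generate": {
        "n_clusters": 50, "membrane_fraction": 0.8, "n_spots": 60,
        "z_weights": [0.667, 0.12, 0.07, 0.05, 0.035,
                      0.025, 0.015, 0.009, 0.005, 0.004],
        "n_particles": 8, "n_frames": 120, "D_um2_s": 0.05,
        "n_genes": 2000, "n_regulated": 100, "n_embryos": 60,
    },
    "coloc": {
        "width_px": 256, "height_px": 256, "pixel_size_um": 0.1,
        "n_clusters": 50, "membrane_fraction": 0.8, "psf_sigma_um": 0.2,
        "background": 10.0, "band_width_um": 0.4, "min_photons": 1000.0,
    },
    "profiles": {
        "ratios": [1.0, 1.5, 3.0], "n_cells": 10, "n_angles": 8,
        "i_inside": 100.0, "i_outside": 50.0, "psf_sigma_um": 0.2,
    },
    "axialdist": {
        "n_sections": 10, "z_spacing_um": 1.0, "n_explants": 3,
        "cells_per_explant": 3, "n_spots": 60, "min_photons": 1000.0,
        "visibility_factor": 5.0,
        "conditions": {
            "minus_wnt5a": [0.1] * 10,
            "plus_wnt5a": [0.667, 0.12, 0.07, 0.05, 0.035,
                           0.025, 0.015, 0.009, 0.005, 0.004],
        },
    },
    "tracking": {
        "n_particles": 8, "n_frames": 120, "D_um2_s": 0.05,
        "frame_interval_s": 0.05, "photon_rate": 5000.0, "fov_um": 15.0,
        "max_disp_um": 2.5, "min_photons": 1000.0, "psf_sigma_um": 0.2,
    },
    "comigrate": {
        "n_particles": 20, "n_frames": 200, "D_um2_s": 0.05,
        "frame_interval_s": 0.05, "n_comigrating_pairs": 3, "fov_um": 20.0,
        "localization_sigma_um": 0.02, "sep_threshold_um": 0.3,
        "min_overlap_frames": 20,
    },
    "screen": {
        "n_genes": 2000, "n_regulated": 100, "fold_change": 4.0,
        "n_replicates": 4, "noise_sd": 0.1, "fold_threshold": 3.8,
        "alpha": 0.05, "top_n": 100,
    },
    "phenotype": {
        "n_embryos": 60,
        "probs": {
            "control": [0.85, 0.10, 0.05],
            "morphant": [0.25, 0.40, 0.35],
        },
    },
}


@dataclasses.dataclass
class RunConfig:
    """One analysis run: name, seed, output directory, parameter overrides."""

    analysis: str
    seed: int = 0
    outdir: str | Path = "."
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.analysis not in DEFAULTS and self.analysis != "demo":
            raise ValueError(f"unknown analysis {self.analysis!r}")
        if self.analysis != "demo":
            unknown = set(self.params) - set(DEFAULTS[self.analysis])
            if unknown:
                raise ValueError(f"unknown parameter keys: {sorted(unknown)}")

    def resolved(self) -> dict:
        merged = dict(DEFAULTS.get(self.analysis, {}))
        merged.update(self.params)
        return merged

    def config_hash(self) -> str:
        blob = json.dumps(
            {"analysis": self.analysis, "seed": self.seed, "params": self.resolved()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _metadata(config: RunConfig) -> dict:
    resolved = config.resolved()
    provenance = {
        k: ("override" if k in config.params else "default") for k in resolved
    }
    return {
        "version": __version__,
        "analysis": config.analysis,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "params": resolved,
        "param_provenance": provenance,
    }


# ---------------------------------------------------------------------------
# analyses


def _run_coloc(p: dict, seed: int, out: Path) -> None:
    from . import coloc, detection, synthgen

    image, truth = synthgen.make_cell_image(
        p["width_px"], p["height_px"], p["pixel_size_um"], p["n_clusters"],
        p["membrane_fraction"], p["psf_sigma_um"], p["background"], seed,
    )
    marker = image.plane("membrane")
    signal = image.plane("clusters")
    m2 = coloc.manders_m2(signal, marker)
    mask = coloc.membrane_mask(marker, p["band_width_um"])
    spots = detection.detect_spots(signal, p["min_photons"], p["psf_sigma_um"])
    cls = coloc.classify_clusters(spots, mask, image.pixel_size_um)
    write_stack(out / "cell_image.tiff", image)
    spots_to_csv(spots, out / "clusters.csv")
    _write_json(out / "coloc.json", {
        "image_id": "synthetic_cell_0",
        "m2": m2.m2,
        "marker_threshold": m2.threshold_membrane,
        "n_membrane": cls.n_membrane,
        "n_cytoplasm": cls.n_cytoplasm,
        "fraction_membrane": cls.fraction_membrane,
        "truth_membrane_fraction": truth.membrane_fraction,
    })


def _run_profiles(p: dict, seed: int, out: Path) -> None:
    from . import profiles, synthgen

    all_ratios, groups, rows = [], [], []
    for gi, true_ratio in enumerate(p["ratios"]):
        for c in range(p["n_cells"]):
            img, truth = synthgen.make_ratio_cell(
                true_ratio, i_inside=p["i_inside"], i_outside=p["i_outside"],
                psf_sigma_um=p["psf_sigma_um"], seed=seed + 1000 * gi + c,
            )
            for prof in profiles.radial_profiles(
                img, truth["center_um"], truth["radius_um"], p["n_angles"]
            ):
                r = profiles.membrane_cytoplasm_ratio(prof)
                all_ratios.append(r)
                groups.append(f"ratio_{true_ratio}")
                rows.append({
                    "group": groups[-1], "cell": c, "ratio": r.ratio,
                    "i_membrane": r.i_membrane, "i_inside": r.i_inside,
                    "i_outside": r.i_outside,
                })
    pd.DataFrame(rows).to_csv(out / "ratios.csv", index=False)
    summary, pairwise = profiles.aggregate_ratios(all_ratios, groups)
    summary.to_csv(out / "ratio_summary.csv", index=False)
    pairwise.to_csv(out / "ratio_tests.csv", index=False)


def _run_axialdist(p: dict, seed: int, out: Path) -> None:
    from . import axialdist, synthgen

    summaries = {}
    per_cell_rows = []
    for ci, (condition, weights) in enumerate(sorted(p["conditions"].items())):
        cells = []
        for e in range(p["n_explants"]):
            for c in range(p["cells_per_explant"]):
                stack, _ = synthgen.make_zstack(
                    p["n_spots"], weights,
                    z_spacing_um=p["z_spacing_um"],
                    seed=seed + 10000 * ci + 100 * e + c,
                )
                z = axialdist.z_fraction_per_cell(
                    stack, "spots", p["min_photons"],
                    visibility_factor=p["visibility_factor"],
                    cell_id=f"c{c}", explant_id=f"e{e}",
                )
                cells.append(z)
                for plane, frac in enumerate(z.fractions):
                    per_cell_rows.append({
                        "condition": condition, "explant": f"e{e}",
                        "cell": f"c{c}", "plane": plane, "fraction": frac,
                    })
        summaries[condition] = axialdist.aggregate_z(cells)
    pd.DataFrame(per_cell_rows).to_csv(out / "z_fractions.csv", index=False)
    axialdist.summary_table(summaries, p["z_spacing_um"]).to_csv(
        out / "z_summary.csv", index=False
    )


def _run_tracking(p: dict, seed: int, out: Path) -> None:
    from . import detection, synthgen, tracking

    movie, truth = synthgen.make_brownian_movie(
        p["n_particles"], p["n_frames"], p["D_um2_s"], p["frame_interval_s"],
        p["photon_rate"], 0, p["fov_um"], seed, psf_sigma_um=p["psf_sigma_um"],
    )
    ch = movie.channel_names[0]
    frames = [
        detection.detect_spots(movie.plane(ch, t), p["min_photons"],
                               p["psf_sigma_um"], frame=t)
        for t in range(movie.n_frames)
    ]
    trajs = tracking.build_trajectories(frames, p["max_disp_um"], channel=ch)
    trajectories_to_csv(trajs, out / "trajectories.csv")
    d_est = tracking.estimate_diffusion(trajs, p["frame_interval_s"])
    _write_json(out / "tracking.json", {
        "n_trajectories": len(trajs),
        "diffusion_um2_s": d_est,
        "true_diffusion_um2_s": p["D_um2_s"],
    })


def _run_comigrate(p: dict, seed: int, out: Path) -> None:
    from . import synthgen, tracking

    truth = synthgen.simulate_brownian_paths(
        p["n_particles"], p["n_frames"], p["D_um2_s"], p["frame_interval_s"],
        p["n_comigrating_pairs"], p["fov_um"], p["localization_sigma_um"],
        seed=seed,
    )
    ch_a, ch_b = truth.trajectories.keys()
    pairs = tracking.find_comigration(
        truth.trajectories[ch_a], truth.trajectories[ch_b],
        p["sep_threshold_um"], p["min_overlap_frames"],
    )
    pd.DataFrame([
        {"id_a": q.id_a, "id_b": q.id_b, "overlap": q.overlap_frames,
         "mean_sep_um": q.mean_separation_um, "comigrating": q.comigrating}
        for q in pairs
    ]).to_csv(out / "comigration.csv", index=False)


def _run_screen(p: dict, seed: int, out: Path) -> None:
    from . import stats, synthgen

    table, truth = synthgen.make_expression_table(
        p["n_genes"], p["n_regulated"], p["fold_change"], p["n_replicates"],
        p["noise_sd"], seed,
    )
    hits = stats.screen_filter(table, p["fold_threshold"], p["alpha"], p["top_n"])
    table.to_csv(out / "expression.csv", index=False)
    hits.to_csv(out / "screen_hits.csv", index=False)
    hits.to_csv(out / "screen_topN.tsv", sep="\t", index=False)


def _run_phenotype(p: dict, seed: int, out: Path) -> None:
    from . import stats, synthgen

    tables = [
        synthgen.make_phenotype_counts(p["n_embryos"], probs, seed + i, cond)
        for i, (cond, probs) in enumerate(sorted(p["probs"].items()))
    ]
    table = pd.concat(tables)
    chi2, df, pval = stats.chi_square_test(table)
    table.to_csv(out / "phenotype_counts.csv")
    _write_json(out / "phenotype.json", {
        "chi2": chi2, "df": df, "p_value": pval,
        "n_embryos": int(table.to_numpy().sum()),
    })


def _run_generate(p: dict, seed: int, out: Path) -> None:
    """Write one synthetic artifact of every kind, with truth sidecars."""
    from . import synthgen

    image, cell_truth = synthgen.make_cell_image(
        n_clusters=p["n_clusters"], membrane_fraction=p["membrane_fraction"],
        seed=seed,
    )
    write_stack(out / "cell_image.tiff", image)
    _write_json(out / "cell_image.truth.json", {
        "cluster_positions": cell_truth.cluster_positions,
        "cluster_on_membrane": cell_truth.cluster_on_membrane,
        "membrane_fraction": cell_truth.membrane_fraction,
        "background_level": cell_truth.background_level,
    })
    stack, z_truth = synthgen.make_zstack(p["n_spots"], p["z_weights"], seed=seed)
    write_stack(out / "zstack.tiff", stack)
    _write_json(out / "zstack.truth.json", {
        "z_weights": list(z_truth.z_weights),
        "spot_records": z_truth.spot_records,
    })
    movie, m_truth = synthgen.make_brownian_movie(
        p["n_particles"], p["n_frames"], p["D_um2_s"], seed=seed,
    )
    write_stack(out / "movie.tiff", movie)
    _write_json(out / "movie.truth.json", {
        "diffusion_um2_s": m_truth.diffusion_coefficient,
        "comigrating_pairs": m_truth.comigrating_pairs,
        "photon_rate": m_truth.photon_rate,
    })
    table, e_truth = synthgen.make_expression_table(
        p["n_genes"], p["n_regulated"], seed=seed,
    )
    table.to_csv(out / "expression.csv", index=False)
    _write_json(out / "expression.truth.json", {
        "regulated_gene_ids": [
            g for g, f in zip(e_truth.gene_ids, e_truth.regulated_flags) if f
        ],
    })
    from .synthgen import make_phenotype_counts

    make_phenotype_counts(p["n_embryos"], [0.85, 0.10, 0.05], seed,
                          "control").to_csv(out / "phenotype_counts.csv")


_RUNNERS = {
    "generate": _run_generate,
    "coloc": _run_coloc,
    "profiles": _run_profiles,
    "axialdist": _run_axialdist,
    "tracking": _run_tracking,
    "comigrate": _run_comigrate,
    "screen": _run_screen,
    "phenotype": _run_phenotype,
}


def run_analysis(config: RunConfig) -> Path:
    """Execute one named analysis (or the full demo) and write its report.

    Returns the output directory.  Outputs are byte-reproducible from
    (config, seed).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.analysis == "demo":
        for name in _RUNNERS:
            sub = RunConfig(name, config.seed, out / name)
            run_analysis(sub)
        _write_json(out / "metadata.json", _metadata(config))
        return out
    params = config.resolved()
    log.info("analysis=%s seed=%d hash=%s", config.analysis, config.seed,
             config.config_hash())
    _RUNNERS[config.analysis](params, config.seed, out)
    _write_json(out / "metadata.json", _metadata(config))
    return out
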