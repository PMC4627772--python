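"""End-to-end runs: synthesize -> segment -> quantify -> summarize, and
simulate -> normalize -> fit.  Deterministic under fixed config + seed;
every run directory carries a manifest with the package version and the
resolved-config hash.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .frap.fitting import compare_mobility, fit_one_phase
from .frap.normalize import normalize_record
from .imaging.background import estimate_background
from .imaging.segment import build_compartments, segment_cells, segment_nuclei
from .imaging.stack import write_stack
from .imaging.tracking import link_labels
from .synthgen.frapsim import FRAPSimSpec, simulate_frap_record
from .synthgen.kinetics import TranslocationKinetics, simulate_kinetics
from .synthgen.scene import CellSpec, SyntheticScene, render_timelapse
from .translocation.ci import track_timelapse
from .translocation.normalize import normalize_minmax
from .translocation.summary import ConditionGroup, summarize_conditions

logger = logging.getLogger(__name__)


def _write_manifest(outdir: Path, config: RunConfig, outputs: list[str]) -> None:
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "outputs": sorted(outputs),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "resolved_config.json").write_text(
        json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n")


def _grid_cells(n_cells: int, cell_radius: float, nucleus_radius: float,
                margin: int = 4) -> tuple[list[CellSpec], tuple[int, int]]:
    """Lay cells on a square grid with no overlap; return cells + image shape."""
    per_row = int(np.ceil(np.sqrt(n_cells)))
    pitch = 2 * cell_radius + 2 * margin
    side = int(np.ceil(per_row * pitch + 2 * margin))
    cells = []
    for i in range(n_cells):
        r, c = divmod(i, per_row)
        center = (margin + pitch * (r + 0.5), margin + pitch * (c + 0.5))
        cells.append(CellSpec(center=center, cell_radius=cell_radius,
                              nucleus_radius=nucleus_radius))
    return cells, (side, side)


def segment_stack(stack, seg_cfg):
    """Per-frame nucleus + cell segmentation with centroid label linking."""
    marker = stack.channel("nuclear_marker")
    reporter = stack.channel("reporter")
    compartments = []
    backgrounds = []
    prev_nuclei = None
    for f in range(stack.n_frames):
        nuclei = segment_nuclei(marker[f], min_area_px=seg_cfg.min_area_px)
        if prev_nuclei is not None:
            nuclei, _ = link_labels(prev_nuclei, nuclei,
                                    max_displacement_px=seg_cfg.max_displacement_px)
        prev_nuclei = nuclei
        cells = segment_cells(reporter[f], nuclei)
        compartments.append(build_compartments(cells, nuclei))
        backgrounds.append(estimate_background(
            reporter[f], cells, dilation_px=seg_cfg.background_dilation_px))
    return compartments, backgrounds


def run_translocation(config: RunConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Synthesize each condition, segment, measure CI, normalize, summarize."""
    if config.translocation is None:
        raise ValueError("config has no translocation section")
    tcfg = config.translocation
    scfg = tcfg.scene
    measurements = []
    for ci, cond in enumerate(tcfg.conditions):
        kin = TranslocationKinetics(
            k_in_base=cond.k_in_base, k_in_stim=cond.k_in_stim,
            k_out=cond.k_out, t_stim=cond.t_stim_s,
        )
        times = np.arange(cond.n_frames) * cond.frame_interval_s
        traj = simulate_kinetics(kin, times)
        cells, shape = _grid_cells(cond.n_cells, scfg.cell_radius_px,
                                   scfg.nucleus_radius_px)
        scene = SyntheticScene(
            cells=cells, gain=scfg.gain, background=scfg.background,
            noise=(scfg.poisson_scale, scfg.gaussian_sd),
            blur_sigma=scfg.blur_sigma, pixel_size_um=scfg.pixel_size_um,
            frame_interval_s=cond.frame_interval_s,
            seed=config.seed + 1000 * ci, shape=shape,
        )
        stack, _truth = render_timelapse(scene, traj)
        compartments, backgrounds = segment_stack(stack, tcfg.segmentation)
        series = track_timelapse(stack, compartments, backgrounds)
        series["condition"] = cond.label
        series["reporter_group"] = cond.reporter_group
        measurements.append(series)
    meas = pd.concat(measurements, ignore_index=True)

    # condition-level CI: each cell's final-frame value, pooled for
    # min-max normalization across the whole batch
    last = meas[meas["frame"] == meas.groupby(
        ["condition", "cell_id"])["frame"].transform("max")]
    valid = last[last["valid"]].copy()
    exclusions = last[~last["valid"]].copy()
    normed, (lo, hi) = normalize_minmax(valid["ci"].to_numpy())
    valid["ci_norm"] = normed

    groups = [
        ConditionGroup(label=lbl, reporter_group=grp,
                       ci_values=sub["ci_norm"].tolist())
        for (grp, lbl), sub in valid.groupby(["reporter_group", "condition"])
    ]
    summary = summarize_conditions(groups, tcfg.baseline_label,
                                   tcfg.reference_group)
    summary.attrs["normalization_pool"] = {"min": lo, "max": hi}

    results = {"measurements": meas, "summary": summary,
               "exclusions": exclusions}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs = []
        for name, df in results.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            outputs.append(path.name)
        pool = {"normalization_min": lo, "normalization_max": hi}
        (outdir / "normalization_pool.json").write_text(
            json.dumps(pool, indent=2) + "\n")
        outputs.append("normalization_pool.json")
        _write_manifest(outdir, config, outputs)
    return results


def run_frap(config: RunConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Simulate configured FRAP groups, double-normalize and fit each record."""
    if config.frap is None:
        raise ValueError("config has no frap section")
    fits_rows = []
    curves = []
    fits_by_group: dict[str, list] = {}
    for gi, grp in enumerate(config.frap.groups):
        fits_by_group[grp.label] = []
        for r in range(grp.n_records):
            spec = FRAPSimSpec(
                mobile_fraction=grp.mobile_fraction, k_true=grp.k_true,
                bleach_depth=grp.bleach_depth, pre_s=grp.pre_s,
                bleach_s=grp.bleach_s, post_s=grp.post_s,
                line_rate_hz=grp.line_rate_hz, line_len_px=grp.line_len_px,
                acq_bleach_rate=grp.acq_bleach_rate, noise_sd=grp.noise_sd,
                seed=config.seed + 10_000 * gi + r,
            )
            record, truth = simulate_frap_record(spec)
            recovery = normalize_record(record)
            fit = fit_one_phase(recovery)
            fits_by_group[grp.label].append(fit)
            fits_rows.append({
                "group": grp.label, "record": r,
                "i0": fit.i0, "a": fit.a, "k": fit.k,
                "t_half_s": fit.t_half_s, "plateau": fit.plateau,
                "if_pct": fit.immobile_fraction_pct,
                "resid_sd": fit.residual_sd, "converged": fit.converged,
                "reliable": fit.reliable, "flags": fit.flags,
                "true_k": truth.k_true,
                "true_if_pct": truth.true_immobile_fraction_pct,
            })
            curves.append(pd.DataFrame({
                "group": grp.label, "record": r,
                "t_s": recovery.t, "y": recovery.y,
            }))
    fits = pd.DataFrame(fits_rows)
    curves_df = pd.concat(curves, ignore_index=True)

    comparisons = []
    labels = list(fits_by_group)
    for other in labels[1:]:
        if len(fits_by_group[labels[0]]) >= 2 and len(fits_by_group[other]) >= 2:
            for metric, comp in compare_mobility(
                    fits_by_group[labels[0]], fits_by_group[other]).items():
                comparisons.append({
                    "group_a": labels[0], "group_b": other, "metric": metric,
                    "mean_a": comp.mean_a, "sem_a": comp.sem_a,
                    "mean_b": comp.mean_b, "sem_b": comp.sem_b,
                    "t": comp.t_statistic, "p": comp.p_value,
                    "stars": comp.stars,
                })
    comparison_df = pd.DataFrame(comparisons)

    results = {"fits": fits, "curves": curves_df, "comparison": comparison_df}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs = []
        for name, df in results.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            outputs.append(path.name)
        _write_manifest(outdir, config, outputs)
    return results


def make_fixtures(config: RunConfig, outdir) -> dict:
    """Write the documented TIFF/CSV fixture set plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []

    kin = TranslocationKinetics(k_in_base=0.05, k_in_stim=0.2, k_out=0.1,
                                t_stim=600.0)
    times = np.arange(12) * 120.0
    traj = simulate_kinetics(kin, times)
    cells, shape = _grid_cells(4, 14.0, 8.0)
    scene = SyntheticScene(cells=cells, seed=config.seed, shape=shape,
                           noise=(1.0, 2.0), blur_sigma=0.5)
    stack, truth = render_timelapse(scene, traj)
    write_stack(stack, outdir / "timelapse.tiff")
    truth.to_frame().to_csv(outdir / "timelapse_truth.csv", index=False)
    outputs += ["timelapse.tiff", "timelapse_truth.csv"]

    spec = FRAPSimSpec(mobile_fraction=0.82, k_true=4.5, noise_sd=0.01,
                       seed=config.seed)
    record, frap_truth = simulate_frap_record(spec)
    np.savetxt(outdir / "frap_kymogram.csv", record.kymogram, delimiter=",")
    outputs.append("frap_kymogram.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "files": sorted(outputs),
        "frap_truth": {
            "mobile_fraction": frap_truth.mobile_fraction,
            "k_true": frap_truth.k_true,
            "true_if_pct": frap_truth.true_immobile_fraction_pct,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
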