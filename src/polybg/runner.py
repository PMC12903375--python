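"""Experiment driver: run a validated config and serialize its outputs.

Every run writes deterministic data tables (TSV/JSON, byte-identical across
reruns of the same config) plus a provenance record (the full config, seed,
package version, timestamp) sufficient to reproduce the run exactly.  Plots
are optional conveniences; all downstream analysis reads the data files.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .architecture import NormalEffects, UniformFrequencies, sample_architecture
from .config import RunConfig, dump_config
from .liability import model_from_background_rate, profiles_to_frame, variant_effect_profile
from .popsim import variance_scaling_experiment
from .selection import FitnessModel, environment_shift_scenario

__all__ = ["run"]

log = logging.getLogger("polybg")


def run(
    config: RunConfig,
    out_dir: str | Path,
    force: bool = False,
    make_plots: bool = False,
) -> list[Path]:
    """Execute the configured experiment and write its outputs.

    Returns the list of files written.  Refuses to overwrite existing output
    files unless ``force`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runner = {
        "variant_profile": _run_profile,
        "variance_scaling": _run_variance,
        "environment_shift": _run_scenario,
    }[config.experiment]
    log.info("experiment=%s root_seed=%d out=%s", config.experiment, config.root_seed, out_dir)
    written = runner(config, out_dir, force, make_plots)
    written.append(_write_provenance(config, out_dir, force))
    return written


def _check_overwrite(path: Path, force: bool) -> Path:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force to overwrite")
    return path


def _write_tsv(frame: pd.DataFrame, path: Path, force: bool) -> Path:
    _check_overwrite(path, force)
    frame.to_csv(path, sep="\t", index=False)
    return path


def _write_provenance(config: RunConfig, out_dir: Path, force: bool) -> Path:
    path = _check_overwrite(out_dir / "provenance.json", force)
    record = {
        "experiment": config.experiment,
        "root_seed": config.root_seed,
        "config": config.model_dump(mode="json"),
        "config_yaml": dump_config(config),
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path


def _run_profile(
    config: RunConfig, out_dir: Path, force: bool, make_plots: bool
) -> list[Path]:
    params = config.profile
    grid = params.grid()
    profiles = []
    for rate in params.background_rates:
        model = model_from_background_rate(rate)
        profiles.append(variant_effect_profile(model, params.delta, grid))
        log.info("profiled background_rate=%g over %d grid points", rate, len(grid))
    frame = profiles_to_frame(profiles)
    written = [_write_tsv(frame, out_dir / "variant_profile.tsv", force)]
    if make_plots:
        written.append(_plot_profile(frame, out_dir, force))
    return written


def _variance_dists(params):
    return (
        UniformFrequencies(params.freq_low, params.freq_high),
        NormalEffects(params.effect_mean, params.effect_sd),
    )


def _run_variance(
    config: RunConfig, out_dir: Path, force: bool, make_plots: bool
) -> list[Path]:
    params = config.variance
    freq_dist, effect_dist = _variance_dists(params)
    results = variance_scaling_experiment(
        params.gene_counts,
        n_individuals=params.n_individuals,
        n_replicates=params.n_replicates,
        freq_dist=freq_dist,
        effect_dist=effect_dist,
        interaction_density=params.interaction_density,
        interaction_dist=NormalEffects(params.interaction_mean, params.interaction_sd),
        modes=params.modes,
        root_seed=config.root_seed,
        resample_architectures=params.resample_architectures,
    )
    replicates = pd.concat([r.to_frame() for r in results.values()], ignore_index=True)
    summary = pd.concat([r.aggregate_frame() for r in results.values()], ignore_index=True)
    for mode, r in results.items():
        log.info(
            "mode=%s mean variance at largest gene count: %.4g",
            mode,
            r.mean_variance[-1],
        )
    written = [
        _write_tsv(replicates, out_dir / "variance_replicates.tsv", force),
        _write_tsv(summary, out_dir / "variance_summary.tsv", force),
    ]
    if make_plots:
        written.append(_plot_variance(summary, out_dir, force))
    return written


def _run_scenario(
    config: RunConfig, out_dir: Path, force: bool, make_plots: bool
) -> list[Path]:
    params = config.scenario
    arch = sample_architecture(
        params.n_genes,
        UniformFrequencies(params.freq_low, params.freq_high),
        NormalEffects(params.effect_mean, params.effect_sd),
        seed=config.root_seed,
    )
    trajectory = environment_shift_scenario(
        arch,
        params.n_individuals,
        model_from_background_rate(params.background_rate),
        FitnessModel(selection_strength=params.selection_strength),
        generations_per_phase=params.generations_per_phase,
        shift_offset=params.shift_offset,
        seed=config.root_seed,
        selection_mode=params.selection_mode,
    )
    summary = trajectory.phase_summary()
    for phase, stats in summary.items():
        log.info(
            "phase=%s end mean liability %.4f, prevalence %.4g",
            phase,
            stats["end_mean_liability"],
            stats["end_prevalence"],
        )
    summary_path = _check_overwrite(out_dir / "scenario_summary.json", force)
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written = [
        _write_tsv(trajectory.to_frame(), out_dir / "trajectory.tsv", force),
        summary_path,
    ]
    if make_plots:
        written.append(_plot_scenario(trajectory.to_frame(), out_dir, force))
    return written


# -- optional plots ---------------------------------------------------------


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _plot_profile(frame: pd.DataFrame, out_dir: Path, force: bool) -> Path:
    plt = _mpl()
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for rate, sub in frame.groupby("background_rate"):
        axes[0].plot(sub["pgs"], sub["odds_ratio_change"], label=f"rate={rate:g}")
        axes[1].plot(sub["pgs"], sub["prevalence_without"])
        axes[2].plot(sub["pgs"], sub["prevalence_change"])
    axes[0].set_ylabel("absolute odds change")
    axes[1].set_ylabel("prevalence")
    axes[2].set_ylabel("prevalence change")
    for ax in axes:
        ax.set_xlabel("background PGS (log-odds units)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    path = _check_overwrite(out_dir / "variant_profile.png", force)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _plot_variance(summary: pd.DataFrame, out_dir: Path, force: bool) -> Path:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    for mode, sub in summary.groupby("mode"):
        ax.errorbar(sub["gene_count"], sub["mean_variance"], yerr=sub["sem"], label=mode)
    ax.set_xlabel("number of contributing genes")
    ax.set_ylabel("PGS variance")
    ax.legend()
    fig.tight_layout()
    path = _check_overwrite(out_dir / "variance_scaling.png", force)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _plot_scenario(frame: pd.DataFrame, out_dir: Path, force: bool) -> Path:
    plt = _mpl()
    fig, axes = plt.subplots(2, 1, figsize=(6, 5), sharex=True)
    axes[0].plot(frame["generation"], frame["mean_liability"])
    axes[0].set_ylabel("mean genetic liability")
    axes[1].plot(frame["generation"], frame["prevalence"])
    axes[1].set_ylabel("disease prevalence")
    axes[1].set_xlabel("generation")
    for boundary in frame.loc[frame["phase"].ne(frame["phase"].shift()), "generation"]:
        for ax in axes:
            ax.axvline(boundary, color="grey", lw=0.5, ls="--")
    fig.tight_layout()
    path = _check_overwrite(out_dir / "environment_shift.png", force)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
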