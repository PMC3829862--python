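"""End-to-end pipeline: simulate (or load) -> segment -> trace -> screen -> QC.

``run_pipeline`` executes the whole analysis for one plate and writes the
result CSVs plus a run manifest (config hash, seed, per-plate Z', hit list).
Re-running with the same config and seed reproduces the outputs byte for
byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash, to_dict
from .io import read_layout, read_stack, write_results, write_stack, write_layout
from .layout import PlateLayout, make_layout
from .screen import build_screen_table, well_results_frame, zprime
from .segmentation import segment_field
from .simulate import SimParams, simulate_plate
from .traces import analyze_well

log = logging.getLogger("fretscreen")

__all__ = ["PipelineResult", "run_pipeline", "analyze_stacks"]


@dataclass
class PipelineResult:
    well_table: pd.DataFrame
    screen_table: pd.DataFrame
    plate_qc: pd.DataFrame
    hits: list
    manifest: dict
    output_paths: dict = field(default_factory=dict)


def _sim_params_from_config(config: RunConfig) -> SimParams:
    sim = config.simulation
    return SimParams(
        genotype_amplitude=sim.genotype_amplitude,
        responder_fraction=sim.responder_fraction,
        n_cells=sim.n_cells,
        field_shape=(sim.field_height, sim.field_width),
        photon_noise_scale=sim.photon_noise_scale,
        compound_suppression=dict(sim.compound_suppression),
    )


def analyze_stacks(
    stacks,
    layout: PlateLayout,
    config: RunConfig,
) -> tuple:
    """Segment and score every stack; returns (well_table, screen_table, qc)."""
    ana = config.analysis
    results = []
    t0 = time.perf_counter()
    for stack in stacks:
        seg = segment_field(stack)
        result, _ = analyze_well(
            stack,
            seg,
            threshold=ana.responsive_threshold,
            min_responsive_cells=ana.min_responsive_cells,
        )
        results.append(result)
    log.info(
        "analyzed %d wells in %.1f s", len(results), time.perf_counter() - t0
    )
    well_df = well_results_frame(results, layout)
    screen_df = build_screen_table(
        well_df,
        hit_cutoff=ana.hit_cutoff,
        k_sd=ana.autofluor_k_sd,
        toxic_fraction=ana.toxic_fraction,
    )
    tp = well_df.loc[(well_df["role"] == "TP") & well_df["valid"]]
    dmso = well_df.loc[(well_df["role"] == "DMSO") & well_df["valid"]]
    dmso_mean = float(dmso["mean_peak_responsive"].mean())
    qc = zprime(
        tp["mean_peak_responsive"].to_numpy(float) / dmso_mean,
        dmso["mean_peak_responsive"].to_numpy(float) / dmso_mean,
        plate_id=layout.plate_id,
    )
    qc_df = pd.DataFrame(
        [
            {
                "plate_id": qc.plate_id,
                "mu_tp": qc.mu_tp,
                "sigma_tp": qc.sigma_tp,
                "mu_dmso": qc.mu_dmso,
                "sigma_dmso": qc.sigma_dmso,
                "zprime_canonical": qc.zprime_canonical,
                "zprime_as_printed": qc.zprime_as_printed,
            }
        ]
    )
    return well_df, screen_df, qc_df


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate/load + full analysis per the configuration and write
    every output table under ``config.paths.output_dir``."""
    outdir = Path(config.paths.output_dir)
    chash = config_hash(config)

    if config.simulation.enabled:
        sim = config.simulation
        compound_ids = sorted(sim.compound_suppression) or [
            f"CMP{i + 1:03d}" for i in range(sim.n_compounds)
        ]
        layout = make_layout(
            compound_ids,
            n_replicates=sim.n_replicates,
            n_dmso=sim.n_dmso,
            n_tp=sim.n_tp,
            n_cpa=0,
            n_tmb8=0,
            n_untreated=0,
        )
        params = _sim_params_from_config(config)
        log.info("simulating %d wells (seed %d)", len(layout), config.seed)
        plate = simulate_plate(layout, params, seed=config.seed)
        stacks = [plate.wells[w.well_id].stack for w in layout]
        if config.paths.stacks_dir:
            stacks_dir = Path(config.paths.stacks_dir)
            for stack in stacks:
                write_stack(stack, stacks_dir / f"{stack.well_id}.tiff")
            write_layout(layout, stacks_dir / "layout.csv")
    else:
        if not config.paths.layout_csv:
            raise ValueError("analysis of stored stacks needs paths.layout_csv")
        layout = read_layout(config.paths.layout_csv)
        stacks_dir = Path(config.paths.stacks_dir)
        stacks = []
        for well in layout:
            p = stacks_dir / f"{well.well_id}.tiff"
            if not p.exists():
                raise FileNotFoundError(f"stage load: no stack for well {well.well_id}")
            stacks.append(read_stack(p))

    try:
        well_df, screen_df, qc_df = analyze_stacks(stacks, layout, config)
    except Exception as exc:
        raise RuntimeError(f"stage analyze failed: {exc}") from exc

    for df in (well_df, screen_df, qc_df):
        df["config_hash"] = chash
    hits = screen_df.loc[screen_df["hit"], "compound_id"].tolist()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "config": to_dict(config),
        "n_wells": int(len(well_df)),
        "zprime_canonical": float(qc_df["zprime_canonical"].iloc[0]),
        "zprime_as_printed": float(qc_df["zprime_as_printed"].iloc[0]),
        "hits": hits,
    }
    paths = write_results(
        {"wells": well_df, "screen": screen_df, "plate_qc": qc_df}, outdir
    )
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return PipelineResult(
        well_table=well_df,
        screen_table=screen_df,
        plate_qc=qc_df,
        hits=hits,
        manifest=manifest,
        output_paths=paths,
    )
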