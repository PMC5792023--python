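"""Pipeline orchestration: simulate -> correct -> segment -> quantify.

Each stage writes its outputs before the next starts; a JSON manifest
records the config hash, per-stage seeds and record counts so that a run
can be replayed bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import (colocalised_fractions, coloc_time_series,
                    population_chance)
from .config import ConfigError, SimulationConfig
from .foci import detect_and_fit, foci_per_cell, write_focus_csv
from .imageprep import (average_projection, cell_intensity_trace,
                        correct_offset_and_flatten, segment_cells,
                        write_cell_geometry_csv)
from .photobleach import (CalibrationConstant, calibrate_single_molecule,
                          concentration, copy_number, find_return_events,
                          fit_two_exponential)
from .sim import generate_rapid_acquisition, save_ground_truth, \
    simulate_focus_tables, timelapse_times_min
from .stack import MovieStack
from .stats import summarise

__all__ = ["StageError", "RunManifest", "run_pipeline",
           "simulate_stage", "analyze_stage", "coloc_stage", "report_stage"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: list = field(default_factory=list)

    def record(self, stage: str, outputs: list, counts: dict) -> None:
        self.stages.append({"stage": stage, "outputs": outputs,
                            "counts": counts})

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "version": self.version, "stages": self.stages}, indent=1))


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _stage_seed(seed: int, stage_index: int) -> int:
    # fixed offsets so each stage is independently reproducible
    return int(seed) + 1000 * stage_index


def simulate_stage(config: SimulationConfig, scenario: str, outdir: Path,
                   seed: int, n_cells: int = 20) -> dict:
    acq = generate_rapid_acquisition(config, scenario=scenario,
                                     n_cells=n_cells, seed=seed)
    acq.yfp.save(outdir / "rapid_yfp")
    acq.brightfield.save(outdir / "brightfield")
    save_ground_truth(acq.ground_truth, outdir / "ground_truth")
    return {"frames": acq.yfp.n_frames, "cells": n_cells,
            "molecules": int(acq.ground_truth.molecules.n)}


def analyze_stage(config: SimulationConfig, outdir: Path, seed: int,
                  threshold_sd: float = 5.0) -> dict:
    stack = MovieStack.load(outdir / "rapid_yfp")
    bf = MovieStack.load(outdir / "brightfield")
    corrected = correct_offset_and_flatten(stack, config.camera_offset_au)
    cells = segment_cells(bf.data[0], config.pixel_size_nm)
    write_cell_geometry_csv(cells, outdir / "cells_measured.csv")

    # foci on an average projection of the first 9 frames
    proj = average_projection(corrected, min(9, corrected.n_frames))
    union = np.zeros(proj.frame_shape, dtype=bool)
    for c in cells:
        union |= c.mask
    foci = [f for f in detect_and_fit(proj.data[0], config.pixel_size_nm,
                                      mask=union,
                                      threshold_sd=threshold_sd,
                                      psf_sigma_px=config.psf_sigma_px)
            if f.accepted]
    assignment = foci_per_cell(foci, cells)
    write_focus_csv(foci, outdir / "foci.csv")

    # single-molecule calibration: transient return events late in the movie
    late = corrected.n_frames * 2 // 3
    events = [fo.integrated_au for fo in find_return_events(
        corrected, config.pixel_size_nm, start_frame=late, mask=union,
        threshold_sd=threshold_sd, psf_sigma_px=config.psf_sigma_px)]
    try:
        cal = calibrate_single_molecule(
            events, reference_exposure_ms=config.reference_exposure_ms)
        cal_source = "return_events"
    except ValueError:
        cal = CalibrationConstant(
            label="YPet", I_single_au=config.I_single_au,
            reference_exposure_ms=config.reference_exposure_ms,
            n_events=0, sd_au=0.0)
        cal_source = "configured"

    rows = []
    for c in cells:
        trace = cell_intensity_trace(corrected, c, capture_halo_px=2)
        # tau2 bounded away from tau1 (the fluorophore-free control decay
        # pins the background lifetime near 60 s); stabilises A1 in dim cells
        fit = fit_two_exponential(corrected.timestamps_s, trace,
                                  tau1_fixed_s=config.tau_bleach_s,
                                  tau2_min_s=30.0)
        n_mol = copy_number(fit, c, cal,
                            exposure_ms=corrected.exposure_ms)
        rows.append({
            "cell_id": c.cell_id, "A1": fit.A1, "A2": fit.A2,
            "tau2": fit.tau2, "area_um2": c.area_um2,
            "volume_fL": c.volume_fl, "N_molecules": n_mol,
            "conc_nM": concentration(n_mol, c.volume_fl),
            "foci": assignment["counts"].get(c.cell_id, 0),
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "copy_numbers.csv", index=False)
    return {"cells_segmented": len(cells), "foci_accepted": len(foci),
            "foci_unassigned": assignment["n_unassigned"],
            "calibration": cal_source,
            "calibration_events": cal.n_events,
            "fits": len(rows)}


def coloc_stage(config: SimulationConfig, scenario: str, outdir: Path,
                seed: int, n_cells: int = 20, n_replicates: int = 3,
                radius_nm: float = 200.0) -> dict:
    times = timelapse_times_min(config)
    records = []
    table_scenario = scenario if scenario in ("damage", "undamaged") \
        else "damage"
    for rep in range(n_replicates):
        cells_t, fa, fb = simulate_focus_tables(
            config, scenario=table_scenario, n_cells=n_cells,
            times_min=times, seed=_stage_seed(seed, 3) + rep)
        for it, t in enumerate(times):
            sa = fa[fa.time_min == t]
            sb = fb[fb.time_min == t]
            foci_by_cell = {cid: grp for cid, grp in sb.groupby("cell_id")}
            outlines = [c.to_outline() for c in cells_t[it]]
            chance = population_chance(outlines, foci_by_cell,
                                       radius_nm=radius_nm)
            records.append(colocalised_fractions(
                sa, sb, radius_nm=radius_nm, time_min=float(t),
                chance=chance, replicate=rep))
    per_rep = pd.DataFrame([{
        "time_min": r.time_min, "replicate": r.replicate,
        "n_A": r.n_a, "n_B": r.n_b,
        "frac_A_with_B": r.frac_a_with_b, "frac_B_with_A": r.frac_b_with_a,
        "se_A": r.se_a, "se_B": r.se_b, "chance": r.chance,
    } for r in records])
    per_rep.to_csv(outdir / "coloc_records.csv", index=False)
    curves = coloc_time_series(records)
    curves.to_csv(outdir / "coloc_curves.csv", index=False)
    return {"time_points": len(times), "replicates": n_replicates,
            "records": len(records)}


def report_stage(outdir: Path) -> dict:
    out = {}
    cn_path = outdir / "copy_numbers.csv"
    if cn_path.exists():
        df = pd.read_csv(cn_path)
        if len(df):
            s = summarise(df["N_molecules"])
            out["copy_number"] = {"mean": s.mean, "sd": s.sd, "sem": s.sem,
                                  "n": s.n}
            sc = summarise(df["conc_nM"])
            out["concentration_nM"] = {"mean": sc.mean, "sd": sc.sd,
                                       "sem": sc.sem, "n": sc.n}
    curves = outdir / "coloc_curves.csv"
    if curves.exists():
        df = pd.read_csv(curves)
        out["coloc_mean_frac_a_with_b"] = float(
            df["frac_a_with_b"].mean())
    (outdir / "summary.json").write_text(json.dumps(out, indent=1))
    return {"sections": len(out)}


def run_pipeline(config: SimulationConfig, scenario: str, outdir: str | Path,
                 seed: int | None = None, n_cells: int = 20,
                 stages: tuple = ("simulate", "analyze", "coloc", "report"),
                 threshold_sd: float = 5.0,
                 radius_nm: float = 200.0) -> RunManifest:
    """Execute the pipeline stages in order, writing a manifest.

    A failing stage raises :class:`StageError` naming the stage; outputs of
    completed stages are retained.
    """
    if scenario not in ("undamaged", "damage", "dead"):
        raise ConfigError(f"unknown scenario {scenario!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    manifest = RunManifest(config_hash=config_hash(config), seed=seed)
    runners = {
        "simulate": lambda: simulate_stage(config, scenario, outdir,
                                           _stage_seed(seed, 0),
                                           n_cells=n_cells),
        "analyze": lambda: analyze_stage(config, outdir,
                                         _stage_seed(seed, 1),
                                         threshold_sd=threshold_sd),
        "coloc": lambda: coloc_stage(config, scenario, outdir,
                                     _stage_seed(seed, 2), n_cells=n_cells,
                                     radius_nm=radius_nm),
        "report": lambda: report_stage(outdir),
    }
    outputs_by_stage = {
        "simulate": ["rapid_yfp.tif", "rapid_yfp.json", "brightfield.tif",
                     "brightfield.json", "ground_truth"],
        "analyze": ["cells_measured.csv", "foci.csv", "copy_numbers.csv"],
        "coloc": ["coloc_records.csv", "coloc_curves.csv"],
        "report": ["summary.json"],
    }
    for stage in stages:
        if stage not in runners:
            raise ConfigError(f"unknown stage {stage!r}")
        try:
            counts = runners[stage]()
        except ConfigError:
            raise
        except Exception as exc:
            manifest.save(outdir / "manifest.json")
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        manifest.record(stage, outputs_by_stage[stage], counts)
        manifest.save(outdir / "manifest.json")
    return manifest
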