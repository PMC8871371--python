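"""File-based `run-all`: execute the full chain and write every artifact
plus a provenance manifest (parameters, seeds, checksums)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .axes import TimeAxis, make_irf
from .config import RunConfig
from .endpoints import omi_index, per_cell_endpoints, redox_ratio_map
from .fitting import FitOptions, fit_image
from .io import (
    read_decay_cube,
    write_decay_cube,
    write_irf_csv,
    write_label_image,
    write_parameter_maps,
)
from .segmentation import classify_tnfa, segment_macrophages
from .simulate import CHANNELS, render_decay_cube, render_reporter_images, simulate_cohort
from .stats import GlmSpec, fit_glm

import tifffile

__all__ = ["run_all"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Run simulate -> fit -> segment -> endpoints -> stats, writing all
    artifacts under ``out_dir`` and a ``manifest.json`` with checksums.

    Any stage failure halts the run with the stage name and the offending
    input in the error message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    axis = TimeAxis(n_bins=config.fit.n_bins, window=config.fit.window_ns)
    irf = make_irf(config.fit.irf_fwhm_ps, axis, peak_bin=config.fit.irf_peak_bin)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
        "files": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as e:
                raise StageError(f"stage {name!r} failed: {e}") from e
            manifest["stages"][name] = {"wall_s": round(time.perf_counter() - t0, 3)}
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return deco

    @stage("simulate")
    def sim_result():
        sim = simulate_cohort(config.simulate)
        write_irf_csv(irf, out / "irf.csv")
        sim.truth.to_csv(out / "truth.csv", index=False)
        for i, scene in enumerate(sim.scenes):
            fdir = out / f"field_{i:03d}"
            fdir.mkdir(exist_ok=True)
            for j, ch in enumerate(CHANNELS):
                cube = render_decay_cube(
                    scene, ch, irf, axis, seed=int(scene.spec.seed) + 1 + j
                )
                write_decay_cube(cube, fdir / f"{ch}.tif")
            mch, gfp = render_reporter_images(
                scene,
                signal=config.reporter.signal,
                background=config.reporter.background,
                noise_sd=config.reporter.noise_sd,
                seed=int(scene.spec.seed) + 3,
            )
            tifffile.imwrite(fdir / "mcherry.tif", mch.astype(np.float32))
            tifffile.imwrite(fdir / "gfp.tif", gfp.astype(np.float32))
            write_label_image(scene.labels, fdir / "labels_true.tif")
        return sim

    sim = sim_result
    field_dirs = sorted(out.glob("field_*"))

    @stage("fit")
    def _fit():
        for fdir in field_dirs:
            for ch in CHANNELS:
                cube = read_decay_cube(fdir / f"{ch}.tif")
                maps = fit_image(
                    cube.counts,
                    irf,
                    axis,
                    threshold=config.fit.threshold,
                    binning=config.fit.binning,
                    options=FitOptions(channel=ch, objective=config.fit.objective),
                )
                write_parameter_maps(maps, fdir / f"{ch}_maps.tif")

    @stage("segment")
    def _segment():
        for fdir in field_dirs:
            mch = tifffile.imread(fdir / "mcherry.tif")
            gfp = tifffile.imread(fdir / "gfp.tif")
            li = segment_macrophages(
                mch, threshold=config.segment.threshold, min_area=config.segment.min_area
            )
            write_label_image(li.labels, fdir / "labels.tif")
            ann = classify_tnfa(li, gfp, gfp_threshold=config.segment.gfp_threshold)
            pd.DataFrame(
                [dataclasses.asdict(a) for a in ann]
            ).to_csv(fdir / "annotations.csv", index=False)
            (fdir / "segmentation.json").write_text(json.dumps(li.provenance, indent=1))

    @stage("endpoints")
    def cells_table():
        from .io import read_label_image, read_parameter_maps
        from .segmentation import CellAnnotation, LabelImage

        tables = []
        for fdir, scene in zip(field_dirs, sim.scenes):
            maps_n = read_parameter_maps(fdir / "nadph_maps.tif")
            maps_f = read_parameter_maps(fdir / "fad_maps.tif")
            labels = LabelImage(labels=read_label_image(fdir / "labels.tif"))
            ann_df = pd.read_csv(fdir / "annotations.csv")
            ann = [CellAnnotation(**row) for row in ann_df.to_dict("records")]
            redox = redox_ratio_map(
                maps_n.intensity, maps_f.intensity, validity=maps_n.valid & maps_f.valid
            )
            tables.append(
                per_cell_endpoints(maps_n, maps_f, redox, labels, ann, metadata=scene.meta)
            )
        cells = pd.concat(tables, ignore_index=True)
        cells = cells.dropna(subset=["orr", "nadph_tm", "fad_tm"]).reset_index(drop=True)
        if len(cells) == 0:
            raise ValueError("no cells with valid endpoints survived")
        cells = omi_index(cells)
        cells.to_csv(out / "cells.csv", index=False)
        return cells

    @stage("stats")
    def _stats():
        sdir = out / "stats"
        sdir.mkdir(exist_ok=True)
        for oc in config.stats.outcomes:
            spec = GlmSpec(
                outcome=oc.outcome,
                treatment=config.stats.treatment,
                interaction=config.stats.interaction,
                block=config.stats.block,
                log_transform=oc.log_transform,
                cluster=config.stats.cluster,
            )
            res = fit_glm(cells_table, spec)
            res.params.rename("estimate").to_csv(sdir / f"{oc.outcome}_coefficients.csv")
            res.group_means.to_csv(sdir / f"{oc.outcome}_means.csv", index=False)
            res.contrasts.to_csv(sdir / f"{oc.outcome}_contrasts.csv", index=False)
            (sdir / f"{oc.outcome}_settings.json").write_text(
                json.dumps(
                    {
                        "spec": dataclasses.asdict(spec),
                        "n_cells": res.n_cells,
                        "n_larvae": res.n_larvae,
                        "n_days": res.n_days,
                        "df_inference": res.df_inference,
                        "covariance": "CR1 cluster sandwich, t(G-1) inference",
                    },
                    indent=1,
                )
            )

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _config_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)
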