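"""In-memory orchestration: simulate -> fit -> segment -> endpoints -> stats.

These helpers chain the pipeline stages on in-memory objects; the file-based
`run-all` command in :mod:`omiflim.runner` wraps them with readers/writers
and a provenance manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .axes import TimeAxis, make_irf
from .endpoints import omi_index, per_cell_endpoints, redox_ratio_map
from .fitting import FitOptions, fit_image
from .segmentation import classify_tnfa, segment_macrophages
from .simulate import CHANNELS, CohortDesign, GroundTruthScene, render_decay_cube, render_reporter_images, simulate_cohort

__all__ = ["PipelineSettings", "process_field", "run_cohort"]


@dataclass(frozen=True)
class PipelineSettings:
    """Tunable parameters of the imaging stages."""

    time_axis: TimeAxis = field(default_factory=TimeAxis)
    irf_fwhm_ps: float = 260.0
    irf_peak_bin: int = 25
    fit_threshold: float = 500.0
    binning: int = 1
    objective: str = "wls"
    seg_threshold: float = 0.15
    min_area: int = 25
    gfp_threshold: float | None = None
    reporter_signal: float = 1000.0
    reporter_background: float = 10.0
    reporter_noise_sd: float = 2.0


def process_field(scene: GroundTruthScene, settings: PipelineSettings | None = None) -> pd.DataFrame:
    """Run one field of view end to end: render both decay channels and the
    reporter images, fit per pixel, segment, classify, and average per cell.

    Returns the per-cell endpoint table for the field (``omi`` unfilled;
    the OMI index needs cohort-level normalization means).
    """
    s = settings or PipelineSettings()
    axis = s.time_axis
    irf = make_irf(s.irf_fwhm_ps, axis, peak_bin=s.irf_peak_bin)
    base_seed = int(scene.spec.seed)

    maps = {}
    for i, ch in enumerate(CHANNELS):
        cube = render_decay_cube(scene, ch, irf, axis, seed=base_seed + 1 + i)
        maps[ch] = fit_image(
            cube.counts,
            irf,
            axis,
            threshold=s.fit_threshold,
            binning=s.binning,
            options=FitOptions(channel=ch, objective=s.objective),
        )

    mcherry, gfp = render_reporter_images(
        scene,
        signal=s.reporter_signal,
        background=s.reporter_background,
        noise_sd=s.reporter_noise_sd,
        seed=base_seed + 3,
    )
    label_image = segment_macrophages(mcherry, threshold=s.seg_threshold, min_area=s.min_area)
    annotations = classify_tnfa(label_image, gfp, gfp_threshold=s.gfp_threshold)
    redox = redox_ratio_map(
        maps["nadph"].intensity,
        maps["fad"].intensity,
        validity=maps["nadph"].valid & maps["fad"].valid,
    )
    return per_cell_endpoints(
        maps["nadph"], maps["fad"], redox, label_image, annotations, metadata=scene.meta
    )


def run_cohort(
    design: CohortDesign, settings: PipelineSettings | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and push every field through the imaging pipeline.

    Returns ``(cell_table, truth_table)``; the cell table has the OMI index
    filled with all cells pooled as the normalization group.
    """
    sim = simulate_cohort(design)
    tables = [process_field(scene, settings) for scene in sim.scenes]
    cells = pd.concat(tables, ignore_index=True)
    cells = cells.dropna(subset=["orr", "nadph_tm", "fad_tm"]).reset_index(drop=True)
    if len(cells):
        cells = omi_index(cells)
    return cells, sim.truth
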