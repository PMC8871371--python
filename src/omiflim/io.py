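"""Readers and writers for the pipeline's interchange formats.

Decay cubes travel as multi-page 16-bit grayscale TIFF (one page per time
bin, page order = time order) with a JSON sidecar describing the channel,
time axis, seeds and cohort identifiers. Parameter maps are 32-bit float
multi-page TIFF with a documented page order. IRFs are 2-column CSV, label
images 16-bit TIFF, and tables plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .axes import IRFKernel, TimeAxis
from .fitting import ParameterMaps

__all__ = [
    "DecayCube",
    "SidecarError",
    "read_decay_cube",
    "write_decay_cube",
    "read_irf_csv",
    "write_irf_csv",
    "read_parameter_maps",
    "write_parameter_maps",
    "read_label_image",
    "write_label_image",
]

PARAMETER_MAP_PAGES = (
    "tau1",
    "tau2",
    "alpha1",
    "tau_mean",
    "intensity",
    "offset",
    "chi2",
    "valid",
    "n_photons",
)


class SidecarError(ValueError):
    """Raised when a JSON sidecar is missing or fails schema validation."""


@dataclass
class DecayCube:
    """Photon-count histogram cube for one spectral channel.

    counts : (rows, cols, n_bins) nonnegative integers (float allowed for
        noiseless expected cubes).
    """

    counts: np.ndarray
    time_axis: TimeAxis
    channel: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 3:
            raise ValueError(f"counts must be 3-D (rows, cols, bins), got {arr.ndim}-D")
        if arr.shape[2] != self.time_axis.n_bins:
            raise ValueError(
                f"cube has {arr.shape[2]} bins but time axis declares "
                f"{self.time_axis.n_bins}"
            )
        if np.any(arr < 0):
            raise ValueError("photon counts must be nonnegative")
        self.counts = arr

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=2)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_decay_cube(cube: DecayCube, path: str | Path) -> Path:
    """Write a cube as multi-page uint16 TIFF plus JSON sidecar (lossless
    round-trip for integer counts)."""
    path = Path(path)
    arr = np.asarray(cube.counts)
    if np.issubdtype(arr.dtype, np.floating):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("cube counts are not integral; cannot write losslessly")
        arr = np.round(arr)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed uint16 range")
    pages = np.ascontiguousarray(np.moveaxis(arr.astype(np.uint16), 2, 0))
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "channel": cube.channel,
        "time_axis": {"n_bins": cube.time_axis.n_bins, "window_ns": cube.time_axis.window},
        **cube.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def read_decay_cube(path: str | Path) -> DecayCube:
    path = Path(path)
    sc = _sidecar_path(path)
    if not sc.exists():
        raise SidecarError(f"missing sidecar {sc}")
    meta = json.loads(sc.read_text())
    if "time_axis" not in meta:
        raise SidecarError("sidecar missing required field 'time_axis'")
    ta = meta.pop("time_axis")
    for key in ("n_bins", "window_ns"):
        if key not in ta:
            raise SidecarError(f"sidecar time_axis missing required field {key!r}")
    axis = TimeAxis(n_bins=int(ta["n_bins"]), window=float(ta["window_ns"]))
    channel = meta.pop("channel", None)
    if channel is None:
        raise SidecarError("sidecar missing required field 'channel'")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != axis.n_bins:
        raise ValueError(
            f"page-count mismatch: TIFF has {pages.shape[0]} pages, sidecar "
            f"declares {axis.n_bins} bins"
        )
    counts = np.moveaxis(pages, 0, 2)
    return DecayCube(counts=counts, time_axis=axis, channel=channel, meta=meta)


def write_irf_csv(irf: IRFKernel, path: str | Path) -> Path:
    path = Path(path)
    rows = np.column_stack([np.arange(len(irf.values)), irf.values])
    header = f"bin,value\nfwhm_ps={irf.fwhm_ps}"
    np.savetxt(path, rows, delimiter=",", header=header)
    return path


def read_irf_csv(path: str | Path, fwhm_ps: float | None = None) -> IRFKernel:
    path = Path(path)
    fwhm = fwhm_ps
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "fwhm_ps=" in line:
                fwhm = float(line.split("fwhm_ps=")[1])
            if not line.startswith("#"):
                break
    data = np.loadtxt(path, delimiter=",")
    values = data[:, 1]
    return IRFKernel(values=values, fwhm_ps=float(fwhm) if fwhm is not None else float("nan"))


def write_parameter_maps(maps: ParameterMaps, path: str | Path) -> Path:
    """Write ParameterMaps as 32-bit float multi-page TIFF.

    Page order: tau1, tau2, alpha1, tau_mean, intensity, offset, chi2,
    valid (0/1), n_photons. Fit settings go in the JSON sidecar.
    """
    path = Path(path)
    pages = np.stack(
        [np.asarray(getattr(maps, name), dtype=np.float32) for name in PARAMETER_MAP_PAGES]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps({"pages": list(PARAMETER_MAP_PAGES), **maps.settings}, indent=1, default=str)
    )
    return path


def read_parameter_maps(path: str | Path) -> ParameterMaps:
    path = Path(path)
    sc = _sidecar_path(path)
    settings = {}
    if sc.exists():
        settings = json.loads(sc.read_text())
        settings.pop("pages", None)
    pages = tifffile.imread(path)
    if pages.shape[0] != len(PARAMETER_MAP_PAGES):
        raise ValueError(
            f"expected {len(PARAMETER_MAP_PAGES)} pages, found {pages.shape[0]}"
        )
    kwargs = {
        name: pages[i].astype(float) for i, name in enumerate(PARAMETER_MAP_PAGES)
    }
    kwargs["valid"] = kwargs["valid"] > 0.5
    return ParameterMaps(settings=settings, **kwargs)


def write_label_image(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    arr = np.asarray(labels)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for uint16")
    tifffile.imwrite(path, arr.astype(np.uint16))
    return path


def read_label_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int64)
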