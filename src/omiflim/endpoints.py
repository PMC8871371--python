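"""Optical endpoints: redox ratio maps, per-cell averaging, and the OMI index.

The optical redox ratio (ORR) is I_NAD(P)H / (I_NAD(P)H + I_FAD) per pixel,
computed from the fitted decay-component photon counts (background offset
excluded), so it lies in [0, 1] wherever defined. All endpoints are
arithmetically averaged over the valid pixels of each segmented cell. The
OMI index of cell i is

    ORR_i/<ORR> + tauM_NAD(P)H_i/<tauM_NAD(P)H> - tauM_FAD_i/<tauM_FAD>,

with <.> arithmetic means over a declared normalization group; by
construction the group-mean OMI index is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import ParameterMaps
from .segmentation import CellAnnotation, LabelImage

__all__ = [
    "RedoxMap",
    "redox_ratio_map",
    "per_cell_endpoints",
    "omi_index",
    "CELL_TABLE_COLUMNS",
]

log = logging.getLogger(__name__)

# Documented column order of the per-cell CSV (the imaging -> statistics contract).
CELL_TABLE_COLUMNS = [
    "cell_id",
    "larva_id",
    "day_id",
    "treatment",
    "tnfa_status",
    "n_valid_pixels",
    "orr",
    "nadph_tm",
    "nadph_t1",
    "nadph_t2",
    "nadph_a1",
    "fad_tm",
    "fad_t1",
    "fad_t2",
    "fad_a1",
    "omi",
]


@dataclass
class RedoxMap:
    """Per-pixel optical redox ratio with a validity mask."""

    values: np.ndarray
    valid: np.ndarray


def redox_ratio_map(
    nadph_intensity: np.ndarray,
    fad_intensity: np.ndarray,
    validity: np.ndarray | None = None,
) -> RedoxMap:
    """ORR = I_N / (I_N + I_F) per pixel.

    Pixels where both intensities are zero (or outside ``validity``) are
    marked invalid. Negative intensities raise.
    """
    i_n = np.asarray(nadph_intensity, dtype=float)
    i_f = np.asarray(fad_intensity, dtype=float)
    if i_n.shape != i_f.shape:
        raise ValueError(f"shape mismatch: {i_n.shape} vs {i_f.shape}")
    if np.any(i_n < 0) or np.any(i_f < 0):
        raise ValueError("intensities must be nonnegative")
    denom = i_n + i_f
    valid = denom > 0
    if validity is not None:
        valid &= np.asarray(validity, dtype=bool)
    values = np.full(i_n.shape, np.nan)
    np.divide(i_n, denom, out=values, where=valid)
    return RedoxMap(values=values, valid=valid)


def _masked_mean(values: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    sel = values[mask]
    if sel.size == 0:
        return np.nan, 0
    return float(sel.mean()), int(sel.size)


def per_cell_endpoints(
    maps_nadph: ParameterMaps,
    maps_fad: ParameterMaps | None,
    redox: RedoxMap | None,
    label_image: LabelImage,
    annotations: list[CellAnnotation] | None = None,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Average every endpoint over the valid pixels of each cell.

    ``maps_fad`` and ``redox`` may be None when the FAD channel was not
    acquired (e.g. GFP-reporter experiments); the corresponding columns are
    NaN. Cells with zero valid pixels in the NAD(P)H map are dropped with a
    warning. ``metadata`` (larva_id, day_id, treatment) is propagated to
    every row.
    """
    labels = label_image.labels
    if labels.shape != maps_nadph.shape:
        raise ValueError(
            f"shape mismatch: labels {labels.shape} vs maps {maps_nadph.shape}"
        )
    if maps_fad is not None and maps_fad.shape != maps_nadph.shape:
        raise ValueError("NAD(P)H and FAD maps have different shapes")
    meta = metadata or {}
    status = {a.cell_id: a.tnfa_status for a in (annotations or [])}

    rows = []
    for cid in sorted(label_image.areas()):
        cell_mask = labels == cid
        valid_n = cell_mask & maps_nadph.valid
        row: dict = {
            "cell_id": int(cid),
            "larva_id": meta.get("larva_id"),
            "day_id": meta.get("day_id"),
            "treatment": meta.get("treatment"),
            "tnfa_status": status.get(cid),
        }
        n_valid = int(np.count_nonzero(valid_n))
        if n_valid == 0:
            log.warning("cell %d has no valid fitted pixels; dropped", cid)
            continue
        row["n_valid_pixels"] = n_valid
        for name, key in (
            ("nadph_tm", "tau_mean"),
            ("nadph_t1", "tau1"),
            ("nadph_t2", "tau2"),
            ("nadph_a1", "alpha1"),
        ):
            row[name], _ = _masked_mean(getattr(maps_nadph, key), valid_n)
        if maps_fad is not None:
            valid_f = cell_mask & maps_fad.valid
            for name, key in (
                ("fad_tm", "tau_mean"),
                ("fad_t1", "tau1"),
                ("fad_t2", "tau2"),
                ("fad_a1", "alpha1"),
            ):
                row[name], _ = _masked_mean(getattr(maps_fad, key), valid_f)
        else:
            row.update({k: np.nan for k in ("fad_tm", "fad_t1", "fad_t2", "fad_a1")})
        if redox is not None:
            row["orr"], _ = _masked_mean(redox.values, cell_mask & redox.valid)
        else:
            row["orr"] = np.nan
        row["omi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def omi_index(
    cohort_table: pd.DataFrame,
    normalization_group: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Fill the ``omi`` column of a per-cell table.

    ``normalization_group`` is a boolean mask selecting the cells whose
    arithmetic means define <ORR>, <tauM_NAD(P)H>, <tauM_FAD>; by default
    all cells are pooled. The mean OMI over the normalization group is 1 by
    construction.
    """
    if len(cohort_table) == 0:
        raise ValueError("cohort table is empty")
    tab = cohort_table.copy()
    if normalization_group is None:
        group = np.ones(len(tab), dtype=bool)
    else:
        group = np.asarray(normalization_group, dtype=bool)
        if group.shape != (len(tab),):
            raise ValueError("normalization_group mask length mismatch")
        if not group.any():
            raise ValueError("normalization group is empty")
    means = {c: tab.loc[group, c].mean() for c in ("orr", "nadph_tm", "fad_tm")}
    for c, m in means.items():
        if not np.isfinite(m) or m <= 0:
            raise ValueError(f"cohort mean of {c} is not positive ({m}); cannot normalize")
    tab["omi"] = (
        tab["orr"] / means["orr"]
        + tab["nadph_tm"] / means["nadph_tm"]
        - tab["fad_tm"] / means["fad_tm"]
    )
    tab.attrs["omi_normalization"] = {
        "n_group": int(group.sum()),
        **{f"mean_{k}": float(v) for k, v in means.items()},
    }
    return tab
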