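"""Cytoplasm masks and single-cell aggregation of fitted lifetime maps.

Whole-cell and nuclear label images (0 = background, matching integer ids
label the same cell in both) are combined into cytoplasm masks by per-label
set subtraction; the eight per-cell OMI variables — NAD(P)H and FAD
tau_m, tau1, tau2, alpha1 — are unweighted means of the per-pixel fitted
values over each cell's valid cytoplasm pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import ParameterMap

logger = logging.getLogger(__name__)

__all__ = ["MaskSet", "derive_cytoplasm", "aggregate_cells", "FEATURE_COLUMNS", "OMI_VARIABLES"]

#: the eight OMI variables, in table order
OMI_VARIABLES = (
    "nadh_tm", "nadh_t1", "nadh_t2", "nadh_a1",
    "fad_tm", "fad_t1", "fad_t2", "fad_a1",
)

#: fixed schema of the single-cell feature table
FEATURE_COLUMNS = (
    "cell_id", "field", "line", "day", "substrate",
    *OMI_VARIABLES,
    "n_valid_nadh", "n_valid_fad",
)

_CHANNEL_MAP_VARS = {"tm": "tau_m_ns", "t1": "tau1_ns", "t2": "tau2_ns", "a1": "alpha1"}


@dataclass
class MaskSet:
    """Whole-cell, nuclear and derived cytoplasm label images."""

    whole_cell: np.ndarray
    nuclei: np.ndarray
    cytoplasm: np.ndarray
    dropped_labels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (self.whole_cell.shape == self.nuclei.shape == self.cytoplasm.shape):
            raise ValueError("mask geometries differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.whole_cell.shape

    @property
    def labels(self) -> np.ndarray:
        """Cell ids present in the whole-cell mask (background excluded)."""
        lab = np.unique(self.whole_cell)
        return lab[lab > 0]

    @property
    def cytoplasm_labels(self) -> np.ndarray:
        lab = np.unique(self.cytoplasm)
        return lab[lab > 0]


def derive_cytoplasm(whole_cell: np.ndarray, nuclei: np.ndarray) -> MaskSet:
    """Subtract nuclear from whole-cell masks, label by label.

    Nuclear pixels lying outside their own cell's whole-cell mask are
    discarded with a warning (segmentation slop, not an error).  Cells
    whose cytoplasm would be empty are dropped from the cytoplasm image
    and reported in ``dropped_labels``.
    """
    whole_cell = np.asarray(whole_cell)
    nuclei = np.asarray(nuclei)
    if whole_cell.shape != nuclei.shape:
        raise ValueError(
            f"geometry mismatch: whole-cell {whole_cell.shape} vs nuclei {nuclei.shape}"
        )
    stray = (nuclei > 0) & (nuclei != whole_cell)
    if np.any(stray):
        logger.warning(
            "%d nuclear pixels fall outside their cell and are ignored",
            int(stray.sum()),
        )
    cytoplasm = np.where((whole_cell > 0) & (nuclei == whole_cell), 0, whole_cell)
    dropped = []
    for lab in np.unique(whole_cell):
        if lab > 0 and not np.any(cytoplasm == lab):
            dropped.append(int(lab))
    if dropped:
        logger.warning("cells with empty cytoplasm dropped: %s", dropped)
    return MaskSet(
        whole_cell=whole_cell,
        nuclei=nuclei,
        cytoplasm=cytoplasm,
        dropped_labels=tuple(dropped),
    )


def _cell_means(pmap: ParameterMap, region: np.ndarray) -> dict[str, float] | None:
    """Mean of each fitted variable over a region's valid pixels, or None."""
    sel = region & pmap.valid
    n = int(sel.sum())
    if n == 0:
        return None
    out = {"n_valid": n}
    for short, attr in _CHANNEL_MAP_VARS.items():
        out[short] = float(pmap.variable(attr)[sel].mean())
    return out


def aggregate_cells(
    param_map_nadh: ParameterMap,
    param_map_fad: ParameterMap,
    masks: MaskSet,
    meta: dict | None = None,
    min_pixels: int = 10,
) -> pd.DataFrame:
    """Aggregate per-pixel fits into one row of eight OMI variables per cell.

    Each variable is the unweighted mean over the cell's valid cytoplasm
    pixels; cells with fewer than ``min_pixels`` valid pixels in either
    channel are excluded (tally in ``result.attrs['n_excluded']``).
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    for pm, name in ((param_map_nadh, "NADH"), (param_map_fad, "FAD")):
        if pm.shape != masks.shape:
            raise ValueError(
                f"geometry mismatch: {name} map {pm.shape} vs masks {masks.shape}"
            )
    meta = dict(meta or {})
    field_id = meta.pop("field", param_map_nadh.field_id)
    line = meta.pop("line", "")
    day = meta.pop("day", "")
    substrate = meta.pop("substrate", "")

    rows = []
    n_excluded = 0
    for lab in masks.cytoplasm_labels:
        region = masks.cytoplasm == lab
        nadh = _cell_means(param_map_nadh, region)
        fad = _cell_means(param_map_fad, region)
        if (
            nadh is None or fad is None
            or nadh["n_valid"] < min_pixels or fad["n_valid"] < min_pixels
        ):
            n_excluded += 1
            continue
        rows.append({
            "cell_id": int(lab), "field": field_id,
            "line": line, "day": day, "substrate": substrate,
            "nadh_tm": nadh["tm"], "nadh_t1": nadh["t1"],
            "nadh_t2": nadh["t2"], "nadh_a1": nadh["a1"],
            "fad_tm": fad["tm"], "fad_t1": fad["t1"],
            "fad_t2": fad["t2"], "fad_a1": fad["a1"],
            "n_valid_nadh": nadh["n_valid"], "n_valid_fad": fad["n_valid"],
        })
    table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    table.attrs["n_excluded"] = n_excluded
    if n_excluded:
        logger.info(
            "aggregate_cells: %d cells excluded (< %d valid pixels), %d emitted",
            n_excluded, min_pixels, len(table),
        )
    return table
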