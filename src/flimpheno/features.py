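"""Per-pixel derived maps and the twelve per-cell autofluorescence features.

The twelve features per cell are the intensity redox ratio
FAD/(FAD + NAD(P)H), the fluorescence lifetime redox ratio
FLIRR = NAD(P)H alpha2 / FAD alpha1, and per channel the mean lifetime
tau_m = alpha1*tau1 + alpha2*tau2, tau1, tau2, alpha1 and intensity.
Undefined pixels carry NaN sentinels which propagate through aggregation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .fitting import FLIMImage
from .segmentation import SegmentationLabels
from .synth import FEATURE_NAMES

logger = logging.getLogger(__name__)


def mean_lifetime_map(flim: FLIMImage) -> np.ndarray:
    """Amplitude-weighted mean lifetime alpha1*tau1 + (1-alpha1)*tau2 (ns)."""
    return flim.alpha1 * flim.tau1 + (1.0 - flim.alpha1) * flim.tau2


def redox_ratio_map(nadh_intensity: np.ndarray,
                    fad_intensity: np.ndarray) -> np.ndarray:
    """Intensity redox ratio FAD / (FAD + NAD(P)H); NaN where both are zero."""
    nadh = np.asarray(nadh_intensity, dtype=float)
    fad = np.asarray(fad_intensity, dtype=float)
    if nadh.shape != fad.shape:
        raise ValueError("channel geometries differ")
    total = nadh + fad
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, fad / total, np.nan)
    return out


def flirr_map(nadh_fits: FLIMImage, fad_fits: FLIMImage) -> np.ndarray:
    """Lifetime redox ratio NAD(P)H alpha2 / FAD alpha1; NaN where FAD alpha1=0."""
    if nadh_fits.alpha1.shape != fad_fits.alpha1.shape:
        raise ValueError("channel geometries differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(fad_fits.alpha1 > 0,
                       (1.0 - nadh_fits.alpha1) / fad_fits.alpha1, np.nan)
    return out


def _compartment_mask(labels: SegmentationLabels, cid: int, compartment: str):
    if compartment == "cytoplasm":
        return labels.cytoplasm == cid
    if compartment == "mitochondria":
        return (labels.cytoplasm == cid) & labels.mitochondria
    if compartment == "cytosol":
        return (labels.cytoplasm == cid) & ~labels.mitochondria
    if compartment == "cell":
        return labels.cells == cid
    raise ValueError(f"unknown compartment {compartment!r}")


def aggregate_cell_features(nadh: FLIMImage, fad: FLIMImage,
                            labels: SegmentationLabels,
                            compartment: str = "cytoplasm",
                            min_valid_pixels: int = 10,
                            group: str | None = None,
                            batch: str = "img") -> pd.DataFrame:
    """Average the twelve per-pixel feature maps over each cell's compartment.

    Cells with fewer than ``min_valid_pixels`` jointly valid pixels are
    dropped (logged).  Returns one row per cell with identifiers first.
    """
    maps = {
        "redox_ratio": redox_ratio_map(nadh.intensity, fad.intensity),
        "flirr": flirr_map(nadh, fad),
        "nadh_tm": mean_lifetime_map(nadh),
        "nadh_t1": nadh.tau1, "nadh_t2": nadh.tau2, "nadh_a1": nadh.alpha1,
        "nadh_intensity": nadh.intensity,
        "fad_tm": mean_lifetime_map(fad),
        "fad_t1": fad.tau1, "fad_t2": fad.tau2, "fad_a1": fad.alpha1,
        "fad_intensity": fad.intensity,
    }
    joint_valid = nadh.valid & fad.valid
    rows, dropped = [], 0
    for cid in labels.cell_ids:
        mask = _compartment_mask(labels, int(cid), compartment) & joint_valid
        if mask.sum() < min_valid_pixels:
            dropped += 1
            continue
        row = {"cell_id": int(cid), "compartment": compartment, "batch": batch}
        if group is not None:
            row["group"] = group
        for name in FEATURE_NAMES:
            row[name] = float(np.nanmean(maps[name][mask]))
        rows.append(row)
    if dropped:
        logger.info("aggregate_cell_features: dropped %d cells with <%d valid "
                    "pixels", dropped, min_valid_pixels)
    return pd.DataFrame(rows)


def normalize_by_control(features: pd.DataFrame, control_group: str,
                         group_col: str = "group", batch_col: str = "batch",
                         feature_names=FEATURE_NAMES) -> pd.DataFrame:
    """Divide every feature by the control-group mean, per batch.

    Raises if a batch lacks control cells or a control mean is zero.
    """
    if batch_col not in features.columns:
        features = features.assign(**{batch_col: "all"})
    out = features.copy()
    for batch, sub in features.groupby(batch_col):
        ctrl = sub[sub[group_col] == control_group]
        if ctrl.empty:
            raise ValueError(f"batch {batch!r} has no {control_group!r} cells")
        means = ctrl[list(feature_names)].mean()
        if (means == 0).any():
            bad = means.index[means == 0].tolist()
            raise ValueError(f"zero control mean for features {bad}")
        idx = sub.index
        out.loc[idx, list(feature_names)] = (
            sub[list(feature_names)] / means).to_numpy()
    return out
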