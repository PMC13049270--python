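"""Voxelwise pipeline: control/label series → ΔS, ΔZ and TCF maps.

Inputs are assumed pre-aligned on a shared voxel grid (registration and
motion correction are upstream); any grid mismatch is an error, never a
silent resample.  ΔZ = (mean control − mean label)/mean control is only
meaningful where CSF dominates the signal — outside CSF the long-TE
readout leaves almost no control signal and the ratio explodes — so ΔZ
and TCF are defined only inside the CSF ∪ PVS mask and above a low-signal
guard; undefined voxels carry NaN, never zero.

Masks only gate where quantities are defined and aggregated; they never
alter stored intensities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .signal_model import MISLModelParams, tcf_from_delta_z

__all__ = [
    "VolumeSeries",
    "MaskSet",
    "ExchangeMaps",
    "QCError",
    "compute_delta_s",
    "compute_delta_z",
    "compute_tcf_map",
    "make_csf_mask",
    "make_pvs_mask",
    "dilate_and_intersect_rois",
    "roi_statistics",
    "estimate_background_noise",
]

logger = logging.getLogger(__name__)

#: ΔZ low-signal guard: mean control must exceed this multiple of the
#: background noise estimate.
LOW_SIGNAL_GUARD_FACTOR = 5.0

#: Connected components larger than this (voxels) are treated as
#: ventricle/SAS sheets rather than PVS tubes (default for 1 mm³ voxels).
DEFAULT_MAX_PVS_COMPONENT = 300


class QCError(RuntimeError):
    """Raised when a quality-control check fails (e.g. an empty CSF mask)."""


def _check_same_grid(*shapes) -> None:
    first = shapes[0]
    for s in shapes[1:]:
        if s != first:
            raise ValueError(f"grid mismatch: {first} vs {s}")


@dataclass
class VolumeSeries:
    """Repeated control/label 3-D volumes on one voxel grid.

    control / label are (n_repeats, x, y, z) stacks; the affine carries
    NIfTI world orientation untouched through the pipeline.
    """

    control: np.ndarray
    label: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.label = np.asarray(self.label, dtype=float)
        if self.control.ndim == 3:
            self.control = self.control[None]
        if self.label.ndim == 3:
            self.label = self.label[None]
        if self.control.ndim != 4 or self.label.ndim != 4:
            raise ValueError("control and label must be 3-D or 4-D (reps first) arrays")
        if self.control.shape[0] != self.label.shape[0]:
            raise ValueError(
                f"unequal repeat counts: {self.control.shape[0]} control vs "
                f"{self.label.shape[0]} label"
            )
        _check_same_grid(self.control.shape[1:], self.label.shape[1:])
        if np.any(self.control < 0) or np.any(self.label < 0):
            raise ValueError("magnitude intensities must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_pairs(self) -> int:
        return self.control.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.control.shape[1:])


@dataclass
class MaskSet:
    """Boolean masks and an integer ROI label map on the series grid."""

    brain_mask: np.ndarray
    csf_mask: np.ndarray
    pvs_mask: np.ndarray | None = None
    roi_labels: np.ndarray | None = None
    roi_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.csf_mask = np.asarray(self.csf_mask, dtype=bool)
        _check_same_grid(self.brain_mask.shape, self.csf_mask.shape)
        if np.any(self.csf_mask & ~self.brain_mask):
            raise ValueError("csf_mask must be a subset of brain_mask")
        if self.pvs_mask is not None:
            self.pvs_mask = np.asarray(self.pvs_mask, dtype=bool)
            _check_same_grid(self.brain_mask.shape, self.pvs_mask.shape)
        if self.roi_labels is not None:
            self.roi_labels = np.asarray(self.roi_labels)
            _check_same_grid(self.brain_mask.shape, self.roi_labels.shape)

    @property
    def defined_mask(self) -> np.ndarray:
        """Where ΔZ/TCF may be defined: CSF plus PVS."""
        if self.pvs_mask is None:
            return self.csf_mask
        return self.csf_mask | self.pvs_mask


@dataclass
class ExchangeMaps:
    """ΔS/ΔZ/TCF volumes plus per-voxel QC flags."""

    delta_s: np.ndarray
    delta_z: np.ndarray
    tcf: np.ndarray
    mean_control: np.ndarray
    low_signal: np.ndarray
    negative: np.ndarray


def compute_delta_s(series: VolumeSeries) -> tuple[np.ndarray, np.ndarray]:
    """ΔS = mean(control) − mean(label) voxelwise; also returns mean control."""
    mean_control = series.control.mean(axis=0)
    mean_label = series.label.mean(axis=0)
    return mean_control - mean_label, mean_control


def estimate_background_noise(volume: np.ndarray, brain_mask: np.ndarray) -> float:
    """Robust background noise level: scaled MAD of intensities outside brain.

    Returns 0.0 when there is no background (all-brain grid), which
    disables the low-signal guard — appropriate for noise-free synthetic
    data.
    """
    bg = np.asarray(volume)[~np.asarray(brain_mask, dtype=bool)]
    if bg.size == 0:
        return 0.0
    med = np.median(bg)
    return float(1.4826 * np.median(np.abs(bg - med)))


def compute_delta_z(
    delta_s: np.ndarray,
    mean_control: np.ndarray,
    masks: MaskSet,
    noise_level: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔZ = ΔS / mean control, defined only inside the CSF ∪ PVS mask.

    Voxels whose mean control falls below LOW_SIGNAL_GUARD_FACTOR × the
    background noise estimate are flagged low-signal and left NaN.
    Returns (delta_z, low_signal_flags).
    """
    _check_same_grid(delta_s.shape, mean_control.shape, masks.brain_mask.shape)
    if noise_level is None:
        noise_level = estimate_background_noise(mean_control, masks.brain_mask)
    guard = LOW_SIGNAL_GUARD_FACTOR * noise_level
    defined = masks.defined_mask & (mean_control > guard)
    low_signal = masks.defined_mask & ~(mean_control > guard)
    delta_z = np.full(delta_s.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_z[defined] = delta_s[defined] / mean_control[defined]
    return delta_z, low_signal


def compute_tcf_map(
    delta_z: np.ndarray, params: MISLModelParams, t_sat_s: float
) -> np.ndarray:
    """Elementwise ΔZ → TCF inversion; NaN propagates through undefined voxels."""
    return tcf_from_delta_z(params, np.asarray(delta_z, dtype=float), t_sat_s)


def make_csf_mask(
    mean_control: np.ndarray,
    brain_mask: np.ndarray,
    threshold: float | str = "otsu",
) -> np.ndarray:
    """Threshold the mean control image to isolate CSF.

    On long-TE images the brain-masked intensity histogram is bimodal
    (bright CSF vs. strongly suppressed parenchyma), so Otsu's rule is a
    reproducible default; an absolute cutoff may be passed instead.
    An empty result is a QC error.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    _check_same_grid(mean_control.shape, brain_mask.shape)
    if threshold == "otsu":
        vals = mean_control[brain_mask]
        if vals.size == 0:
            raise QCError("brain mask is empty; cannot determine a CSF threshold")
        cutoff = float(threshold_otsu(vals))
    else:
        cutoff = float(threshold)
    mask = (mean_control > cutoff) & brain_mask
    if not mask.any():
        raise QCError(f"CSF mask is empty at threshold {cutoff:g}")
    coverage = mask.sum() / brain_mask.sum()
    logger.info("CSF mask: cutoff=%.4g, coverage %.2f%% of brain", cutoff, 100 * coverage)
    return mask


def make_pvs_mask(
    long_te_t2w: np.ndarray,
    brain_mask: np.ndarray,
    intensity_threshold: float | str = "otsu",
    max_component_size: int = DEFAULT_MAX_PVS_COMPONENT,
    connectivity: int = 3,
) -> np.ndarray:
    """Segment perivascular spaces on a long-TE T2-weighted volume.

    Bright (fluid) voxels inside the brain are thresholded, connected
    components are labeled (connectivity 1..3 = 6/18/26-neighborhood, 26
    by default), and components larger than `max_component_size` voxels —
    ventricles and SAS sheets — are removed.  What remains (small tubes)
    is classified as PVS.  An empty result is allowed with a warning.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    _check_same_grid(long_te_t2w.shape, brain_mask.shape)
    if intensity_threshold == "otsu":
        vals = long_te_t2w[brain_mask]
        if vals.size == 0:
            raise QCError("brain mask is empty; cannot threshold for PVS")
        cutoff = float(threshold_otsu(vals))
    else:
        cutoff = float(intensity_threshold)
    bright = (long_te_t2w > cutoff) & brain_mask
    if not bright.any():
        warnings.warn("no suprathreshold voxels; PVS mask is empty", stacklevel=2)
        return np.zeros_like(brain_mask)
    labels, n = cc_label(bright, connectivity=connectivity, return_num=True)
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] <= max_component_size
    pvs = keep[labels]
    if not pvs.any():
        warnings.warn(
            "all bright components exceed max_component_size; PVS mask is empty",
            stacklevel=2,
        )
    return pvs


def dilate_and_intersect_rois(
    roi_labels: np.ndarray,
    csf_mask: np.ndarray,
    dilation_radius: int = 1,
) -> np.ndarray:
    """Dilate each atlas ROI and keep only voxels inside the CSF mask.

    Atlas ROIs sit in parenchyma; the CSF that exchanges with them is the
    adjacent rim, so each label is grown by a Euclidean ball of
    `dilation_radius` voxels before intersection.  Where the dilations of
    several ROIs overlap, the voxel goes to the nearest original label;
    exact distance ties break deterministically to the lower label id.
    """
    roi_labels = np.asarray(roi_labels)
    csf_mask = np.asarray(csf_mask, dtype=bool)
    _check_same_grid(roi_labels.shape, csf_mask.shape)
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    if dilation_radius == 0:
        return np.where(csf_mask, roi_labels, 0)
    ids = [int(i) for i in np.unique(roi_labels) if i != 0]
    best_dist = np.full(roi_labels.shape, np.inf)
    out = np.zeros_like(roi_labels)
    for roi_id in ids:  # ascending order ⇒ ties keep the lower id
        dist = ndimage.distance_transform_edt(roi_labels != roi_id)
        closer = dist < best_dist
        out[closer] = roi_id
        best_dist = np.where(closer, dist, best_dist)
    out[best_dist > dilation_radius] = 0
    return np.where(csf_mask, out, 0)


def roi_statistics(
    maps: ExchangeMaps,
    masks: MaskSet,
    composite_spec: dict[str, list[int]] | None = None,
    subject: str = "",
    session: int = 1,
) -> pd.DataFrame:
    """Per-ROI and per-composite ΔZ/TCF summaries.

    Means/SDs are taken over voxels where ΔZ is defined (not NaN, not
    flagged low-signal); an ROI with no valid voxels is reported with
    n_voxels = 0 and NaN statistics, never as zero.  Composite rows
    (roi_id = −1) aggregate the voxels of their member ROIs, so a
    composite mean is the voxel-count-weighted mean of its parts.
    """
    if masks.roi_labels is None:
        raise ValueError("masks.roi_labels is required for ROI statistics")
    valid = np.isfinite(maps.delta_z)
    rows = []

    def _row(roi_id, name, composite, sel):
        sel = sel & valid
        n = int(sel.sum())
        if n == 0:
            dz_m = dz_s = tcf_m = tcf_s = np.nan
        else:
            dz = maps.delta_z[sel]
            tc = maps.tcf[sel]
            dz_m, dz_s = float(dz.mean()), float(dz.std(ddof=1)) if n > 1 else 0.0
            tcf_m, tcf_s = float(tc.mean()), float(tc.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            dict(
                subject=subject,
                session=session,
                roi_id=roi_id,
                roi_name=name,
                composite=composite,
                n_voxels=n,
                mean_dz=dz_m,
                sd_dz=dz_s,
                mean_tcf=tcf_m,
                sd_tcf=tcf_s,
            )
        )

    id_to_composite = {}
    if composite_spec:
        for comp_name, members in composite_spec.items():
            for rid in members:
                id_to_composite[rid] = comp_name
    ids = [int(i) for i in np.unique(masks.roi_labels) if i != 0]
    for rid in ids:
        name = masks.roi_names.get(rid, f"roi_{rid}")
        _row(rid, name, id_to_composite.get(rid, ""), masks.roi_labels == rid)
    if composite_spec:
        for comp_name, members in composite_spec.items():
            sel = np.isin(masks.roi_labels, members)
            _row(-1, comp_name, comp_name, sel)
    return pd.DataFrame(rows)


def quantify_series(
    series: VolumeSeries,
    masks: MaskSet,
    params: MISLModelParams,
    t_sat_s: float,
    noise_level: float | None = None,
) -> ExchangeMaps:
    """Full voxelwise pipeline: series → ΔS → ΔZ → TCF with QC flags."""
    delta_s, mean_control = compute_delta_s(series)
    delta_z, low_signal = compute_delta_z(delta_s, mean_control, masks, noise_level)
    tcf = compute_tcf_map(delta_z, params, t_sat_s)
    negative = np.isfinite(delta_z) & (delta_z < 0)
    if negative.any():
        logger.info("%d voxels with negative ΔZ retained and flagged", int(negative.sum()))
    return ExchangeMaps(
        delta_s=delta_s,
        delta_z=delta_z,
        tcf=tcf,
        mean_control=mean_control,
        low_signal=low_signal,
        negative=negative,
    )
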