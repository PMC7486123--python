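"""Image stage: segmentation, round-to-round FFT registration, CPA quantification.

Chromogenic in-situ images are blurred, thresholded and watershed-split;
DAPI max projections are thresholded, watershed-split, area-filtered and
dilated by 5 um to encompass the soma; Slc17a7 somata are blurred and
thresholded without watershed (the punctate signal over-fragments
otherwise). Multi-round stacks are aligned by integer-pixel phase
correlation of DAPI projections, and per-cell expression is quantified as
counts-per-area (CPA): the fraction of an ROI's pixels above the probe's
signal threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.registration import phase_cross_correlation
from skimage.segmentation import expand_labels, watershed

logger = logging.getLogger(__name__)


@dataclass
class ROISet:
    """Segmented regions of interest over one field of view.

    ``label_image`` holds 0 for background and 1..n for ROIs; ``table`` has
    one row per ROI: roi_id, x_um, y_um (centroid), area_um2.
    """

    label_image: np.ndarray
    pixel_size_um: float
    table: pd.DataFrame

    @property
    def n_rois(self) -> int:
        return len(self.table)

    def mask(self, roi_id: int) -> np.ndarray:
        return self.label_image == roi_id


def _binarize(img: np.ndarray, threshold: float | None) -> tuple[np.ndarray, float]:
    if threshold is None:
        threshold = float(threshold_otsu(img))
        logger.info("automatic (Otsu) threshold %.4g used; record in provenance", threshold)
    if threshold >= img.max():
        logger.warning("threshold %.4g at/above image maximum; no signal segmented", threshold)
        return np.zeros(img.shape, dtype=bool), threshold
    return img > threshold, threshold


def _watershed_split(binary: np.ndarray, min_distance_px: int) -> np.ndarray:
    """Split touching objects with a distance-transform watershed."""
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=min_distance_px, labels=binary, exclude_border=False)
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        return ndi.label(binary)[0]
    return watershed(-dist, markers, mask=binary)


def _labels_to_roiset(
    labels: np.ndarray,
    pixel_size_um: float,
    area_min_um2: float,
    area_max_um2: float,
) -> ROISet:
    """Area-filter labelled components (inclusive bounds) into an ROISet."""
    px_area = pixel_size_um**2
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros(labels.shape, dtype=np.int32)
    rows = []
    next_id = 1
    for i in ids:
        mask = labels == i
        area = mask.sum() * px_area
        if area < area_min_um2 or area > area_max_um2:
            continue
        cy, cx = ndi.center_of_mass(mask)
        out[mask] = next_id
        rows.append((next_id, cx * pixel_size_um, cy * pixel_size_um, area))
        next_id += 1
    table = pd.DataFrame(rows, columns=["roi_id", "x_um", "y_um", "area_um2"])
    return ROISet(label_image=out, pixel_size_um=pixel_size_um, table=table)


def segment_chromogenic(
    img: np.ndarray,
    pixel_size_um: float = 1.0,
    sigma_px: float = 1.0,
    threshold: float | None = None,
    area_min_um2: float = 100.0,
    area_max_um2: float = 400.0,
    min_distance_px: int = 5,
) -> ROISet:
    """Blur, binarise, watershed-split, and area-filter chromogenic signal.

    Cells with area in [100, 400] um^2 (inclusive) are retained.
    """
    if img.ndim != 2:
        raise ValueError("segment_chromogenic expects a 2-D image")
    sm = gaussian(img.astype(float), sigma=sigma_px, preserve_range=True)
    binary, _ = _binarize(sm, threshold)
    labels = _watershed_split(binary, min_distance_px)
    return _labels_to_roiset(labels, pixel_size_um, area_min_um2, area_max_um2)


def segment_nuclei(
    dapi_max_projection: np.ndarray,
    pixel_size_um: float = 1.0,
    threshold: float | None = None,
    area_min_um2: float = 40.0,
    area_max_um2: float = 200.0,
    dilation_um: float = 5.0,
    min_distance_px: int = 4,
) -> ROISet:
    """Threshold + watershed DAPI nuclei, filter 40-200 um^2, dilate 5 um.

    ROIs under 40 um^2 (partial cells) or over 200 um^2 (abutting cells) are
    discarded before dilation; the dilation grows surviving ROIs without
    letting neighbours overlap, and areas are re-reported post-dilation.
    """
    if dapi_max_projection.ndim != 2:
        raise ValueError("segment_nuclei expects a 2-D max projection")
    binary, _ = _binarize(dapi_max_projection.astype(float), threshold)
    labels = _watershed_split(binary, min_distance_px)
    rois = _labels_to_roiset(labels, pixel_size_um, area_min_um2, area_max_um2)
    if dilation_um > 0 and rois.n_rois:
        grown = expand_labels(rois.label_image, distance=dilation_um / pixel_size_um)
        px_area = pixel_size_um**2
        rows = []
        for roi_id in rois.table["roi_id"]:
            mask = grown == roi_id
            cy, cx = ndi.center_of_mass(mask)
            rows.append((roi_id, cx * pixel_size_um, cy * pixel_size_um, mask.sum() * px_area))
        rois = ROISet(
            label_image=grown,
            pixel_size_um=pixel_size_um,
            table=pd.DataFrame(rows, columns=["roi_id", "x_um", "y_um", "area_um2"]),
        )
    return rois


def segment_slc17a7(
    img: np.ndarray,
    pixel_size_um: float = 1.0,
    sigma_px: float = 2.0,
    threshold: float | None = None,
    area_min_um2: float = 75.0,
    area_max_um2: float = 450.0,
) -> ROISet:
    """Blur + threshold Slc17a7 somata; connected components, no watershed.

    The punctate in-situ signal makes watershed splitting unreliable, so
    touching somata merge; areas in [75, 450] um^2 (inclusive) are kept.
    """
    if img.ndim != 2:
        raise ValueError("segment_slc17a7 expects a 2-D image")
    sm = gaussian(img.astype(float), sigma=sigma_px, preserve_range=True)
    binary, _ = _binarize(sm, threshold)
    labels = ndi.label(binary)[0]
    return _labels_to_roiset(labels, pixel_size_um, area_min_um2, area_max_um2)


def register_rounds(ref_dapi: np.ndarray, mov_dapi: np.ndarray) -> tuple[int, int, int]:
    """Integer (dx, dy, dz) displacement of a moving round relative to the reference.

    XY comes from phase correlation of the z-max projections; Z from phase
    correlation of the central y-slice (a z-x plane) of each stack. The
    returned offsets are the shift the moving round has undergone;
    :func:`apply_offset` applies the inverse to the round's DAPI and probe
    channels to bring them back onto the reference frame.
    """
    if ref_dapi.shape != mov_dapi.shape:
        raise ValueError("stacks must share a shape")
    if ref_dapi.ndim != 3:
        raise ValueError("register_rounds expects 3-D (z, y, x) stacks")
    for name, stk in (("reference", ref_dapi), ("moving", mov_dapi)):
        if np.ptp(stk) == 0:
            raise ValueError(f"{name} stack has zero variance; registration undefined")
    ref_xy = ref_dapi.max(axis=0)
    mov_xy = mov_dapi.max(axis=0)
    shift_xy, _, _ = phase_cross_correlation(ref_xy, mov_xy, upsample_factor=1)
    # phase correlation yields the alignment shift; displacement is its negative
    ady, adx = (int(round(v)) for v in shift_xy)
    # correlate a z-x slice through the strongest DAPI row for the z offset
    ybest = int(np.argmax(ref_dapi.sum(axis=(0, 2))))
    ref_zx = ref_dapi[:, ybest, :]
    mov_zx = np.roll(mov_dapi, (ady, adx), axis=(1, 2))[:, ybest, :]
    if np.ptp(ref_zx) == 0 or np.ptp(mov_zx) == 0:
        adz = 0
    else:
        shift_zx, _, _ = phase_cross_correlation(ref_zx, mov_zx, upsample_factor=1)
        adz = int(round(shift_zx[0]))
    return -adx, -ady, -adz


def apply_offset(stack: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Undo an integer (dx, dy, dz) displacement on a stack (wrap-around)."""
    dx, dy, dz = offset
    return np.roll(stack, (-dz, -dy, -dx), axis=(0, 1, 2))


def quantify_cpa(
    rois: ROISet,
    probe_img: np.ndarray,
    threshold: float,
    smooth_sigma_px: float | None = None,
) -> pd.Series:
    """Counts-per-area of one probe: positive pixels in each ROI / ROI area.

    ``smooth_sigma_px`` applies the pre-threshold smoothing used for the
    noisy far-red (750 nm) channels. The probe image must already be
    registered onto the ROI frame.
    """
    if probe_img.shape != rois.label_image.shape:
        raise ValueError("probe image shape does not match the ROI frame; register first")
    img = probe_img.astype(float)
    if smooth_sigma_px:
        img = gaussian(img, sigma=smooth_sigma_px, preserve_range=True)
    positive = img > threshold
    labels = rois.label_image
    ids = rois.table["roi_id"].to_numpy()
    pos_counts = ndi.sum_labels(positive.astype(float), labels, index=ids)
    tot_counts = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, index=ids)
    cpa = pos_counts / tot_counts
    return pd.Series(cpa, index=pd.Index(ids, name="roi_id"), name="cpa")


def quantify_panel(
    rois: ROISet,
    probes: dict[str, tuple[np.ndarray, float, float | None]],
) -> pd.DataFrame:
    """CPA table over a probe panel: {gene: (image, threshold, smooth_sigma)}."""
    cols = {g: quantify_cpa(rois, img, thr, sm) for g, (img, thr, sm) in probes.items()}
    table = rois.table.set_index("roi_id")[["x_um", "y_um", "area_um2"]].copy()
    for g, s in cols.items():
        table[g] = s
    return table.reset_index()
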