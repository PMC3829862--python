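"""Nucleus detection, single-cell region assignment and edge-cell exclusion.

Segmentation runs on the first timepoint only and is reused across frames
(cells are assumed static over the ~23 s protocol): nuclei are detected on
the far-red nuclear channel, cell regions are grown from each nucleus on the
summed FRET channels, and cells touching the frame border are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .stacks import TimeLapseStack

__all__ = [
    "CellSegmentation",
    "segment_nuclei",
    "assign_cell_regions",
    "exclude_edge_cells",
    "segment_field",
]


@dataclass
class CellSegmentation:
    """Labeled nuclei and cell regions for one field.

    Cell and nucleus label images share label values; ``cell_to_nucleus``
    records the (identity at default settings) mapping, ``edge_flags`` marks
    cells whose region touches the frame border.
    """

    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    cell_to_nucleus: dict
    edge_flags: dict
    fg_mask: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_to_nucleus)

    @property
    def cell_ids(self) -> list:
        return sorted(self.cell_to_nucleus)

    def mask(self, cell_id: int) -> np.ndarray:
        return self.cell_labels == cell_id

    @property
    def foreground(self) -> np.ndarray:
        """Union of all detected cell regions, including any later excluded
        as edge cells — background estimates must omit their pixels too."""
        return self.fg_mask if self.fg_mask is not None else self.cell_labels > 0

    def to_frame(self, well_id: str = ""):
        """Per-cell table: centroid (0-based row/col), area, edge flag."""
        import pandas as pd

        rows = []
        for cid in self.cell_ids:
            mask = self.cell_labels == cid
            com = ndi.center_of_mass(mask)
            rows.append(
                {
                    "cell_id": cid,
                    "well_id": well_id,
                    "centroid_y": float(com[0]),
                    "centroid_x": float(com[1]),
                    "area_px": int(mask.sum()),
                    "edge_flag": bool(self.edge_flags.get(cid, False)),
                }
            )
        return pd.DataFrame(rows)


def _border_labels(labels: np.ndarray) -> set:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return set(np.unique(edge[edge > 0]).tolist())


def segment_nuclei(
    nuclear_frame: np.ndarray,
    min_area_px: int = 20,
    smoothing_scale: float = 2.0,
    threshold_policy="otsu",
    min_peak_separation: int = 5,
) -> np.ndarray:
    """Detect nuclei on a single nuclear-channel frame.

    Smooth, threshold (Otsu by default, or a fixed value), drop specks below
    ``min_area_px``, then split touching nuclei by watershed seeded at
    distance-transform maxima at least ``min_peak_separation`` px apart
    (default: one nucleus radius).
    """
    img = np.asarray(nuclear_frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclear frame must be 2-D")
    if np.any(img < 0):
        raise ValueError("nuclear frame must be non-negative")
    smoothed = gaussian(img, sigma=smoothing_scale, preserve_range=True)
    if smoothed.max() == smoothed.min():
        return np.zeros(img.shape, dtype=np.int32)
    if threshold_policy == "otsu":
        thr = threshold_otsu(smoothed)
    else:
        thr = float(threshold_policy)
    mask = smoothed > thr
    mask = remove_small_objects(mask, max_size=min_area_px - 1)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=min_peak_separation,
        labels=cc_label(mask),
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask).astype(np.int32)
    # watershed can orphan tiny slivers; re-apply the area floor
    for lab, area in zip(*np.unique(labels[labels > 0], return_counts=True)):
        if area < min_area_px:
            labels[labels == lab] = 0
    return labels


def assign_cell_regions(
    nuclei_labels: np.ndarray,
    reference_frame: np.ndarray,
    max_radius_px: float = 15.0,
) -> tuple:
    """Grow one cell region per nucleus on the reference FRET intensity.

    Nucleus-seeded watershed on the (smoothed, inverted) reference image,
    restricted to foreground pixels within ``max_radius_px`` of any nucleus;
    contested pixels between adjacent cells go to exactly one region.
    Returns ``(cell_labels, cell_to_nucleus)``.
    """
    nuclei = np.asarray(nuclei_labels)
    ref = np.asarray(reference_frame, dtype=float)
    if nuclei.shape != ref.shape:
        raise ValueError("nuclei labels and reference frame shapes differ")
    if nuclei.max() == 0:
        return np.zeros_like(nuclei, dtype=np.int32), {}

    smoothed = gaussian(ref, sigma=1.0, preserve_range=True)
    if smoothed.max() > smoothed.min():
        fg = smoothed > threshold_otsu(smoothed)
    else:
        fg = np.ones_like(nuclei, dtype=bool)
    fg |= nuclei > 0
    within_reach = ndi.distance_transform_edt(nuclei == 0) <= max_radius_px
    cell_labels = watershed(
        -smoothed, markers=nuclei, mask=fg & within_reach
    ).astype(np.int32)
    mapping = {int(lab): int(lab) for lab in np.unique(nuclei) if lab > 0}
    return cell_labels, mapping


def exclude_edge_cells(seg: CellSegmentation) -> CellSegmentation:
    """Remove every cell whose *region* (not just nucleus) touches the frame
    border; the strict reading of edge exclusion."""
    on_edge = _border_labels(seg.cell_labels)
    cell_labels = np.where(
        np.isin(seg.cell_labels, list(on_edge)), 0, seg.cell_labels
    ).astype(np.int32)
    nuclei_labels = np.where(
        np.isin(seg.nuclei_labels, list(on_edge)), 0, seg.nuclei_labels
    ).astype(np.int32)
    kept = {c: n for c, n in seg.cell_to_nucleus.items() if c not in on_edge}
    return CellSegmentation(
        nuclei_labels=nuclei_labels,
        cell_labels=cell_labels,
        cell_to_nucleus=kept,
        edge_flags={c: False for c in kept},
        fg_mask=seg.foreground,
    )


def segment_field(
    stack: TimeLapseStack,
    min_area_px: int = 20,
    smoothing_scale: float = 2.0,
    threshold_policy="otsu",
    max_radius_px: float = 15.0,
    drop_edge_cells: bool = True,
) -> CellSegmentation:
    """Full segmentation of one well from its first timepoint.

    Nuclei come from the nuclear channel; the cell-assignment reference is
    the donor + acceptor sum at t=0 (total sensor fluorescence).
    """
    nuclear = stack.channel("nuclear")[0]
    reference = stack.channel("donor")[0] + stack.channel("acceptor")[0]
    nuclei = segment_nuclei(
        nuclear,
        min_area_px=min_area_px,
        smoothing_scale=smoothing_scale,
        threshold_policy=threshold_policy,
    )
    cells, mapping = assign_cell_regions(nuclei, reference, max_radius_px)
    edge = _border_labels(cells)
    seg = CellSegmentation(
        nuclei_labels=nuclei,
        cell_labels=cells,
        cell_to_nucleus=mapping,
        edge_flags={c: c in edge for c in mapping},
    )
    return exclude_edge_cells(seg) if drop_edge_cells else seg


def match_detections(
    detected_labels: np.ndarray, true_centers, match_radius: float
) -> tuple:
    """Greedy one-to-one matching of detected objects to planted centers.

    Returns ``(recall, precision)``: a detection matches a planted center if
    its centroid lies within ``match_radius`` pixels.
    """
    ids = np.unique(detected_labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return 0.0, 0.0
    centroids = np.array(
        ndi.center_of_mass(detected_labels > 0, detected_labels, ids)
    )
    true_centers = np.asarray(true_centers, dtype=float)
    if len(true_centers) == 0:
        return 0.0, 0.0
    d = np.linalg.norm(
        centroids[:, None, :] - true_centers[None, :, :], axis=-1
    )
    matched_true: set = set()
    matched_det: set = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for di, ti in order:
        if d[di, ti] > match_radius:
            break
        if di in matched_det or ti in matched_true:
            continue
        matched_det.add(int(di))
        matched_true.add(int(ti))
    n_match = len(matched_det)
    return n_match / len(true_centers), n_match / len(ids)
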