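"""Single-cell FRET-ratio transients, ΔF/F0 normalization and well summaries.

For every segmented cell the donor and acceptor channels are averaged inside
the cell mask and background-corrected per frame; the acceptor/donor ratio is
normalized to the pre-dispense baseline, ΔF/F0 = (F − F0)/F0 with F0 the mean
ratio over the frames preceding agonist application. The peak ΔF/F0 after the
dispense is the single-cell readout; the well readout is the mean peak over
responsive cells (peak ≥ threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmentation import CellSegmentation
from .stacks import Timebase, TimeLapseStack

__all__ = [
    "CalciumTrace",
    "WellResult",
    "extract_trace",
    "extract_well_traces",
    "normalize_trace",
    "peak_amplitude",
    "classify_responsive",
    "summarize_well",
    "threshold_for_target_fraction",
    "analyze_well",
]

#: Default responsiveness threshold on peak ΔF/F0: small relative to evoked
#: peaks in the mutant line, above the photometric noise floor.
DEFAULT_RESPONSIVE_THRESHOLD = 0.1
#: Minimum responsive cells for a well readout to count as valid.
DEFAULT_MIN_RESPONSIVE_CELLS = 20


@dataclass
class CalciumTrace:
    """Per-cell transient: raw channel means, ratio kinetics and ΔF/F0."""

    cell_id: int
    donor: np.ndarray
    acceptor: np.ndarray
    ratio: np.ndarray
    valid: bool = True
    f0: float | None = None
    dff: np.ndarray | None = None
    peak: float | None = None
    responsive: bool | None = None

    @property
    def baseline_donor(self) -> float:
        """Pre-normalization mean donor intensity (first frame)."""
        return float(self.donor[0])

    @property
    def baseline_acceptor(self) -> float:
        return float(self.acceptor[0])


@dataclass
class WellResult:
    """Per-well summary; ``mean_peak_responsive`` is the screening readout."""

    well_id: str
    n_cells: int
    n_responsive: int
    responsive_fraction: float
    mean_peak_responsive: float
    sd_peak_responsive: float
    valid: bool
    baseline_donor_mean: float = float("nan")
    baseline_acceptor_mean: float = float("nan")


def extract_trace(
    stack: TimeLapseStack,
    cell_mask: np.ndarray,
    cell_id: int = 0,
    background_policy: str = "mean_outside",
    foreground_mask: np.ndarray | None = None,
) -> CalciumTrace:
    """Mean background-corrected donor/acceptor intensities in one cell mask.

    ``background_policy``: ``"mean_outside"`` subtracts, per frame and
    channel, the mean intensity over pixels outside ``foreground_mask`` (the
    union of all cell regions; defaults to this cell's mask); ``"none"``
    skips correction. A trace whose corrected donor drops to ≤ 0 in any
    frame is flagged invalid.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    donor_frames = stack.channel("donor")
    acceptor_frames = stack.channel("acceptor")
    donor = donor_frames[:, cell_mask].mean(axis=1)
    acceptor = acceptor_frames[:, cell_mask].mean(axis=1)

    if background_policy == "mean_outside":
        fg = cell_mask if foreground_mask is None else np.asarray(foreground_mask, bool)
        bg = ~fg
        if not bg.any():
            raise ValueError("no background pixels available for correction")
        donor = donor - donor_frames[:, bg].mean(axis=1)
        acceptor = acceptor - acceptor_frames[:, bg].mean(axis=1)
    elif background_policy != "none":
        raise ValueError(f"unknown background policy {background_policy!r}")

    valid = bool(np.all(donor > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(donor > 0, acceptor / donor, np.nan)
    return CalciumTrace(
        cell_id=cell_id, donor=donor, acceptor=acceptor, ratio=ratio, valid=valid
    )


def extract_well_traces(
    stack: TimeLapseStack,
    seg: CellSegmentation,
    background_policy: str = "mean_outside",
) -> list:
    """Traces for every segmented cell, sharing one background estimate
    (mean over all non-cell pixels per frame).

    Equivalent to :func:`extract_trace` per cell but computed in one pass
    per frame over the label image.
    """
    ids = seg.cell_ids
    if not ids:
        return []
    labels = seg.cell_labels
    fg = seg.foreground
    bg = ~fg
    if background_policy == "mean_outside" and not bg.any():
        raise ValueError("no background pixels available for correction")
    if background_policy not in ("mean_outside", "none"):
        raise ValueError(f"unknown background policy {background_policy!r}")
    donor_frames = stack.channel("donor")
    acceptor_frames = stack.channel("acceptor")
    n_frames = stack.timebase.n_frames
    donor = np.empty((len(ids), n_frames))
    acceptor = np.empty((len(ids), n_frames))
    for k in range(n_frames):
        donor[:, k] = ndi.mean(donor_frames[k], labels, ids)
        acceptor[:, k] = ndi.mean(acceptor_frames[k], labels, ids)
        if background_policy == "mean_outside":
            donor[:, k] -= donor_frames[k][bg].mean(dtype=np.float64)
            acceptor[:, k] -= acceptor_frames[k][bg].mean(dtype=np.float64)
    traces = []
    for i, cid in enumerate(ids):
        d, a = donor[i], acceptor[i]
        valid = bool(np.all(d > 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, a / d, np.nan)
        traces.append(
            CalciumTrace(cell_id=cid, donor=d, acceptor=a, ratio=ratio, valid=valid)
        )
    return traces


def normalize_trace(trace: CalciumTrace, tb: Timebase) -> CalciumTrace:
    """Fill in F0 (mean pre-dispense ratio) and ΔF/F0 = (F − F0)/F0."""
    if tb.n_pre < 1:
        raise ValueError("need at least one pre-dispense frame")
    if len(trace.ratio) != tb.n_frames:
        raise ValueError("trace length does not match timebase")
    if not trace.valid:
        return trace
    f0 = float(np.mean(trace.ratio[: tb.n_pre]))
    if not np.isfinite(f0) or f0 <= 0:
        trace.valid = False
        return trace
    trace.f0 = f0
    trace.dff = (trace.ratio - f0) / f0
    return trace


def peak_amplitude(trace: CalciumTrace, tb: Timebase) -> float:
    """Max ΔF/F0 at/after the dispense frame; pre-dispense excursions are
    outside the scoring window."""
    if trace.dff is None:
        raise ValueError("trace is not normalized; call normalize_trace first")
    return float(np.max(trace.dff[tb.dispense_index :]))


def classify_responsive(
    peak: float, threshold: float = DEFAULT_RESPONSIVE_THRESHOLD
) -> bool:
    """A cell responds iff its post-dispense peak ΔF/F0 reaches the
    threshold (inclusive boundary)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return bool(peak >= threshold)


def summarize_well(
    traces,
    tb: Timebase,
    well_id: str = "",
    threshold: float = DEFAULT_RESPONSIVE_THRESHOLD,
    min_responsive_cells: int = DEFAULT_MIN_RESPONSIVE_CELLS,
) -> WellResult:
    """Well readout: responsive fraction and mean peak over responsive cells.

    Invalid traces are dropped; a well with fewer than
    ``min_responsive_cells`` responsive cells is marked invalid (its mean is
    still reported when at least one responsive cell exists).
    """
    peaks = []
    baseline_d, baseline_a = [], []
    n_valid = 0
    for trace in traces:
        trace = normalize_trace(trace, tb) if trace.dff is None else trace
        if not trace.valid:
            continue
        n_valid += 1
        trace.peak = peak_amplitude(trace, tb)
        trace.responsive = classify_responsive(trace.peak, threshold)
        baseline_d.append(trace.baseline_donor)
        baseline_a.append(trace.baseline_acceptor)
        if trace.responsive:
            peaks.append(trace.peak)

    n_resp = len(peaks)
    if n_valid == 0:
        return WellResult(well_id, 0, 0, float("nan"), float("nan"), float("nan"), False)
    mean_peak = float(np.mean(peaks)) if n_resp else float("nan")
    sd_peak = float(np.std(peaks, ddof=1)) if n_resp > 1 else 0.0 if n_resp else float("nan")
    return WellResult(
        well_id=well_id,
        n_cells=n_valid,
        n_responsive=n_resp,
        responsive_fraction=n_resp / n_valid,
        mean_peak_responsive=mean_peak,
        sd_peak_responsive=sd_peak,
        valid=n_resp >= min_responsive_cells,
        baseline_donor_mean=float(np.mean(baseline_d)),
        baseline_acceptor_mean=float(np.mean(baseline_a)),
    )


def threshold_for_target_fraction(peaks, target_fraction: float) -> float:
    """Calibration helper: the peak-ΔF/F0 threshold at which a given
    fraction of the supplied cells would be called responsive."""
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target fraction must be in (0, 1)")
    peaks = np.sort(np.asarray(peaks, dtype=float))
    return float(np.quantile(peaks, 1.0 - target_fraction))


def analyze_well(
    stack: TimeLapseStack,
    seg: CellSegmentation,
    threshold: float = DEFAULT_RESPONSIVE_THRESHOLD,
    min_responsive_cells: int = DEFAULT_MIN_RESPONSIVE_CELLS,
    background_policy: str = "mean_outside",
) -> tuple:
    """Segment-to-summary convenience: returns ``(WellResult, traces)``."""
    traces = extract_well_traces(stack, seg, background_policy)
    tb = stack.timebase
    for t in traces:
        normalize_trace(t, tb)
    result = summarize_well(
        traces,
        tb,
        well_id=stack.well_id,
        threshold=threshold,
        min_responsive_cells=min_responsive_cells,
    )
    return result, traces


def traces_to_frame(traces, tb: Timebase, well_id: str = "") -> pd.DataFrame:
    """Long-format per-cell trace table."""
    rows = []
    for tr in traces:
        for k in range(len(tr.ratio)):
            rows.append(
                {
                    "well_id": well_id,
                    "cell_id": tr.cell_id,
                    "frame": k,
                    "t_s": float(tb.times[k]),
                    "donor": float(tr.donor[k]),
                    "acceptor": float(tr.acceptor[k]),
                    "ratio": float(tr.ratio[k]),
                    "dff": float(tr.dff[k]) if tr.dff is not None else float("nan"),
                }
            )
    return pd.DataFrame(rows)
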