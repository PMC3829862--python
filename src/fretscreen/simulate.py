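"""Ground-truthed synthetic screening plates.

Emulates the statistical structure of an agonist-evoked ER-calcium screen in
an HEK293 monolayer expressing a ratiometric FRET calcium sensor:

* fields of ~150-200 non-overlapping cells (nucleus disk inside a larger
  cytoplasm disk), each with a latent responder flag and evoked-amplitude
  scale;
* carbachol-like evoked calcium transients — flat baseline, fast rise at the
  dispense, exponential decay — whose amplitude carries the genotype
  fold-change (FAD-mutant vs wild-type presenilin) and per-well compound
  suppression;
* optical rendering through a saturating calcium→FRET-ratio map with
  Poisson-like photon noise and uniform per-channel background;
* full plate layouts with vehicle (DMSO), untreated and suppressor-control
  (TP/CPA/TMB-8) wells.

Every well retains its ground truth (cell masks, responder flags, planted
suppression) so downstream segmentation and scoring can be benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .layout import CONTROL_ROLES, PlateLayout
from .stacks import CHANNELS, Timebase, TimeLapseStack, default_timebase

__all__ = [
    "SensorMap",
    "SimParams",
    "CellGroundTruth",
    "WellSimulation",
    "PlateSimulation",
    "simulate_field",
    "calcium_series",
    "render_stack",
    "ground_truth_labels",
    "simulate_well",
    "simulate_plate",
    "simulate_control_wells",
    "expected_peak_dff",
    "expected_normalized_response",
    "suppression_for_normalized_response",
    "random_fingerprints",
]


@dataclass(frozen=True)
class SensorMap:
    """Monotone saturating map from calcium (arbitrary units) to the
    acceptor/donor emission ratio, R(c) = r_min + dynamic_range * c/(c + k_half).

    Defaults keep evoked peaks far below half-saturation so the measured
    ΔF/F0 stays near-linear in evoked amplitude across the simulated
    genotype range.
    """

    r_min: float = 1.0
    dynamic_range: float = 25.0
    k_half: float = 50.0

    def ratio(self, calcium):
        c = np.asarray(calcium, dtype=float)
        if np.any(c < 0):
            raise ValueError("calcium must be non-negative")
        return self.r_min + self.dynamic_range * c / (c + self.k_half)


@dataclass
class SimParams:
    """Generator parameters.

    Defaults describe the screened cell line: an FAD-mutant presenilin-1
    background in which ~96% of cells respond to carbachol and the evoked
    peak is 3-fold the wild-type amplitude. Use :meth:`wild_type` for the
    comparison line and :meth:`noiseless` for analytically exact wells.
    """

    genotype_amplitude: float = 3.0
    responder_fraction: float = 0.96
    n_cells: int = 175
    field_shape: tuple = (512, 512)
    baseline_calcium: float = 0.1
    peak_scale_sd: float = 0.15
    rise_tau: float = 0.8
    decay_tau: float = 6.0
    photon_noise_scale: float = 1.0
    background: dict = field(
        default_factory=lambda: {"nuclear": 80.0, "donor": 120.0, "acceptor": 120.0}
    )
    cell_brightness: float = 1500.0
    nuclear_intensity: float = 2000.0
    sensor_r_min: float = 1.0
    sensor_dynamic_range: float = 25.0
    sensor_k_half: float = 50.0
    nucleus_radius_mean: float = 5.0
    nucleus_radius_sd: float = 0.5
    cytoplasm_radius_mean: float = 12.0
    cytoplasm_radius_sd: float = 0.8
    min_center_distance: float = 26.0
    border_margin: float = 7.0
    control_suppression: float = 0.7
    compound_suppression: dict = field(default_factory=dict)
    autofluorescent_compounds: frozenset = frozenset()
    autofluorescence_boost: float = 0.5
    toxic_compounds: frozenset = frozenset()
    toxic_cell_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        for cid, s in self.compound_suppression.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"suppression for {cid!r} outside [0, 1]")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")

    @property
    def sensor(self) -> SensorMap:
        return SensorMap(
            self.sensor_r_min, self.sensor_dynamic_range, self.sensor_k_half
        )

    @classmethod
    def fad_mutant(cls, **overrides) -> "SimParams":
        return cls(**overrides)

    @classmethod
    def wild_type(cls, **overrides) -> "SimParams":
        overrides.setdefault("genotype_amplitude", 1.0)
        overrides.setdefault("responder_fraction", 0.29)
        return cls(**overrides)

    def noiseless(self) -> "SimParams":
        """Copy with photon noise and cell-to-cell amplitude spread removed."""
        return replace(self, photon_noise_scale=0.0, peak_scale_sd=0.0)


@dataclass
class CellGroundTruth:
    """Latent state of one simulated cell."""

    cell_id: int
    nucleus_center: tuple          # (row, col) pixels
    nucleus_radius: float
    cytoplasm_radius: float
    is_responder: bool
    peak_scale: float              # evoked-amplitude multiplier; 0 for non-responders
    baseline_calcium: float
    rise_tau: float
    decay_tau: float

    def __post_init__(self) -> None:
        if self.nucleus_radius <= 0 or self.cytoplasm_radius <= 0:
            raise ValueError("radii must be positive")
        if self.peak_scale < 0:
            raise ValueError("peak_scale must be non-negative")
        if not self.is_responder and self.peak_scale != 0:
            raise ValueError("non-responders must have peak_scale = 0")


def simulate_field(
    n_cells: int,
    field_shape: tuple,
    params: SimParams,
    rng,
    max_attempts_per_cell: int = 2000,
) -> list:
    """Place ``n_cells`` non-overlapping cells uniformly in a field.

    Centers keep ``params.min_center_distance`` from each other (dart
    throwing with bounded retries) and ``params.border_margin`` from the
    frame border, so nuclei never touch the frame edge but cytoplasms of
    border-adjacent cells may — exercising downstream edge exclusion.
    Responder flags are i.i.d. Bernoulli(``responder_fraction``).
    """
    rng = np.random.default_rng(rng)
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    h, w = field_shape
    m = params.border_margin
    if n_cells and (h - 2 * m <= 0 or w - 2 * m <= 0):
        raise ValueError("field too small for the requested margin")

    centers = np.empty((0, 2))
    attempts = 0
    budget = max(max_attempts_per_cell * max(n_cells, 1), 10_000)
    while len(centers) < n_cells:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n_cells} cells with minimum spacing "
                f"{params.min_center_distance} in a {h}x{w} field "
                f"after {attempts} attempts; reduce density"
            )
        attempts += 1
        cand = np.array(
            [rng.uniform(m, h - 1 - m), rng.uniform(m, w - 1 - m)]
        )
        if len(centers) and (
            np.min(np.hypot(*(centers - cand).T)) < params.min_center_distance
        ):
            continue
        centers = np.vstack([centers, cand])

    cells = []
    for i, (cy, cx) in enumerate(centers):
        nuc_r = float(
            np.clip(
                rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd),
                params.nucleus_radius_mean - 1.0,
                params.nucleus_radius_mean + 1.0,
            )
        )
        cyt_r = float(
            np.clip(
                rng.normal(
                    params.cytoplasm_radius_mean, params.cytoplasm_radius_sd
                ),
                params.cytoplasm_radius_mean - 2.0,
                params.cytoplasm_radius_mean + 1.0,
            )
        )
        responder = bool(rng.random() < params.responder_fraction)
        scale = (
            float(np.clip(rng.normal(1.0, params.peak_scale_sd), 0.3, 1.7))
            if responder
            else 0.0
        )
        cells.append(
            CellGroundTruth(
                cell_id=i + 1,
                nucleus_center=(float(cy), float(cx)),
                nucleus_radius=nuc_r,
                cytoplasm_radius=cyt_r,
                is_responder=responder,
                peak_scale=scale,
                baseline_calcium=params.baseline_calcium,
                rise_tau=params.rise_tau,
                decay_tau=params.decay_tau,
            )
        )
    return cells


def _transient_shape(tau: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak over
    continuous time; zero for tau <= 0."""
    if rise <= 0 or decay <= 0:
        raise ValueError("time constants must be positive")
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if rise >= decay:
        raise ValueError("rise_tau must be smaller than decay_tau")
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    norm = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    out[pos] = (np.exp(-tau[pos] / decay) - np.exp(-tau[pos] / rise)) / norm
    return out


def calcium_series(
    cell: CellGroundTruth,
    tb: Timebase,
    suppression: float = 0.0,
    genotype_amplitude: float = 1.0,
) -> np.ndarray:
    """Latent calcium at the frame times of ``tb``.

    Pre-dispense frames sit at the cell's baseline; responders add an evoked
    transient of amplitude ``peak_scale * genotype_amplitude *
    (1 - suppression)`` starting at the dispense moment.
    """
    if not 0.0 <= suppression <= 1.0:
        raise ValueError("suppression must be in [0, 1]")
    amplitude = cell.peak_scale * genotype_amplitude * (1.0 - suppression)
    series = np.full(tb.n_frames, cell.baseline_calcium, dtype=float)
    if cell.is_responder and amplitude > 0:
        tau = tb.times - tb.dispense_time
        series = series + amplitude * _transient_shape(
            tau, cell.rise_tau, cell.decay_tau
        )
    return series


def _disk_mask(shape, center, radius):
    """Boolean disk and its bounding-box slices."""
    h, w = shape
    cy, cx = center
    r = int(np.ceil(radius))
    y0, y1 = max(0, int(cy) - r - 1), min(h, int(cy) + r + 2)
    x0, x1 = max(0, int(cx) - r - 1), min(w, int(cx) + r + 2)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return mask, (slice(y0, y1), slice(x0, x1))


def ground_truth_labels(cells, field_shape) -> tuple:
    """Ground-truth nucleus and cell label images (labels = cell ids)."""
    nuclei = np.zeros(field_shape, dtype=np.int32)
    cyto = np.zeros(field_shape, dtype=np.int32)
    for cell in cells:
        mask, box = _disk_mask(field_shape, cell.nucleus_center, cell.cytoplasm_radius)
        cyto[box][mask] = cell.cell_id
        mask, box = _disk_mask(field_shape, cell.nucleus_center, cell.nucleus_radius)
        nuclei[box][mask] = cell.cell_id
    return nuclei, cyto


def render_stack(
    cells,
    calcium,
    tb: Timebase,
    params: SimParams,
    rng,
    well_id: str = "",
    autofluorescence_boost: float = 0.0,
) -> TimeLapseStack:
    """Render a field to a (time, channel, y, x) stack.

    The nuclear channel is static (nucleus disks over background); donor and
    acceptor intensities inside each cell follow the sensor map — total FRET
    brightness is constant while the acceptor/donor split tracks calcium, so
    acceptor/donor equals the sensor ratio exactly before noise. Gaussian
    noise with variance proportional to the signal approximates photon shot
    noise; ``autofluorescence_boost`` adds a constant compound-fluorescence
    offset to the donor channel inside cells.
    """
    rng = np.random.default_rng(rng)
    calcium = np.asarray(calcium, dtype=float)
    if calcium.shape != (len(cells), tb.n_frames):
        raise ValueError(
            f"calcium must have shape (n_cells, n_frames) = "
            f"({len(cells)}, {tb.n_frames}), got {calcium.shape}"
        )
    h, w = params.field_shape
    t = tb.n_frames
    # noisy renders are shot-noise dominated, so single precision suffices;
    # noiseless renders stay double so analytic recoveries are exact
    dtype = np.float32 if params.photon_noise_scale > 0 else np.float64
    frames = np.empty((t, len(CHANNELS), h, w), dtype=dtype)
    frames[:, 0] = params.background["nuclear"]
    frames[:, 1] = params.background["donor"]
    frames[:, 2] = params.background["acceptor"]

    sensor = params.sensor
    bright = params.cell_brightness
    for i, cell in enumerate(cells):
        ratio = sensor.ratio(calcium[i])                 # (t,)
        donor = bright / (1.0 + ratio) + autofluorescence_boost * bright
        acceptor = bright * ratio / (1.0 + ratio)
        cmask, cbox = _disk_mask(
            (h, w), cell.nucleus_center, cell.cytoplasm_radius
        )
        nmask, nbox = _disk_mask(
            (h, w), cell.nucleus_center, cell.nucleus_radius
        )
        frames[(slice(None), 0) + nbox][:, nmask] = (
            params.background["nuclear"] + params.nuclear_intensity
        )
        for k in range(t):
            frames[(k, 1) + cbox][cmask] = params.background["donor"] + donor[k]
            frames[(k, 2) + cbox][cmask] = (
                params.background["acceptor"] + acceptor[k]
            )

    if params.photon_noise_scale > 0:
        # single-precision draws are plenty for noise and markedly faster
        noise = rng.standard_normal(frames.shape, dtype=np.float32)
        frames += params.photon_noise_scale * np.sqrt(frames) * noise
        np.clip(frames, 0.0, None, out=frames)
    return TimeLapseStack(frames=frames, timebase=tb, well_id=well_id)


@dataclass
class WellSimulation:
    """One rendered well plus its complete ground truth."""

    well_id: str
    stack: TimeLapseStack
    cells: list
    calcium: np.ndarray
    suppression: float
    nuclei_labels: np.ndarray
    cell_labels: np.ndarray

    @property
    def true_responder_fraction(self) -> float:
        if not self.cells:
            return float("nan")
        return float(np.mean([c.is_responder for c in self.cells]))


def simulate_well(
    params: SimParams,
    rng,
    suppression: float = 0.0,
    well_id: str = "",
    tb: Timebase | None = None,
    n_cells: int | None = None,
    autofluorescent: bool = False,
) -> WellSimulation:
    """Simulate one well end to end: field -> calcium -> rendered stack."""
    rng = np.random.default_rng(rng)
    tb = tb or default_timebase()
    n = params.n_cells if n_cells is None else n_cells
    cells = simulate_field(n, params.field_shape, params, rng)
    calcium = np.array(
        [
            calcium_series(c, tb, suppression, params.genotype_amplitude)
            for c in cells
        ]
    ).reshape(len(cells), tb.n_frames)
    stack = render_stack(
        cells,
        calcium,
        tb,
        params,
        rng,
        well_id=well_id,
        autofluorescence_boost=(
            params.autofluorescence_boost if autofluorescent else 0.0
        ),
    )
    nuclei, cyto = ground_truth_labels(cells, params.field_shape)
    return WellSimulation(
        well_id=well_id,
        stack=stack,
        cells=cells,
        calcium=calcium,
        suppression=suppression,
        nuclei_labels=nuclei,
        cell_labels=cyto,
    )


@dataclass
class PlateSimulation:
    layout: PlateLayout
    params: SimParams
    seed: int
    wells: dict = field(default_factory=dict)

    def ground_truth_frame(self):
        import pandas as pd

        rows = []
        for wid, sim in self.wells.items():
            for c in sim.cells:
                rows.append(
                    {
                        "cell_id": c.cell_id,
                        "well_id": wid,
                        "x": c.nucleus_center[1],
                        "y": c.nucleus_center[0],
                        "is_responder": c.is_responder,
                        "peak_scale": c.peak_scale,
                        "suppression": sim.suppression,
                    }
                )
        return pd.DataFrame(rows)


def _well_suppression(well, params: SimParams) -> float:
    if well.role in ("DMSO", "untreated"):
        return 0.0
    if well.role in CONTROL_ROLES:
        return params.control_suppression
    if well.role == "compound":
        return float(params.compound_suppression.get(well.compound_id, 0.0))
    raise ValueError(f"unknown role {well.role!r}")


def simulate_plate(
    layout: PlateLayout, params: SimParams, seed: int, tb: Timebase | None = None
) -> PlateSimulation:
    """Simulate every well of a plate.

    Suppressor controls (TP/CPA/TMB-8) are rendered with the strong default
    suppression, vehicle/untreated wells with none, and compound wells with
    their planted suppression from ``params.compound_suppression``.
    Deterministic: each well's generator stream is derived from
    ``(seed, well position)``.
    """
    layout.validate()
    tb = tb or default_timebase()
    plate = PlateSimulation(layout=layout, params=params, seed=seed)
    for i, well in enumerate(layout):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        n_cells = params.n_cells
        if well.role == "compound" and well.compound_id in params.toxic_compounds:
            n_cells = max(1, int(round(params.toxic_cell_fraction * n_cells)))
        plate.wells[well.well_id] = simulate_well(
            params,
            rng,
            suppression=_well_suppression(well, params),
            well_id=well.well_id,
            tb=tb,
            n_cells=n_cells,
            autofluorescent=(
                well.role == "compound"
                and well.compound_id in params.autofluorescent_compounds
            ),
        )
    return plate


def simulate_control_wells(
    rng,
    n_tp: int = 16,
    n_dmso: int = 16,
    tp_mean: float = 0.3,
    tp_sd: float = 0.01,
    dmso_mean: float = 1.0,
    dmso_sd: float = 0.03,
) -> tuple:
    """Well-level control readouts for plate-QC studies.

    Draws per-well normalized responses directly at the well level —
    Gaussian around the stated control means — for fast Z'-factor
    characterization without rendering images.
    """
    rng = np.random.default_rng(rng)
    tp = rng.normal(tp_mean, tp_sd, size=n_tp)
    dmso = rng.normal(dmso_mean, dmso_sd, size=n_dmso)
    return tp, dmso


def expected_peak_dff(
    params: SimParams,
    suppression: float = 0.0,
    peak_scale: float = 1.0,
    tb: Timebase | None = None,
) -> float:
    """Noise-free measured peak ΔF/F0 of an archetype responder.

    Propagates the latent transient through the sensor map and the frame
    grid exactly as rendering + trace extraction would, so it predicts the
    pipeline's readout for noiseless wells.
    """
    tb = tb or default_timebase()
    cell = CellGroundTruth(
        cell_id=0,
        nucleus_center=(0.0, 0.0),
        nucleus_radius=params.nucleus_radius_mean,
        cytoplasm_radius=params.cytoplasm_radius_mean,
        is_responder=True,
        peak_scale=peak_scale,
        baseline_calcium=params.baseline_calcium,
        rise_tau=params.rise_tau,
        decay_tau=params.decay_tau,
    )
    ratio = params.sensor.ratio(
        calcium_series(cell, tb, suppression, params.genotype_amplitude)
    )
    f0 = float(np.mean(ratio[: tb.n_pre]))
    return float(np.max((ratio[tb.dispense_index :] - f0) / f0))


def expected_normalized_response(
    suppression: float, params: SimParams, tb: Timebase | None = None
) -> float:
    """Noise-free normalized ER calcium response planted by ``suppression``:
    the archetype peak ΔF/F0 at that suppression over the vehicle peak."""
    return expected_peak_dff(params, suppression, tb=tb) / expected_peak_dff(
        params, 0.0, tb=tb
    )


def suppression_for_normalized_response(
    target: float, params: SimParams, tb: Timebase | None = None
) -> float:
    """Invert :func:`expected_normalized_response` for planting compounds
    with a prescribed true normalized response."""
    if not 0.0 < target <= 1.0:
        raise ValueError("target normalized response must be in (0, 1]")
    if target == 1.0:
        return 0.0
    return float(
        brentq(
            lambda s: expected_normalized_response(s, params, tb) - target,
            0.0,
            1.0,
            xtol=1e-13,
        )
    )


def random_fingerprints(
    n_compounds: int, n_bits: int, rng, density: float = 0.3
) -> np.ndarray:
    """Random binary fingerprint matrix with at least one set bit per row."""
    rng = np.random.default_rng(rng)
    fps = (rng.random((n_compounds, n_bits)) < density).astype(np.uint8)
    for row in fps:
        if not row.any():
            row[rng.integers(n_bits)] = 1
    return fps
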