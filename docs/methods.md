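# Methods

## The assay being emulated

The pipeline models a single-cell FRET calcium-imaging screen: adherent
HEK293-like cells expressing a genetically encoded ratiometric calcium
sensor (CFP-like donor, YFP-like acceptor; the acceptor/donor emission ratio
rises with cytosolic calcium) are imaged in 384-well plates together with a
far-red nuclear stain. Part-way through each well's time lapse the
muscarinic agonist carbachol is dispensed, triggering IP₃-mediated calcium
release from the ER. Cells carrying FAD-linked presenilin-1 mutations show
an exaggerated evoked peak (~3-fold wild type) and near-universal
responsiveness (>95 % vs ~29 % of cells), and the screen scores compounds by
how far they suppress the evoked peak relative to vehicle (DMSO) controls on
the same plate.

## Imaging timebase

Each well is sampled on a 13-frame grid: baseline for 5 s at 2.5 s spacing
(t = 0, 2.5, 5 s), dispense immediately after the third frame (modeled at
t = 5.5 s, midway to the next frame), then 5 s at 1 s spacing and 12.5 s at
2.5 s spacing (last frame t = 22.5 s). The 23.5 s protocol duration is the
sum of the acquisition windows including the dispense gap; the grid is
configurable (`Timebase`).

## Synthetic-plate generator

The generator's defaults are the study conditions; they are set once and are
not tuning knobs.

**Cell fields.** Cells are disks — a nucleus (radius 5 ± 0.5 px, clipped
±1 px) inside a cytoplasm (radius 12 ± 0.8 px, clipped [10, 13] px) — placed
uniformly by dart throwing with a minimum center distance of 26 px, so cell
disks never overlap, and a 7 px border margin, so nuclei stay off the frame
edge while border-adjacent cytoplasms may touch it (exercising edge
exclusion). Default 175 cells per 512×512 field, the midpoint of the
150–200 cells detected per well in the emulated assay; impossible packings
fail explicitly after bounded retries.

**Calcium dynamics.** Latent calcium is dimensionless with baseline 0.1.
Responders (i.i.d. Bernoulli with the genotype's responder fraction: 0.29
wild-type-like, 0.96 FAD-like) add an evoked transient — a difference of
exponentials with rise τ 0.8 s and decay τ 6 s, normalized to unit
continuous peak — of amplitude `peak_scale × genotype_amplitude ×
(1 − suppression)`. `peak_scale` is per-cell heterogeneity, Normal(1, 0.15)
clipped to [0.3, 1.7] (the floor keeps true responders above the default
responsiveness threshold, so classification errors reflect noise, not
construction); `genotype_amplitude` is 1 (wild type) or 3 (FAD);
`suppression` ∈ [0, 1] is the planted compound effect. Suppressor controls
(TP/CPA/TMB-8) are all modeled as evoked-release suppressors at
suppression 0.7 (planted normalized response ≈ 0.31); their pharmacological
distinctions are not modeled.

**Optics.** Calcium maps to the emission ratio through a saturating
Hill-type sensor map R(c) = 1 + 25·c/(c + 50). The half-saturation constant
is deliberately far above the evoked range so the measured ΔF/F₀ is
near-linear in evoked amplitude: the predicted FAD/wild-type measured peak
ratio at a 3-fold calcium amplitude is 2.89, inside the ±10 % window the
assay reproduces. Each cell emits constant total FRET brightness
(1500 counts/px) split between donor and acceptor by R, so acceptor/donor
equals R exactly before noise; the nuclear channel is static (nucleus disks
at 2000 counts over an 80-count background; FRET backgrounds 120 counts).
Photon shot noise is approximated as Gaussian with variance proportional to
the signal (scale 1.0); noisy renders use single precision (noise dwarfs
quantization), noiseless renders double precision so analytic recoveries
are exact. Optional artifacts: autofluorescent compounds add a constant
donor-channel offset inside cells; toxic compounds reduce the cell count to
15 % of nominal.

**What the generator does not model** (so what passing tests do not show
about real data): optical PSF and focus variation, photobleaching, cell
movement/division/morphological irregularity, dispense artifacts,
non-uniform illumination, sensor kinetics (the ratio follows calcium
instantaneously), and basal-calcium differences between genotypes. Results
on real plates depend on segmentation quality and background structure the
synthetic fields idealize.

## Analysis

**Segmentation** runs on the first timepoint only and is reused across
frames (cells assumed static over ~23 s). Nuclei: Gaussian smoothing
(σ = 2 px), Otsu threshold by default (a fixed threshold is accepted), area
floor 20 px², touching nuclei split by watershed seeded at
distance-transform maxima ≥ 5 px apart. Cell regions: nucleus-seeded
watershed on the smoothed, inverted donor+acceptor sum, restricted to
foreground pixels within 15 px of a nucleus; every nucleus receives exactly
one region and contested pixels belong to exactly one cell. Edge exclusion
removes any cell whose *region* (not merely nucleus) touches the border —
the stricter of the two possible readings. Background estimation always
uses the union of all detected regions, including edge-excluded ones, so
excluded cells never contaminate the background term.

**Traces.** Per frame and channel, the cell mean minus the mean over
non-cell pixels ("mean_outside"; "none" is selectable). A trace whose
corrected donor is ≤ 0 in any frame is invalid. F₀ is the mean ratio over
pre-dispense frames; ΔF/F₀ as defined; the peak is taken at or after the
dispense frame, so pre-dispense excursions never score. Responsiveness uses
an inclusive boundary (peak ≥ threshold, default 0.1 ΔF/F₀ — small against
FAD-like evoked peaks ≈ 1.3, far above the photometric noise floor at
default optics ≈ 0.004); `threshold_for_target_fraction` reports the
threshold that would yield a target responsive fraction on control wells.
Wells with fewer than 20 responsive cells (configurable) are invalid — a
conservative floor given 150–200 cells/well.

**Screen statistics.** Normalization divides each valid well's readout by
the mean over valid DMSO wells on the same plate (well-mean-of-means, not a
pooled cell population); replicate aggregation is the arithmetic mean ±
sample sd over valid replicates, with invalid replicates excluded and
counted. Hits require a replicate-mean normalized response strictly below
0.9 *and* no artifact flag; a compound inherits a flag if any of its wells
is flagged. Before the strict comparison the score is rounded to 9 decimal
places — a numerical guard so a compound sitting exactly on the cutoff is
classified by its exact score rather than last-bit float noise; any real
effect is orders of magnitude larger. Artifact flags are operational
defaults (the emulated assay names the filters but no numbers):
autofluorescent if a well's per-cell baseline donor or acceptor exceeds the
DMSO mean by more than 5 DMSO sds; toxic if its detected cell count falls
below 0.3× the plate median. Z′ is computed in both forms — canonical
Zhang, 1 − 3(σ₊+σ₋)/|μ₊−μ₋| (the default), and the variant
1 − (3σ₊+σ₋)/|μ₊−μ₋| — with sample sds (ddof 1); equal control means raise
an explicit error.

**Dose-response.** The 4-parameter log-logistic curve
response = bottom + (top − bottom)/(1 + (EC50/dose)^slope), fit by
nonlinear least squares on (log EC50, slope, top, bottom) with multi-start
over slope magnitude, the sign constrained by the declared direction
(agonist rising, antagonist falling, or both tried). The initial EC50 is
the geometric mean of the doses bracketing the half-response. Constant
responses are refused; convergence is reported honestly and non-converged
fits cannot be evaluated. Four free parameters require four distinct doses;
fixing the asymptotes (the natural choice for normalized 0–1 data) lowers
the requirement. Note on precision: with 5 % Gaussian noise on a 7-point
grid the fully free fit's EC50 spread (median relative error ≈ 19 %) is
statistical — an independent fit started at the generating parameters lands
on the same optimum — while pinning bottom = 0, top = 1 brings the median
error under 10 %.

**SAR clustering.** Tanimoto dissimilarity 1 − |a∧b|/|a∨b| on binary
fingerprints. OptiSim selection: per round, compounds farther than radius
*r* from every selected compound are eligible; a seeded random subsample of
at most *k* eligible compounds is drawn (first *k* positions of a
permutation of the eligible list in canonical order) and the candidate with
the greatest minimum dissimilarity to the selected set is added (lowest
index on ties; the first pick is the first subsample entry). Defaults
k = 10, r = 0.4 (the emulated procedure names the algorithm but no
parameters). Actives (normalized response < 0.9) provide the
representatives; every active joins its nearest representative, inactives
join only within the assignment radius (= r) or fall to an unclustered
pool, and representatives within the merge radius (= r) merge single-link.
Compounds are sorted by id before selection, making memberships invariant
to input order. Clusters with >50 % active members are starred; starred
clusters with more than four actives are highlighted. The 2-D SAR map
layout is out of scope; the membership and annotation tables are the
output.

## Pipeline, I/O and determinism

Stacks are TIFF (time × channel × y × x) with a JSON sidecar naming axes,
channels, frame times and the dispense index; tables are UTF-8 CSV with
zero-padded well ids (A01) and 0-based (row, col) pixel coordinates. The
run configuration is a strict-keyed YAML (unknown keys rejected, lossless
round-trip, mandatory seed); every output table carries the config hash and
the manifest records seed, version, per-plate Z′ and the hit list. All
randomness flows from explicit seeds (per-well streams derived from
(seed, well index)), so re-running a configuration reproduces outputs byte
for byte.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the screen at desk scale,
the package's own choice for quick iteration: 20 wells × 100 cells per
genotype for the responder-fraction and amplitude checks (384×384 fields at
default density), 10 plates × (16+16) control wells for Z′, 10 default
512×512 fields for segmentation counts, a 32-compound noiseless screen
(2 replicates, 30 cells/well) for hit-calling exactness, and 100 random
instances of ≤ 15 compounds for the OptiSim brute-force equivalence sweep.
With the prescribed well-level control parameters (DMSO 1.0 ± 0.03,
TP 0.3 ± 0.01, 16 wells each) the expected canonical Z′ is ≈ 0.83 with a
per-plate sampling sd of ≈ 0.025, so the minimum over ten plates hovers
around 0.79–0.84 depending on the seed — the same order of plate-to-plate
variation the emulated assay reports (0.806 ± 0.029).
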