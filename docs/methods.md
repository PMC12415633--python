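# Methods

## Diffraction model

The simulation is kinematic and intensity-free: a reflection is either
excited or absent, and all spots are rendered identically.  For a unit cell
(a, b, c, α, β, γ) the direct basis is built in a fixed Cartesian frame
(**a** ∥ x, **b** in the x–y plane, **c** completing a right-handed set);
the reciprocal basis is its dual without the 2π factor, so aᵢ·a*ⱼ = δᵢⱼ and
V* = 1/V.  The cell volume uses the closed form
abc·√(1 − cos²α − cos²β − cos²γ + 2 cosα cosβ cosγ) and is validated
against the triple product of the basis vectors.

For a unit beam direction **b̂** the Ewald sphere has radius R = 1/λ and
centre −R·**b̂**.  Writing g = g∥·**b̂** + g⊥, the excitation error is the
signed along-beam distance from the lattice point to the sphere surface,

    s = −g∥ − R + √(R² − |g⊥|²),

which reduces to the sphere sag −|g|²λ/2 for a zero-order-zone reflection.
A reflection is excited when |g| ≤ g_max and |s| ≤ s_max.  The along-beam
convention was chosen over the nearest-distance alternative because only
the magnitude threshold is physically specified; the two conventions differ
by O(λ·g), which is far below s_max at electron wavelengths.  The test
suite cross-checks the excitation set against an independent quadratic
root-finding oracle on random cells.

Candidate reflections are enumerated exactly: by duality h = g·**a**, so
|h| ≤ g_max·a (and likewise k, l).  This per-index bound cannot miss a
reflection however oblique the cell.

Defaults (config-exposed): λ = 0.0251 Å (the relativistic wavelength of
200 kV electrons, h/√(2m₀eU(1+eU/2m₀c²))), g_max = 1 Å⁻¹,
s_max = 0.01 Å⁻¹.

## Orientations

Beam directions come from the Fibonacci-sphere construction: point *i* of
*n* sits at z = 1 − (2i+1)/n with azimuth i·golden-angle.  A uniformly
random in-plane roll of the detector is drawn per orientation from the
dataset seed; rolling the detector about the beam rotates the projected
pattern but can never change which reflections are excited, so labels are
roll-invariant (tested).  Each snapshot projects the excited g-vectors onto
a flat detector normal to the beam.

## Cell generation

Lengths and angles are drawn uniformly from configurable windows —
triclinic angles [75°, 115°], monoclinic β [95°, 115°] with α = γ = 90°,
lengths [5, 12] Å ("nearly isotropic") or [3, 22] Å ("strongly
anisotropic") — and the three lengths are then rescaled isotropically so
the volume hits the target exactly, preserving the sampled shape
anisotropy.  The windows are package defaults chosen to produce
non-degenerate cells resembling the published example cells; they are not
taken from any printed sampling protocol.  Inadmissible angle draws (closure
or positivity violations) are rejected and redrawn with a bounded retry
budget.  Randomness is organized as one seed per dataset with per-cell
substreams, so datasets are reproducible and cells independent.

The monoclinic fixture uses the two published cells
(a = 3.8155, b = 10.0452, c = 13.7425 Å, β = 107.8717°;
a = 3.7061, b = 12.0249, c = 11.7474 Å, β = 103.1097°) with the 2₁ screw
axis along **b**, modelled as the axial reflection condition 0k0: k = 2n.
Because patterns are binary, only this geometric absence matters; general
positions carry no intensity information.  The `training_1000A3`
preset uses 4 cells × 1000 orientations (alternating isotropic and
anisotropic length windows); the 500/700 Å³ generalization presets use
2 cells each — the pattern counts per cell are fixed by the study design,
the cell counts for the smaller-volume presets are the package's choice.

## Zonal labelling

A pattern is `2DZone` exactly when the integer matrix of its excited hkl
rows has rank 2.  The rank is computed with integer cross and dot products
only, so the criterion is exact and tolerance-free — the noiseless
equivalent of labelling images by eye under the strict "only a visible 2D
net, nothing else" rule.  The zone axis is the primitive integer normal of
the common plane (coprime components, first nonzero component positive).
Patterns with rank < 2 (empty, single spot, or a collinear row) cannot show
a 2D net and are labelled `3DLaueIntersections` with a `degenerate` flag;
they are useless for downstream unit-cell work either way.  For rank-3
patterns, `n_off_zone` reports the fewest reflections violating any single
zone law, found by searching the cross products of reflection pairs (exact
whenever the best zone holds two independent reflections).

Physics makes the strict criterion meaningful at the default parameters:
first-order Laue zones of cells in the simulated size range sit ≥ 0.04 Å⁻¹
from the zero-order plane, beyond reach of the ±0.01 Å⁻¹ excitation band,
so an exactly on-zone beam produces a pure ZOLZ net bounded by the sag
cutoff √(2·s_max/λ) ≈ 0.89 Å⁻¹.  Near-zone beams excite coplanar sets out
to g_max, and slightly larger tilts admit the first out-of-zone reflection,
flipping the label (tested by a tilt scan).

At V = 1000 Å³ under the default physics, the strict criterion labels
~3% of Fibonacci-sphere snapshots zonal (measured 3.1 ± 0.6% over seeded
cells); the fraction is the acceptance quantity `t2`.

## Rendering

Patterns are 8-bit {0, 255} PNGs.  Detector coordinates map linearly with
±gmax_to_edge (default 1 Å⁻¹) spanning the image half-width; reflections
are filled discs of `spot_radius` (default 3 px at 512²) and the primary
beam is always drawn at the centre with a slightly larger disc (default
6 px).  Disc centres are quantized to the pixel grid, which sets a
sub-pixel noise floor that the classifier's feature extractor must absorb.
Spots falling outside the canvas are clipped silently.

## Classifier

The classifier never sees the integer hkl ground truth — only pixels — so
its validation accuracy against the geometric labels is a genuine test of
image-based sorting.  It is a deliberately lightweight, CPU-scale design:

1. **Spot extraction.**  The image is downscaled to `image_size`
   (default 254; the scaled-down experiments use 128) with box averaging,
   binarized, and decomposed into 4-connected components.  The component
   covering the image centre (the enlarged primary-beam spot) is dropped.
   Sub-pixel centroids are estimated from the grey anti-aliasing skirt
   around each component; components whose integrated intensity reveals a
   multiplicity > 1 (spots bridged by their skirts in dense nets) are split
   by intensity-weighted k-means.
2. **Invariant descriptors** (17, all rotation/roll/scale-invariant):
   spot count, radial statistics, Friedel-mate completeness,
   nearest-neighbour spacing statistics, and a family of 2D-net misfit
   measures.  The net is found in Fourier space: the spot centroids are
   splatted onto a fine grid, the transform of a 2D net concentrates into
   sharp dual-lattice peaks, and candidate nets are non-collinear pairs of
   the strongest peaks.  The pair cohering with the most spots (median
   phase criterion, so a minority of off-net spots cannot steer the
   choice) — preferring the coarsest real-space net among ties, so
   non-primitive or over-fine bases cannot absorb off-net spots — defines
   the net; integer node indices then come from global phases, and a
   least-squares refit of basis and origin gives per-spot residuals limited
   only by each spot's own centroid noise.  Derived descriptors: mean /
   fraction / count / maximum of off-net residuals (in both
   net-spacing-relative and absolute units), hull-restricted node
   occupancy, local four-neighbour node occupancy, and the raw phase
   misfit.
3. **Head.**  Descriptors are standardized and fed to a small MLP (one
   hidden layer of 24 units, L2 penalty α = 0.1).  One *epoch* draws one
   bootstrap resample of the training split — each sample selected with
   probability inversely proportional to its class size, so the rare zonal
   class carries half the effective weight — and re-optimizes the network
   on it with warm-started L-BFGS (≤ 200 iterations per epoch).  After each
   epoch the validation accuracy is logged; the best checkpoint is kept,
   ties broken toward the earliest epoch.  All stochastic components
   (split, sampler, weight init) derive from one config seed.

Without the balanced sampling the 3%-minority problem admits a degenerate
high-accuracy solution that never predicts zonal; inverse-class-size
sampling removes it, which is the point of the class-imbalance design.

`classify` is a pure function of (weights, pixels) returning the argmax
class and its probability as the confidence.  `sort_dataset` fills the
manifest, reports a confusion matrix and accuracy against the geometric
labels when present, and lists *hybrid candidates* — patterns predicted
zonal with confidence below a threshold (default 0.99), which in practice
are near-zone snapshots with a few extra reflections from another Laue
layer, still usable for unit-cell work after manual review.

Only this lightweight backbone ships; `TrainConfig.backbone` rejects
anything else explicitly.  Heavy pretrained detection networks are out of
scope for this package's CPU-oriented design.

### Scaled-down experiment and what it shows

The acceptance experiment (`t3`) trains on 2 cells × 250 orientations at
image size 128 for 7 epochs with a stratified 80:20 split and reports the
best-epoch validation accuracy; across twelve dataset seeds it reached
100% on every run during development.  The residual failure mode is real
and worth knowing: when the beam is near-zonal, reflections from an
adjacent Laue layer project at a fixed in-plane shift, and if that shift is
nearly commensurate with the zonal net the off-zone spots are separated
from net nodes by less than the rendering/extraction noise (~0.3 px).  Such
patterns are geometrically rank-3 but pixel-wise indistinguishable from
zonal at finite resolution — no image-based observer, human or learned,
can label them reliably.  They are rare (well under 1% of snapshots at
these conditions) but bound any image-level sorter away from exactness in
sufficiently large datasets.

## What the generator does and does not emulate

It emulates the geometry of a serial ED experiment: random orientations,
excitation-error-limited kinematic spot selection, resolution cutoff,
systematic absences, binary rendering with a primary-beam marker.  It does
**not** emulate detector noise or gain, Bragg intensities or dynamical
effects, mosaicity, partiality, multi-crystal frames or no-hit frames.
Passing tests therefore demonstrate that the sorting architecture works on
clean geometry; they say nothing about robustness to experimental
pathologies, which would need either experimental training data or
semi-synthetic patterns built from extracted peak positions.

## Numerical choices and degenerate inputs

- Volume rescaling hits the target to 1e-6 relative; basis duality and
  reciprocal volume identities hold to 1e-9.
- Integer rank/zone-axis computations use int64 throughout; no floating
  tolerance exists in the labeller.
- Candidate enumeration bound: floor(g_max·axis length) per index.
- Empty reflection lists render as an image with only the central spot and
  are labelled `3DLaueIntersections` (degenerate).
- Manifests: CSV records + JSON sidecar with the full configuration and
  the per-pattern hkl sets, so labels can be re-derived and audited without
  re-simulation; a schema-version gate rejects incompatible files; missing
  image files are reported as warnings, not errors.
- Stratified splitting apportions the train share by largest remainder,
  keeps both classes in validation whenever each has ≥ 2 members, and
  places singleton classes wholly in training with a warning.

## Problem sizes

Development and test runs use 2–5 cells × 150–1000 orientations
(≤ 5000 patterns) and 128-pixel training images; these sizes give stable
zonal-fraction estimates (binomial SE ≈ 0.5% at n = 1000) and training
sets large enough for the head to converge, while keeping a full suite run
in a couple of minutes on one CPU.  The generator scales linearly in cells
× orientations and the candidate enumeration is O((2·g_max·a)³) per cell.
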