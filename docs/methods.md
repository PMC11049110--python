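# Methods

This note records the models implemented in `holotox`, the choices made
where the procedure left room for design, and what the synthetic data do
and do not establish about real measurements.

## Forward model: scenes and holograms

A *phase scene* is a 2D map of optical path delay (radians) over a
405 µm × 538 µm field of view. Cells are raised-cosine radial bumps
(`peak · cos²(πr/2R)`); each cell's integrated phase encodes its dry mass
through `dm = λ/(2πα) · Σφ · A_px`, and the per-cell peak is rescaled after
discrete rendering so the recorded scene mass is exact to float precision.
Peak phase is kept near 2 rad so single cells never span a 2π interval.
Placement is uniform with a bounded pairwise overlap (default 35% of the
summed radii); a scene too dense to place raises rather than silently
overlapping.

The 24 h evolution at dose x multiplies population mass by
`g(x) = g_floor + f(x)·(g_ctrl − g_floor)` where `f` is the 4PL response
fraction, `g_ctrl = 2.0` (medium-control doubling over 24 h, typical of the
fibroblast/macrophage lines this emulates) and `g_floor = 0.5` (net mass
loss at saturating dose). Growth adds cells; attrition removes them, and
when `f < 0.2` thirty percent of the surviving mass is rendered as
sub-cellular debris fragments, mirroring the debris seen at lethal doses.
A final exact rescale pins the rendered t=24 mass to `g · m(t0)`.

Holograms are `I = |O + R|²` with `O = exp(iφ)` and a tilted plane
reference at carrier (0.25, 0.15) cycles/pixel; the sign convention places
the object phase, with positive sign, on the positive-frequency sideband.
Noise terms, all seeded: per-frame coherence speckle (Gaussian-filtered
white noise, σ = 0.1 rad, 8 px correlation — decorrelated between frames,
which is what frame averaging exploits), additive detector noise (1% of
mean intensity; Poisson optional, off by default), and a *frame-common*
scattering background whose amplitude grows as √dose (0.15 rad at
512 µg/mL) to emulate the raised phase background at high particle
concentrations. No published noise statistics exist for the emulated
instrument; these magnitudes are plausible rather than calibrated, so
round-trip accuracies measured here characterize the algorithms, not the
hardware.

## Reconstruction

Carrier detection takes the strongest spectral peak outside a DC exclusion
disk (0.03 c/px), refines it by 3×3 magnitude centroid, and then by two
iterations of demodulation feedback: the amplitude-weighted mean phase step
of the demodulated low-passed field measures the residual carrier error
directly (the integrated gradient of compact cell signal is ≈ 0). The
centroid alone is good to ~0.15 spectral bins, which is enough to corrupt
the autofocus metric; the feedback loop brings the error below ~0.05 bins.

Demodulation multiplies the hologram by the conjugate carrier ramp (exact
for sub-bin carriers) and applies a raised-cosine circular low-pass of
radius 0.45·|carrier| (30% taper) — soft edges suppress ringing. Filtering
can only remove spectral power. Residual tilt/piston is removed twice:
wrap-safely on the complex field (conjugate-product gradients over
cell-free pixels), and after unwrapping by a least-squares plane fit
anchored on cell-free pixels, whose full-field lever arm is far more
precise. Cell-free pixels are the lowest-activity 40% of a smoothed
wrap-safe gradient map, falling back to a 16 px border frame.

Unwrapping uses reliability-sorted (quality-guided) 2D unwrapping
(`skimage.restoration.unwrap_phase`). Refocusing uses the angular-spectrum
kernel (unitary on propagating components; no evanescent content at these
pixel pitches). The autofocus score is the *negated* Tamura coefficient of
the amplitude: a pure phase object has minimal amplitude contrast in focus,
so the argmax of the score is the focus plane; the criterion is pluggable.
Ties are broken toward the smallest |distance| and flagged.

Frames are averaged as unwrapped phase maps after per-frame piston removal
(median over cell-free pixels of the stack's median frame mask), not as
complex fields — immune to inter-frame piston introduced by the tunable
lens. Ten-frame averaging reduces background phase noise by ≈ √10.

## Background correction and dry mass

The rolling-ball background is the exact grayscale opening with a
spherical-cap structuring element; no shrink/scale speedup. Two parameters:
radius (default 50 px at 512×512, about twice a cell diameter) and a
height scale converting the cap's vertical extent to radians (default
0.01 rad/px). The height scale is the radian analogue of the gray-value
scaling in classic 8-bit implementations: the ball must be flatter than a
cell (so it rolls under, not into, the cells) yet curved enough to track
slow background relief. Its residual footprint is a sag of
`h_s(R − √(R²−w²))` under a blob of half-width w — about 2–5% of cell mass
at defaults — which cancels in the DMI difference and in the relative
normalization. The image is reflect-padded by twice the kernel radius,
making the result the exact opening of the extended image and hence
idempotent including borders.

Δφ̄ is the arithmetic mean over the *full* field of view (not cell-masked),
which is what makes `dm = λ/(2πα)·Δφ̄·S_FOV` equal to the integrated phase
times pixel area. The printed value of α in the source literature for this
workflow is dimensionally inconsistent (mm³/g at 10⁻³ scale); this package
uses the standard protein refractive increment 0.19 mL/g ≡ 0.19 µm³/pg and
exposes it as configuration. Only t = 0 and t = 24 h enter the endpoint;
intermediate time points are accepted by the data model but ignored.
The DMI normalization reference is the maximal per-dose mean DMI within a
cell line × experiment (in practice the medium control; configurable to
the explicit zero-dose group), since the exact reference set of the
"normalize to the maximal dry mass value" convention is not fixed by the
assay description.

## Plate assays

WST-8 uses the 450−620 nm difference; the dose-proportional particle
turbidity term enters both channels and cancels. The LDH normalization
uses raw OD₄₉₂ slopes without a 620 nm term, matching the release formula
as conventionally printed. LDH linear-range detection is seed-and-extend:
the best 5-point window (highest r²) grows while each new point's
predictive residual stays within `max(4·s, 0.25·|slope|·Δt)`; the absolute
term lets exactly-linear data extend to the full series while rejecting a
plateau point, whose deviation is a full slope step. The final window must
reach r² ≥ 0.99, else the full-series slope is returned flagged
"nonlinear". A plain longest-window-above-r² rule cannot exclude plateau
points: one flat point among 20 linear ones still leaves r² ≈ 0.999.
Release percentages are reported unclamped.

## Dose–response and statistics

The 4PL is fit on log₁₀ dose by least squares with multi-start
initialization (EC50 at the 25/50/75% dose quantiles, Hill ∈ {±1, ±3});
parameters are canonicalized to Hill > 0 with `top` the zero-dose
asymptote. Top/bottom are unconstrained. Zero-dose controls normalize the
response scale but are excluded from the fit (log 0). Acceptance gates, in
priority order: (1) per-dose means must be monotone — a counter-trend step
exceeding 3 combined SEMs rejects as `non_monotonic`; this is a property
of the data and is checked even when the optimizer fails; (2) r² ≥ 0.8;
(3) EC50 inside the tested dose range. Cross-experiment summaries are the
arithmetic mean ± SD of per-experiment EC50s (not a pooled fit); a single
experiment reports no SD, and conditions with no accepted fit report
"not determined".

Control comparisons: one-way ANOVA across control and dose groups gates at
α = 0.05; per-dose Welch t-tests against the control are Holm step-down
adjusted and starred at p < 0.05/0.01/0.001. The exact post-hoc procedure
behind such stars is rarely stated; this concretization keeps the
family-wise false-positive rate at or below the gate level (measured
≈ 0.01–0.015 under a simulated global null). All-constant groups short-
circuit to an exact-tie flag.

## Problem sizes and defaults

Unit validation of the optical chain runs at the instrument geometry
(512×512, 10 frames). The orchestrated demo runs at 256×256 over the same
physical field (coarser pitch), rolling-ball radius 25 px, 8 doses ×
2 wells × 1 FOV × 2 time points per experiment — small enough for a
seconds-to-minutes desk run while leaving every stage exercised; the
plate branch keeps 4 technical replicates per condition and the imaging
sampling design (2 FOVs × 4 wells) remains available through
configuration.

## What the synthetic data do not show

The generator emulates adherent-cell morphology, growth, debris, carrier
fringes, speckle, detector noise and dose-dependent scatter — not partial
coherence, Mie scattering, aberrations beyond tilt, cell motility between
frames, or assay-specific chemistry (substrate depletion appears only as
an optional LDH plateau). Passing round-trip and recovery tests therefore
demonstrates correctness of the algorithms under the stated noise model,
not instrument-level performance. EC50 recovery accuracy is conditional on
the response truly being sigmoidal; the rebound scenario shows the
pipeline declining to report an EC50 when it is not.
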