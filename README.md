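# holotox

Multimodal assessment of nanoparticle cytotoxicity from a single cell
culture: a label-free **digital holographic microscopy (DHM)** proliferation
readout, followed by the downstream biochemical **WST-8** (metabolic
viability) and **LDH** (membrane damage / cell death) assays, compared
through four-parameter logistic **EC50** estimation.

The package is aimed at quantitative-phase-imaging and nanotoxicology
groups who want a tested, fully synthetic-data-driven implementation of
this workflow: every stage — from off-axis interferogram to EC50 table —
runs on simulated inputs with known ground truth, so each algorithm can be
validated end to end without instrument data.

## The measurements

**DHM dry-mass proliferation.** Off-axis holograms (10 frames per field of
view, decorrelated by tunable-lens modulation) are reconstructed by Fourier
sideband demodulation, unwrapped, averaged, and background-corrected with a
rolling-ball (grayscale opening) filter. The population dry mass in a field
of view follows from the mean phase shift Δφ̄:

    dm = λ / (2π α) · Δφ̄ · S_FOV

with λ = 532 nm, refractive increment α = 0.19 mL/g and
S_FOV = 405 µm × 538 µm. The 24 h **dry-mass increment**
DMI = dm(t=24 h) − dm(t=0), normalized to the maximal (control) increment,
is the relative proliferation in percent.

**WST-8 viability.** Turbidity-corrected endpoint absorbance, normalized so
reagent background maps to 0% and the medium control to 100%:

    viability% = 100 · (OD₄₅₀₋₆₂₀,sample − OD₄₅₀₋₆₂₀,bg) / (OD₄₅₀₋₆₂₀,ctrl − OD₄₅₀₋₆₂₀,bg)

**LDH release.** Kinetic OD₄₉₂ read every minute for 30 min; the per-well
activity is the regression slope over the detected linear range, scaled
between the medium control (0%) and digitonin full lysis (100%):

    release% = 100 · (mOD_sample − mOD_ctrl) / (mOD_digitonin − mOD_ctrl)

**Dose–response.** Each endpoint is fit with the four-parameter logistic

    y(x) = bottom + (top − bottom) / (1 + (x / EC50)^h)

on log dose, with multi-start initialization and direction inferred from
the data. A fit is reported only if the per-dose means are monotone within
a noise allowance, R² clears a threshold, and the EC50 lies inside the
tested dose range; otherwise the condition is reported **not determined**
(as happens for drug-loaded particles whose response rebounds at
intermediate dose).

## Worked example

Simulate one complete experiment in which proliferation arrest (true
EC50 = 10 µg/mL) precedes metabolic shutdown (25 µg/mL) which precedes
membrane rupture (60 µg/mL):

```python
from holotox.pipeline import demo_config, run_multimodal_pipeline

bundle = run_multimodal_pipeline(demo_config(seeds=[101]))
print(bundle.ec50_summary[["assay", "n_accepted", "ec50_mean", "label"]])
```

prints

```
assay  n_accepted  ec50_mean      label
  DHM           1   9.553193 9.55 µg/mL
WST-8           1  25.274786 25.3 µg/mL
  LDH           1  60.211433 60.2 µg/mL
```

Each row is one assay's mean EC50 across experiments. The imaging branch
(DHM) recovers its truth through the complete optical simulation —
hologram synthesis, reconstruction, rolling-ball correction, dry-mass
conversion — and the three assays order exactly as their underlying
sensitivities: the label-free proliferation readout flags toxicity at
lower dose than either biochemical assay.

The same stages are available from the shell (`holotox simulate`,
`holotox reconstruct`, `holotox postprocess`, `holotox assays wst8|ldh`,
`holotox fit`, `holotox demo`).

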