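# spenfmri

A desk-scale simulator and analysis chain for single-shot functional MRI
of the mouse olfactory bulb (OB) with **spatiotemporal encoding (SPEN)**
sequences, built for studying why SPEN succeeds where echo-planar imaging
(EPI) fails next to air interfaces at ultrahigh field, and for
prototyping the full block-design olfactory activation-mapping workflow
on fully synthetic, fully known ground truth.

It is aimed at MR-physics and fMRI-methods researchers: everything —
phantom, field map, raw samples, reconstruction, hemodynamics, statistics
— is generated and analysed in Python, so every stage of the pipeline can
be tested against an oracle.

## What it models

**Acquisition.** Four single-shot sequences on a 2D digital OB phantom
(10.4 × 7.5 mm² FOV, ~108 × 107 µm² pixels, 0.8 mm slice):

- **GE-EPI / SE-EPI** — Fourier encoding along the low-bandwidth axis;
  a pixel at off-resonance Δf displaces by Δf·T_acq pixels
  (bandwidth per pixel = 1/T_acq).
- **FR-SPEN** — a 180° chirp pulse applied with a gradient imparts a
  quadratic phase φₑ(y) = αy² + βy, so sample m localises signal at the
  stationary point y\*(t_m) which sweeps linearly across the FOV; under
  *full refocusing* each position's off-resonance/T2\* phase is unwound
  exactly at its own acquisition moment (τ(y, t) = t − t\*(y)), and the
  residual displacement shrinks to Δf·T_acq·N_y/R pixels for a chirp
  time–bandwidth product R (default R = 2000).
- **PR-SPEN** — *partial refocusing* leaves a uniform residual T2\*
  evolution time Δ = 4 ms, restoring BOLD sensitivity at a small cost in
  robustness.

Raw data follow
`s_m = Σ_n ρ(y_n) e^{i[φₑ(y_n)+k(t_m)y_n]} e^{i2πΔf τ} e^{−t/T2} e^{−|τ|/T2′} Δy + ε`,
with the readout axis an ideal Fourier dimension and complex Gaussian
noise summed over 2 coherent averages (TR 1 s → one volume per 2 s).

**Reconstruction.** Inverse DFT for EPI; for SPEN either the
stationary-point magnitude |s(t_m)| (no Fourier transform involved) or
super-resolution (SR) recovery of nominal resolution by Tikhonov
inversion of the explicit encoding operator `min_ρ ‖Aρ−s‖² + λ‖ρ‖²`.

**Experiment.** The study's block paradigm (10 events of 120 s air +
26 s odor, 700 volumes at 2 s, ≈23 min), activation as an R2\* decrease
in odor-specific laminae (EPL for aversive, lateral glomeruli for
appetitive, both for neutral), canonical double-gamma HRF, saturating
Hill concentration response, single-nostril lateralization, drift and
motion nuisances.

**Analysis.** Raw epoch-averaged percent-change curves, pixelwise GLM
t-maps (p < 0.001), two-sample t / one-way ANOVA second level,
max-statistic permutation (SnPM-style) inference, and a QC screen
reproducing the motion/drift/consistency discard criteria.

## Worked example

```bash
$ spenfmri compare-sequences
sequence       snr  centroid_shift_mm     dice  peak_percent_change
  GE_EPI    11.828              0.509    0.858               12.595
  SE_EPI    19.056              0.322    0.862                4.525
 FR_SPEN    18.024             -0.048    0.986                5.056
 PR_SPEN    17.406             -0.024    0.990                6.287
```

(Values for `--seed 1` on the default phantom with the air-interface
field.)  Under several hundred
Hz of air-interface off-resonance the EPI images displace by a few
pixels and lose ~0.13 of support Dice, while both SPEN variants stay at
Dice ≈ 0.99; the partially refocused variant's BOLD response (6.3% peak
percent change) exceeds the fully refocused one's (5.1%) because Δ = 4 ms
of T2\* weighting is retained.

```bash
$ python examples/03_bold_run_percent_change.py
epochs averaged: 3
peak percent signal change in the active ROI: 6.68%
peak occurs 20 s after odor onset
```

The `examples/` directory holds one short script per capability
(phantom/field, sequence comparison, BOLD run, first-level map + QC,
nostril/concentration scenarios, second-level + permutation inference).
The `spenfmri` CLI offers `simulate`, `analyze`, `compare-sequences` and
`calibrate-noise` over YAML configs, writing 4D NIfTI, events TSV, CSV
metric tables and YAML provenance.

## Layout

| Module | Contents |
| --- | --- |
| `spenfmri.phantom` | OB phantom, region masks, air-interface dipole field |
| `spenfmri.sequences` | sequence parameters, quadratic-phase and timing math |
| `spenfmri.forward_sim` | raw-data simulation, noise calibration |
| `spenfmri.recon` | EPI inverse DFT, SPEN magnitude and SR inversion |
| `spenfmri.bold_experiment` | paradigm, HRF, activation model, run simulation |
| `spenfmri.activation_analysis` | GLM, second level, permutation, QC |
| `spenfmri.metrics` | SNR, centroid shift, Dice |
| `spenfmri.io`, `spenfmri.cli` | configs, NIfTI/TSV/CSV/YAML, CLI verbs |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
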