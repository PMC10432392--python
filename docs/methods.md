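# Methods

This note documents the models behind `spenfmri`, the defaults and their
rationale, the numerical choices, and what the synthetic pipeline does
and does not establish about real data.

## Phantom

The object is a single 2D slice: two mirrored elliptical OB hemispheres
on a 96 × 70 grid (10.4 × 7.5 mm² FOV, ~108 × 107 µm² pixels, slice
thickness 0.8 mm entering only as a scalar signal weight).  Each
hemisphere is layered radially into a glomerular rim (elliptical radius
0.85–1.0), an external plexiform (EPL) ring (0.60–0.85) and a core, with
per-layer proton density and relaxation constants.  A seeded, smoothed
2%-SD multiplicative texture breaks exact uniformity.  Tissue values
(T2 35–45 ms, T2′ 22–30 ms) are *placeholders* chosen to give visible
T2\* contrast at short echo times; they are not measured OB values at
any particular field strength, and every function accepts overrides.
Pixel centers sit at ((i+0.5) − N/2)·Δ mm; x is the readout axis, y the
low-bandwidth (phase/SPEN) axis.

Region masks (`ob_left/ob_right`, `epl`, `glomerular_lateral`,
`background`, `noise_roi`) satisfy, by construction and by test:
hemispheres disjoint, laminae inside the bulb, background disjoint from
tissue.  The lateral glomerular sectors are the outward-facing (away
from midline) part of the rim.  The noise ROI is all background at
least 3 px clear of the object and 2 px off the frame, large enough that
its SD estimate contributes ≲1% to SNR variance.

**Air-interface field.**  Each perturber (air pocket) contributes an
analytic 2D dipole Δf = peak·(a/r)²·cos 2θ outside its disk of radius a
(clamped to `peak` inside), not a susceptibility FFT solver — the closed
form doubles as the test oracle and reproduces the qualitative behavior
(several hundred Hz near the interface decaying as 1/r²).  The default
field places two pockets anterior to the hemispheres (peak 750 Hz) and
one posterior (−600 Hz), giving −620 to +880 Hz across tissue — strong
but realistic for air/tissue interfaces at ultrahigh field, and enough
to displace EPI by several pixels.

## Sequences and encoding

All four sequences share TR 1 s, TE ≈ 26 ms, T_acq 26 ms, 2 coherent
averages (one volume per TR × averages = 2 s).

**EPI.**  The low-bandwidth axis is Fourier-encoded with
k_m = 2π(m − N/2)/L_y; the line acquired at time t carries its full
off-resonance evolution time (GE: t from excitation; SE: t − TE), which
yields the textbook displacement Δf·T_acq pixels (bandwidth per pixel
1/T_acq ≈ 38 Hz) and T2′ weighting growing away from the echo.

**SPEN.**  The chirp is modelled by its net quadratic phase
φₑ(y) = αy² + βy (instantaneous-inversion approximation), with
α = −πR/L_y² set by the chirp time–bandwidth product R and β fixed so
the stationary point y\*(t) = −(β + k(t))/2α sweeps linearly from
−L_y/2 to +L_y/2 over T_acq (k(t) is the blipped-gradient moment,
k(T_acq) − k(0) = 2|α|L_y).  Sample times t_m = (m+½)T_acq/N_y map
one-to-one onto pixel centers.

*Choice of R.*  R controls both the stationary-phase point-spread
(≈ L_y√(2/R)) and the residual off-resonance displacement
(Δf·T_acq·N_y/R pixels).  The default **R = 2000** (e.g. a 13 ms chirp
sweeping ~150 kHz) makes the SPEN displacement ~23× smaller than EPI's,
which is the regime the full-refocusing robustness claims describe; it
is attainable on preclinical gradient sets and is the package's own
design choice, with the high pulse power such chirps imply being exactly
the SAR cost noted for these sequences.

*Refocusing bookkeeping.*  Rather than tracking the pre-acquisition
delay explicitly, the timing table stores its net effect: the
off-resonance/T2\* evolution time per position at its own acquisition
moment, τ_resid ≡ 0 for FR and ≡ Δ (default 4 ms) for PR; during
acquisition τ(y, t) = τ_resid + (t − t\*(y)).  The placement of Δ within
the sequence is not otherwise modelled, and the final broadband rewind
pulse is phase-transparent.

*Discretisation.*  The encoding matrix uses a voxel (box) basis: entry
(m, n) is the exact Fresnel-integral of e^{i[φₑ(y)+k(t_m)y]} over pixel
n.  At R ≈ 2000 the chirp oscillates many times inside a pixel, and the
box basis is what keeps the discrete operator near-unitary (condition
number ≈ 10 at default settings) — pointwise sampling of the same phase
is badly aliased and numerically rank-deficient.  The off-resonance
phase is handled exactly as well: within a pixel it is linear in y (t\*
is linear), so its slope joins the Fresnel integral's linear coefficient
and only the pixel-constant part remains outside.  EPI, by contrast, is
point-sampled so that its samples are literally the 2D DFT of the
object (the round-trip oracle).

## Forward simulation and noise

Raw sample (m, readout column) =
Σ_n ρ(y_n)·E[m,n]·e^{i2πΔf(x,y_n)τ(y_n,t_m)}·e^{−t_abs(m)/T2}·e^{−|τ|/T2′}
with the readout axis an ideal Fourier dimension (all single-shot
artifact mechanisms act along y).  T2′ dephasing is Lorentzian
(exponential in |τ|); the T2 clock runs from excitation with the
acquisition window centered on TE.  Complex i.i.d. Gaussian noise of
standard deviation σ per component is added per sample and per average;
the 2 averages are summed coherently (signal ×2, noise variance ×2).
Multi-shot, partial Fourier, odd/even ghosting, eddy currents and RF
waveform effects are not modelled.

**Noise calibration.**  `calibrate_noise` finds σ such that the
reconstructed-image SNR — mean over the OB mask divided by the SD over
the background noise ROI, no Rician correction by default (a
Rayleigh-corrected option exists) — hits a target (default 30) within
10%, using the near-exact SNR ∝ 1/σ scaling plus secant refinement over
repeated noisy reconstructions.  Calibration always runs on the
homogeneous-field phantom: thermal noise is a coil/receiver property,
and distortion leakage into the background must not masquerade as noise.

## Reconstruction

EPI: centered inverse DFT, magnitude.  SPEN magnitude: |s(t_m)| assigned
to y\*(t_m) — a low-resolution image with no Fourier transform along y.
SPEN super-resolution: per readout column, ridge-regularised inversion
min_ρ ‖Aρ − s‖² + λ‖Dρ‖² (D identity by default, first-difference
optional), magnitude of the solution.  λ defaults to a discrepancy
estimate from the known noise level (0 for noiseless data, where the
solve matches the pseudo-inverse to machine precision).  Phase is
discarded after reconstruction; no coil-profile correction is applied.

## BOLD model

Activation is an odor-driven *decrease* of R2\*, partitioned
mechanistically: a fraction f (default 0.4) acts on 1/T2 (microvascular,
survives refocusing) and the rest on 1/T2′ (macrovascular/static), so
1/T2\* = 1/T2 + 1/T2′ is preserved per volume.  Each sequence then
responds through its own weighting times — f·ΔR2\* over TE plus
(1−f)·ΔR2\* over τ_resid — which yields the orderings the pipeline
verifies: GE-EPI ≥ PR-SPEN ≥ FR-SPEN in percent change, and PR slightly
above FR (e.g. 6.2% vs 5.0% at defaults).  The 40% fraction is a
modelling choice, not a measured value.

Default peak amplitude ΔR2\* = 5 s⁻¹: with f = 0.4, TE = 26 ms and
Δ = 4 ms this puts the PR-SPEN epoch-averaged peak percent change at
~6%, i.e. in the "exceeds 5% without statistics" regime the default
conditions are meant to represent.  The default odor level is 450 ppm
through a Hill response c^h/(c^h + c50^h) with c50 = 60 ppm and h = 1.5
— parameters chosen so the 60–700 ppm grid is monotone yet strongly
saturating (scale(700)/scale(300) < 1.25), consistent with physiological
odors rarely exceeding ~100 ppm.

The hemodynamic kernel is the canonical double-gamma (peak delay 6 s,
undershoot delay 16 s, ratio 1/6) applied unchanged to the mouse, as in
the workflow being reproduced; a faster rodent preset
(`RODENT_HRF`) is provided.  The stimulus boxcar ramps linearly over
10 s (olfactometer rise time).  An optional exponential adaptation term
exists but is off by default since 26 s blocks sit below the ≥40 s
adaptation regime.  Paradigm bookkeeping: 10 × (120 + 26) s = 1460 s
does not fit 700 × 2 s = 1400 s; the final baseline block is truncated,
and epoch averaging simply skips incomplete trailing epochs.

Nuisances: multiplicative drift (1% linear + 0.5% cosine of 300 s period
per run) and Poisson-timed single-volume in-plane translations
(transient displacement of the object; rotations and cumulative motion
are not modelled — enough to exercise the QC discard logic, no more).

## Analysis chain

First level: pixelwise OLS with task (HRF-convolved boxcar,
max-normalised), task × t and task × t² time-modulation columns
(mean-centred; the "second-order time modulation" accounting for
non-stationary response amplitude), a discrete-cosine drift basis up to
1/256 s (equivalent to high-pass filtering under OLS and easier to
test), and an intercept.  t = cᵀβ̂/√(σ̂²cᵀ(XᵀX)⁻¹c), df = N − rank(X);
exact zero residual variance yields an ±∞ sentinel rather than an
error.  Default threshold: uncorrected p < 0.001 (matching the maps
being reproduced); BH-FDR and permutation FWE are available because the
original workflow states corrections were applied without naming one.
Smoothing uses the stated 2.5 mm FWHM default but warns when the kernel
exceeds 25% of the object extent — 2.5 mm is large for an OB.

Second level: pooled-variance two-sample t (signed maps; both polarities
meaningful) and one-way ANOVA (F, (k−1, N−k) df), pixelwise across
co-registered first-level effect maps; phantom-born maps share a grid so
co-registration reduces to identity.  Odor-difference maps are pairwise
group-mean difference t-maps.

Permutation inference: two-group label permutation with the max-|t|
null; exhaustive enumeration whenever the number of distinct splits fits
the budget (3 vs 3 → exactly 20 splits; corrected p-values are multiples
of 1/20), otherwise random permutations including the observed
labelling.  Significance uses p ≤ α since attainable p-values are
discrete.

QC screen (all metrics reported; any violation discards): frame-to-frame
intensity spikes (|z| > 4 against a running-median residual *and* >1% of
the mean — the amplitude floor stops ultra-stable series from flagging
their own noise), center-of-mass jumps > 1 px, fitted linear drift
> 3%/run, and split-half (odd/even epochs, linearly detrended) response
correlation < 0.3.  The thresholds are package defaults chosen to
separate the simulated clean/corrupted regimes; the original criteria
were by-eye.

## Problem sizes and determinism

Everything is seeded; identical seeds give bit-identical phantoms, raw
data and runs.  One base seed expands via `numpy.random.SeedSequence`
into phantom/noise/calibration children (all < 2³¹).  The test suite
exercises full-geometry physics (96 × 70) but runs fMRI simulations at
48 × 36 with 4 events × 180 volumes, where per-run simulation takes ~1 s;
the acceptance script runs the full 700-volume protocol at full
geometry.  Statistical calibration tests use ≥2 × 10⁴ pixel-tests
(binomial 99% CI at p = 0.001) and 200 replicate null experiments for
permutation FWE.

## What the synthetic data do not show

The phantom's anatomy, relaxation values, activation amplitudes and
noise are idealised: no physiological (respiratory/cardiac) noise, no
anesthesia-depth or sex-difference mechanisms (amplitude scalings only),
no ghosting or partial-Fourier artifacts, no 3D susceptibility
modelling, no atlas registration.  Passing tests therefore establish
the *internal* correctness of encoding, reconstruction and statistics
under the stated model — not that real OB data at ultrahigh field will
show these effect sizes.  The FR ≈ PR distortion tie at the default
field is likewise a model statement: their Dice difference is below the
support-quantisation level, so tests treat them as equal within 0.01.
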