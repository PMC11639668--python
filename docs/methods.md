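# Methods

This note documents the models, numerical choices and known limitations of
`neoflow`. It describes what the code computes and why the defaults are
what they are; every empirical number quoted here is produced by the test
suite or by `scripts/acceptance.py`.

## Acquisition model

An ultrafast Doppler block is a complex IQ cube (depth × width × time) on
an isotropic beamformed grid. The compounded frame rate equals the pulse
repetition frequency divided by the number of tilted plane-wave angles,
and both it and the block duration are derived properties of
`AcquisitionParams`, so the sequence arithmetic cannot drift from its
inputs. Two presets mirror common practice: a high-velocity sequence
(PRF 9600 Hz, 3 angles → 3200 Hz; 2500 frames → 0.78 s) and a
high-sensitivity sequence (PRF 8000 Hz, 5 angles → 1600 Hz; 1600 frames →
1 s). The axial Doppler shift of blood moving at speed `V` is
`f = 2 V f_pulse cos θ / c0` with `c0 = 1540 m/s` and a 6 MHz probe by
default; the two-sided spectrum is sampled at the frame rate, giving a
Nyquist speed of 20.5 cm/s at 3200 Hz, doubled to 41.1 cm/s by
de-aliasing.

## Synthetic data: what it emulates, what it does not

The generator produces inputs with the statistical structure the pipeline
assumes, each paired with an exact `GroundTruth`:

* **Vessels** are straight or polyline tubes, 0.2–2 mm, with top-hat or
  Gaussian cross-lumen intensity (Gaussian std = radius, the model that
  underlies Hessian vesselness). Rendered images are blurred with an
  isotropic Gaussian point-spread function of 0.2 mm FWHM — the method's
  resolution limit — and the default grid samples it at 0.1 mm/pixel.
* **Blood signal**: every lumen pixel is a complex phasor with a random
  initial phase whose instantaneous frequency follows the Doppler law
  above (plug flow: one waveform per vessel; intra-lumen velocity
  profiles are not modelled). The amplitude map carries the same PSF,
  as a beamformed grid would.
* **Cardiac waveform**: a raised-cosine systolic upstroke (60 ms) and
  downstroke (90 ms) followed by an exponential diastolic decay
  (τ = 120 ms) over a 400 ms cycle (150 bpm, neonatal), rescaled so its
  extrema are exactly the requested PSV and EDV. Cohort heart rates and
  waveform shapes are not clinically constrained; they are configuration.
* **Tissue clutter** is an exact rank-`r` (default 5) sum of spatial
  modes times slowly varying (< 20 Hz) temporal modes, scaled 40 dB above
  the blood energy by default — the echogenicity gap that motivates SVD
  filtering. Crucially, all spatial modes share one magnitude map (a
  smooth lognormal echogenicity envelope) and differ in phase only,
  mimicking quasi-rigid tissue motion; this shared magnitude is what
  produces the bright diagonal block in the spatial-similarity matrix
  that adaptive rank selection exploits. The modes are mutually
  orthogonal by construction (phase harmonics of a smooth warp field)
  with decaying energies, so the planted clutter subspace is
  well-defined.
* **Noise** is complex white Gaussian; `noise_db` is the blood-to-noise
  energy ratio (20 dB default).

Blood, clutter and noise are stored separately and sum to the emitted
block exactly (machine precision), so every downstream estimate can be
scored against truth. The generator does **not** simulate acoustic wave
propagation, speckle, attenuation, or the acoustic texture of any physical
phantom — synthetic phantom recoveries therefore validate the estimator's
geometry and noise behaviour, not transducer physics, and real-data
performance can be worse in ways these tests cannot reveal (out-of-plane
vessels, motion, reverberation clutter).

Statistical cohorts (`make_cohort`) skip imaging entirely: each subject
draws a slope from N(0.08, 0.07) mm⁻¹ and an RI-in-small-vessels from
N(0.58, 0.08) — the population structure of a very preterm cohort's
anterior-cerebral-artery territory — and emits noisy skeleton measurement
tables, reproducibly under a seed.

## Clutter filtering

`svd_decompose` computes the exact thin SVD of the Casorati matrix
(depth-major flattening, documented and fixed). `svd_clutter_filter`
subtracts the rank-`r` truncation; energy therefore partitions exactly
(clutter + filtered = total) and filtered energy is non-increasing in
`r`.

The adaptive rank rule concretises the similarity-matrix idea (the
published sources describe it only by reference): form
`C(i,j) = |⟨|U_i|, |U_j|⟩|` from the **centred**, normalised magnitudes of
the spatial singular vectors. Centring matters at desk scale: the plain
cosine of two independent complex-Gaussian magnitude vectors is π/4 ≈
0.785, which leaves almost no contrast between tissue (≈ 0.9) and noise;
after removing the mean magnitude level, noise and blood similarities
drop to ≈ 0 while tissue stays ≈ 0.9. The profile `d(k)` is the mean
similarity of component `k` to its `w = 5` predecessors (a one-sided
diagonal band — the trailing side would mix post-block columns into the
estimate); the selected rank is the first `k` where `d(k)` falls below
the midpoint of the initial plateau (first 5 values) and the floor (last
20 %). Two guards make the rule safe outside its design regime:

* a **slow-time guard** caps the rank at the first component whose
  power-weighted mean |frequency| exceeds 50 Hz — tissue is slow, blood
  is not, so a clutter-free block yields rank 0 (identity filter) rather
  than deleting the dominant blood component;
* a degenerate profile (no plateau/floor contrast) falls back to a
  fixed-fraction rank with a warning, still capped by the slow-time
  guard.

A rank of 0 is deliberately allowed. On the default synthetic conditions
the rule recovers the planted rank 5 across seeds, suppresses clutter by
≈ 60 dB (≥ 30 dB required) and leaves the filtered lumen signal
correlated ≥ 0.99 with true blood. The rule is exposed as ordinary
function parameters so alternative strategies can be substituted.

## Morphology

Vesselness is a Jerman-type ratio-of-eigenvalues response: per scale,
`σ = scale/2` pixels (scales are vessel *diameters*; a tube of Gaussian
cross-section with std = radius responds maximally near σ = radius),
eigenvalues are σ²-normalised, and

```
V = λ2²(λρ − λ2)(3/(λ2 + λρ))³,  V = 1 where λ2 ≥ λρ/2 > 0,
λρ = max(λ2, τ·max λ2),  τ = 0.5
```

with signs flipped so bright ridges are positive. The response saturates
at 1 for strong ridges by design. Scales must lie strictly between the
pixel spacing and 3 mm, and sub-pixel kernels (σ < 1 px) are dropped:
below the PSF there is no anatomy, only speckle, and at σ < 1 px speckle
has the sharpest Hessian response in the image. Defaults: scales
{0.2, 0.4, 0.8, 1.2, 1.6} mm, mask threshold 0.15, minimum component
area 10 px — all configurable, and worth configuring: responses at scales
much larger than the vessels present only add halos that can bridge
neighbouring vessels (the bundled demo scene therefore uses {0.4, 0.8} mm
for its 0.3–0.8 mm tubes).

The skeleton is the medial axis (centres of maximal inscribed disks;
tie-breaking order pinned for reproducibility). Junctions — skeleton
pixels with ≥ 3 skeleton neighbours in 8-connectivity — and all skeleton
pixels within a Euclidean disk of radius 4 px (read literally in pixels)
are excluded, because FWHM overestimates diameters at crossings. Local
orientation is the principal axis of skeleton pixels in an 11 × 11 window
(the same window as the measurement, for consistency); θ ∈ (−π/2, π/2]
versus the image vertical.

The diameter at a skeleton pixel is the FWHM of the intensity sampled
(bilinear) along the line orthogonal to the vessel axis — 11 samples at
1 px spacing, equivalent to rotating the 11 × 11 neighbourhood so the
vessel is vertical and reading the central row. Numerical choices:

* the **baseline** is the profile minimum within the window (a global
  zero baseline misbehaves on elevated backgrounds); half maximum is
  measured above it;
* the **peak position** is the centroid of samples within 10 % of the
  maximum (on near-flat tops the plain argmax wanders with noise; ties at
  flat tops thus resolve to the plateau centre), and pixels whose peak
  sits more than 2 samples off-centre are discarded as mis-registered —
  a guard of this package, flagged in the quality column;
* crossings are located by linear interpolation between samples;
  profiles that do not cross half maximum on both sides inside the
  window, or whose window leaves the image, are flagged undefined rather
  than extrapolated.

The 11-sample window bounds the measurable FWHM at ~10 px; on a 0.1 mm
grid vessels much above 1 mm are increasingly flagged or underestimated
(power Doppler is an energy image, so profiles are squared amplitudes and
edges sharpen, biasing FWHM slightly low — a few hundredths of a mm at
these sizes). On synthetic three-tube phantoms (0.46/0.86/1.60 mm, 0.2 mm
PSF, 20 dB SNR, 0.2 mm pixels so the largest tube fits the window) median
recoveries are within ±10 % and strictly increasing; the stated property
is ±20 %.

## Spectral analysis

Windows are `round(0.040·frame_rate)` samples with a
`round(0.003·frame_rate)` hop (128/10 at 3200 Hz), Hann-tapered (the
taper is unstated in the sources; Hann is the unsurprising choice). Only
slices fully inside the record are kept — zero-padded border columns
otherwise masquerade as low-velocity samples and corrupt end-diastolic
landmarks. The "5-pixel neighbourhood" is a 5 × 5 square, truncated at
borders; magnitudes (not powers) are averaged. The 10 % noise floor is
relative to the whole averaged spectrogram's maximum (not per column) and
is idempotent.

De-aliasing decides the dominant flow sign by the time-integrated
signed-frequency power after flooring (ambiguity ratio 1.2; ambiguous
pixels are flagged and left untouched) and remaps the opposite half of
the spectrum onto the extension of the dominant side, doubling the
measurable |f|. It runs **before** mean-frequency estimation — the only
order that fixes the centroid bias. One physical caveat: a lone,
fully-wrapped narrowband tone is sign-ambiguous in principle (all of its
energy sits on the wrong side); the unidirectional-flow trick works
because real pulsatile spectra keep in-band (diastolic) energy that
anchors the sign. Verification uses that construction: a pulsatile trace
peaking at 0.7× frame rate is read back within ~1 % with de-aliasing and
is ~56 % wrong without.

Mean frequency is the power-weighted centroid per time step (the
alternative edge-fitting estimators in the literature are not
implemented); all-zero columns yield 0 and a flag. Image-wide cardiac
landmarks come from the mask-averaged spectrogram's speed trace: systolic
peaks by peak detection (minimum separation 250 ms, prominence 20 % of
the modulation), end-diastolic minima as the minimum between consecutive
peaks (plus a leading segment spanning at least half an inter-beat
interval); a trace whose relative modulation is below 10 % raises
"no cardiac signal". Per pixel, PSV/EDV are the extrema of the velocity
trace within ±6.25 ms of each global landmark, averaged across cycles
before forming RI (averaging reduces variance; the sources use singular
phrasing). A negative EDV (flow reversal) is flagged and reported as-is —
RI may exceed 1 there — never clamped.

Because RI is a ratio, the cos θ beam-angle factor cancels: simulated
vessels at 0°/30°/60° agree in RI to < 0.001 (requirement ≤ 0.03), and
scaling the IQ amplitude leaves every velocity quantity unchanged.

## Resistivity biomarkers

The artery/vein threshold fits a two-component univariate Gaussian
mixture to raw pooled RI values (the histogram phrasing in the sources is
treated as exposition) — EM, k-means initialisation, 20 restarts, 1e-6
tolerance, seeded — and returns the intersection of the *weighted*
component densities between the means (bracketed root find; closer means
than 0.05 trigger a unimodal warning and the midpoint). Against the
analytic density intersection of a known mixture the recovered threshold
is within ~0.001 at n = 10⁵. Per-dataset thresholds are recomputed; fixed
clinical thresholds can be passed instead for comparability.

Per acquisition, RI is regressed on diameter by ordinary least squares
(minimum 20 points, diameter span ≥ 0.3 mm, diameters below the 0.2 mm
resolution limit excluded); `ri_small` is the prediction at 0.2 mm. Group
mean regression averages member slopes and intercepts; the 95 % band is

```
ȳ ± 1.96·σ_y·√(1/n + (x − x̄)² / Σ(x_i − x̄)²)
```

with `σ_y` the ddof-1 standard deviation of member lines at `x̄`, the mean
of the diameter grid (0.2–2.0 mm, 0.05 mm steps), and the sum over the
grid. The radical is implemented in the standard mean-response form (its
printed extent is typographically ambiguous) and the 1.96 normal quantile
is kept as printed; both choices are recorded in the result metadata.
A known property of this construction: with σ_y *estimated* from n
members, the exact coverage of the band at x̄ is P(|t_{n−1}| ≤ 1.96) —
90.9 % at n = 8, not 95 % (a t quantile would restore nominal coverage
but is not what the formula states). The acceptance suite measures and
reports this honestly.

ROC analysis sweeps the unique scores, computes trapezoidal AUC —
verified exactly equal to the Mann–Whitney pair statistic — and returns
the Youden point (ties resolved to the lower threshold).

## Pipeline, determinism, problem sizes

`run_pipeline` chains simulate-or-load → filter → power Doppler →
morphology → spectral → regression, stamps every artefact with a hash of
the scientific configuration (paths and log level excluded) and derives
each stage's seed from the global seed and the stage name, so identical
config + seed reruns are byte-identical. Stage failures keep partial
artefacts and a machine-readable error report. Configuration is validated
against a published JSON schema with unknown keys rejected.

Verification problem sizes are chosen to exercise every mechanism while
staying desk-sized: single-vessel RI recovery uses 24 × 16 px blocks at
3200 Hz × 0.8 s (two cardiac cycles) over 100 seeds; the image-level
cohort uses six subjects of 64 × 80 px at 1600 Hz × 0.8 s, four vessels
of 0.3–0.8 mm each, pooled-GMM artery selection, then per-subject
regression — recovering a group slope within ~0.003 of the true
0.08 mm⁻¹ and mean RI-in-small-vessels within ~0.002 of the true 0.58.

## Known limitations

* 2-D only: no out-of-plane angle correction (absolute PSV/EDV are
  reported per pixel but are angle-biased; RI is the robust quantity).
* The FWHM window bounds measurable diameters (~10 px); choose the pixel
  spacing to match the vessel sizes of interest.
* The adaptive rank rule is this package's concretisation of a method the
  sources cite but do not specify; it is validated on the synthetic
  clutter model described above.
* Veins are modelled as strictly non-pulsatile; venous pulsatility
  (e.g. near the heart) would blur the artery/vein separation.
* No motion correction, beamforming or compounding: the pipeline starts
  at beamformed IQ.
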