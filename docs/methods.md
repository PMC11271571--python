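# Methods

This note documents the models implemented in `porepulse`, the defaults
and why they were chosen, the numerical choices, and what the synthetic
data do and do not establish about real measurements.

## Pore physics

The pore is modelled as a cylinder of diameter *d* and length *h* in an
electrolyte of resistivity *ρ*, with total resistance
*R = 4hρ/πd² + ρ/d*: the cylindrical channel in series with the access
resistance of the electrolyte converging on the two pore mouths. The
open-pore current is *I₀ = V/R*, exactly linear in voltage. Defaults:
*d* = 1.2 µm, *h* = 50 nm, *ρ* = 0.625 Ω·m (1× PBS, conductivity
1.6 S/m — a standard literature value; the resistivity is configurable).
At 0.1 V this gives 182.3 nA.

The hydrostatic drive from a chamber liquid-level difference *L* is
*P = ρ_f g L* with water density 1000 kg/m³ and *g* = 9.81 m/s², signed so
that positive *L* (higher cis level) drives cis → trans flow: 29.4 Pa at
*L* = 3 mm.

Bead size maps to blockade amplitude through a pure quadratic
*I_p = a·d²* fitted through the origin (volume displacement per unit pore
length scales with the particle cross-section for particles shorter than
the channel; no intercept is physically motivated). The default anchor is
a 1.5 nA mode for 300 nm beads, i.e. *a* = 1.667×10⁻⁵ nA/nm². The
detection floor is the diameter whose amplitude equals `detect_k` × the
baseline noise sigma; with the default 5σ rule and σ ≈ 0.21 nA this is
≈250 nm, consistent with sub-250 nm beads being lost in the noise.

Antigen mass concentrations convert to molarity with a default molar mass
of 34 kDa (prostate-specific antigen; 1 ng/mL ≡ 29.4 pM), configurable.

## Trace generator

The generator produces the statistical structure the assay analyses
assume, with exact ground truth:

* **Baseline and noise.** Constant baseline *I₀* from the pore model plus
  white Gaussian noise, default σ = 0.21 nA. Real traces additionally
  show drift and 1/f components; the detector's windowed-median baseline
  is designed to absorb slow drift but the generator does not emulate it.
* **Arrivals.** A homogeneous Poisson process with rate
  α × (particle concentration), α = 2.15×10⁻⁷ min⁻¹ per particles/mL,
  back-calculated from the observed ≈49 pulses/min at 2.3×10⁸ beads/mL.
  The rate is independent of particle size by construction. Saturation of
  the frequency at very high concentration is not modelled.
* **Pulse shape.** A raised-cosine dip whose FWHM equals the event's
  dwell time, so simulated and detected (FWHM-based) durations are
  directly comparable. Dwell times are lognormal around a mode of 1.1 ms
  with hydrostatic drive (1.8 ms without), log-sd 0.25. Overlapping
  events superpose; they are the model of coincidence waveforms.
* **Amplitudes.** The on-axis amplitude is *a·d²* for beads, or a lookup
  table (1.5, 2.8, 3.5, 6.0 nA for 1–4 beads) for aggregates — the
  printed cluster amplitudes deviate from an n^(2/3) volume law, so the
  lookup is used verbatim and clusters beyond four beads extrapolate as
  6.0·(n/4)^(2/3) as a documented approximation. Dispersion is
  deliberately one-sided: an axial transit gives the *minimal* blockade,
  and off-axis passage only enlarges it. Two components model this: a
  Bernoulli off-axis event (probability 0.2, factor 1.35, anchored to the
  observed secondary histogram modes at ≈1.35–1.4× the primary) and a
  half-normal enhancement 1 + |N(0, cv)| with cv = 0.04·(300 nm)/d_eff,
  so smaller particles disperse more. The 0.04 scale keeps within-mode
  widths small enough to resolve amplitude peaks 0.7 nA apart, as the
  measured histograms do. A symmetric (e.g. lognormal) jitter was
  rejected because it would put a large share of the 600 nm population
  below a classification cut that sits just under its mode, contradicting
  the cleanly separated histogram classes observed.
* **Aggregation.** Antigen binding follows a Langmuir isotherm:
  bound fraction *p = c/(c+K)*. The mean cluster size is
  *m = 1 + s + βp* and cluster sizes are shifted-geometric with that mean
  (the maximum-entropy choice given a mean; the true cluster-size law is
  not published). The particle concentration falls as (bead
  concentration)/m, which is what couples antigen dose to pulse
  frequency. Defaults: *K* = 0.294 pM, the geometric mid-point of the
  2.94 fM–29.4 pM dose ladder; *β* = 9.9, chosen so the simulated
  frequency at the top dose falls to ≈1/11 of the blank, matching the
  observed dose–response suppression; *s* = 0.05 for the small
  antigen-independent dimer background seen in blanks. A consequence of
  these constants is that the designed limit of detection of the
  synthetic dose ladder is its lowest positive dose (2.94 fM): at that
  dose the designed mean D sits ≈8 blank sampling-SDs above the blank.

A single top-level integer seed drives every draw through one
`numpy.random.Generator`; the seed is recorded in the trace and
propagated into output metadata.

## Pulse detector

* **Baseline**: median over non-overlapping 50 ms windows, linearly
  interpolated — statistically equivalent to a moving median at far lower
  cost, and robust to the ≤2% duty cycle of events.
* **Noise sigma**: 1.4826 × MAD of baseline-subtracted samples, then
  recomputed excluding samples more than k·σ/2 below baseline (a first
  detection pass), so pulse tails do not inflate it.
* **Detection**: maximal runs with depth > k·σ on the *raw* trace
  (k = 5); runs closer than 0.2 ms are merged — a simultaneous
  translocation remains one oversized event, mirroring how the assay
  treats coincidences; runs narrower than 3 samples are discarded as
  noise spikes. At 5σ with the width filter the false-event rate on pure
  noise is far below 1 per 10⁶ samples.
* **Features**: I_p is the maximum blockade depth after a 0.2 ms boxcar
  smooth. The smoothing is required for an unbiased amplitude: the raw
  maximum over a segment of noisy samples is biased upward by ≈2σ,
  whereas the smoothed estimator keeps |bias| below σ/2 while attenuating
  a 1.1 ms FWHM pulse by <1%. t_d is the full width at half of I_p
  (interpolated crossings walked outward from the peak); FWHM is
  noise-robust and independent of the detection threshold, and matches
  the generator's duration definition. Width at threshold crossing is
  available as an option. A one-sample segment degenerates to one sample
  period.

The exact conventions of the commercial extractor this re-implements are
unpublished; reported dwell-time modes can therefore only be qualitative
anchors, and the detector's contract is instead validated against the
generator's ground truth and a brute-force scanning oracle.

## Assay statistics

Mixing ratios use the k/N counting estimator per amplitude class, with
Wilson 95% intervals (stable at small counts; Wald intervals degenerate
there). An amplitude exactly on a cut point goes to the upper class — a
deterministic, documented tie-break. Coincidence candidates (I_p ≥ 6 nA
or t_d ≥ 5 ms for two-bead runs; ≥ 10 nA or ≥ 7 ms for three-bead runs)
are excluded before classification.

The aggregation degree is defined here as D = mean(I_p)/(monomer mode
amplitude): 1 for an ideal monomer-only table, invariant to pulse order
and table duplication, and strictly increasing when any pulse grows. The
original assay's dispersion statistic is defined only in unpublished
supplementary material; this implementation preserves its contract
(dispersion-based, monotone in aggregation, blank-referenced) and is
pluggable, but its numerical blank value is not comparable to published
ones.

The LOD rule is: threshold = blank mean + 3 × sample SD (n−1, ≥2 blank
replicates required); the LOD is the smallest tested concentration whose
replicate-mean D exceeds the threshold *and* whose larger tested
concentrations all exceed it too — the monotone-exceedance condition
guards against single-point excursions, which the bare ±3 SD line does
not. Replicates across pore modules aggregate as the mean of per-module
statistics.

When aggregation is active, pulse frequency falls with antigen dose, so
frequency is not inverted to a bead concentration in the dose–response
workflow; the two analyses are kept separate.

## Problem sizes and scaling

Simulated studies run at 20 kHz sampling (≥20 samples per pulse FWHM;
the instrument's 250 kHz adds fidelity the analyses do not need), chosen
as the package's standard desk-scale setting:

* Mixture study: two-bead runs 240 s at 4×10⁹ beads/mL, three-bead runs
  960 s at 1×10⁹ beads/mL — ≈3400 detected pulses per run, eleven runs.
* Dose-response modules: 60 s at 2.4×10⁹ beads/mL, three modules per
  concentration — ≈500 blank events per module, the same counting
  statistics as a 10-minute module at the assay's working concentration
  of ≈3.7×10⁸ beads/mL.

## Known limitations

* Electroosmotic/pressure flow fields, voltage-dependent sublinearity of
  amplitudes, pore clogging and serum-matrix nonspecific aggregation are
  out of scope; voltage scales amplitudes linearly if varied.
* The cluster-size law, off-axis mechanism and dwell-time distribution
  are plausible stand-ins constrained by printed summary values, not
  fitted to deposited raw data; passing tests demonstrate the *pipeline's*
  correctness on data with the assumed structure, not that real traces
  have exactly that structure.
* The D statistic is this package's definition (see above); published
  numerical D values are not reproduction targets.
* Detected amplitudes carry a small (+≈0.03–0.05 nA) residual upward
  bias from peak-picking in smoothed noise; it is shared by blanks and
  samples and cancels in blank-referenced analyses.
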