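# porepulse

A toolkit for resistive-pulse (Coulter-type) immunoassays on solid-state
micropores: it simulates ionic current–time traces of beads and
antigen-induced bead aggregates translocating a pore, detects the
translocation pulses, and runs the quantitative assay analyses —
concentration from pulse frequency, mixture deconvolution by amplitude
thresholds, coincidence filtering, and a blank-referenced
aggregation-degree statistic for antigen limit-of-detection estimation.

It is aimed at people developing or validating bead-counting pore assays
(e.g. latex-agglutination readouts on micropore sensors) who need a
reproducible, scriptable reference pipeline with ground-truth simulation.

## The physics and statistics in brief

**Pore model.** A pore of diameter *d* and length *h* in electrolyte of
resistivity *ρ* has resistance *R = 4hρ/πd² + ρ/d* (channel + access
term), so the open-pore current at voltage *V* is *I₀ = V/R*. A 1.2 µm
pore in a 50 nm membrane filled with 1× PBS (ρ = 0.625 Ω·m) carries
≈182 nA at 0.1 V. A liquid-level difference *L* between the chambers adds
a hydrostatic drive *P = ρ_f g L* (≈30 Pa at *L* = 3 mm).

**Pulses.** A particle transiting the pore blocks a volume-proportional
share of the conductance, producing a downward current spike with peak
amplitude *I_p* ∝ (particle diameter)² and dwell time *t_d* ~1 ms.
Arrivals are Poisson with rate proportional to particle concentration and
independent of particle size, so pulse frequency counts particles and the
*I_p* histogram sizes them.

**Assay statistics.** For a mixture, the fraction of pulses above an
amplitude cut estimates the mixing ratio (*k/N*, with Wilson intervals).
Antigen cross-links antibody-coated beads into clusters, shifting pulses
into larger-amplitude classes; the aggregation degree
*D* = mean(*I_p*)/(monomer mode amplitude) rises from 1 with aggregation,
and the limit of detection is the smallest tested concentration whose
replicate-mean *D* exceeds the blank mean + 3 SD (with all larger doses
also exceeding it).

## Worked example

Simulate two minutes of a 300/500 nm bead mixture (10% 500 nm by count,
4×10⁹ beads/mL total), detect the pulses, and recover the mixing ratio:

```python
import porepulse as pp
from porepulse.trace_sim import BeadSpec, synth_trace
from porepulse.quantify import (ClassThresholds, classify_pulses,
                                filter_coincidences, pulse_frequency)

print(round(pp.baseline_current(pp.DEFAULT_PORE, 0.1) * 1e9, 1))  # 182.3 nA

cfg = pp.MeasurementConfig(duration_s=120.0, sampling_rate_hz=20_000.0)
beads = [BeadSpec(300, 3.6e9, "300nm"), BeadSpec(500, 4e8, "500nm")]
trace = synth_trace(cfg, pp.DEFAULT_PORE, beads, pp.DEFAULT_CALIBRATION, seed=42)
table = pp.detect(trace)
print(len(table), round(pulse_frequency(table), 1))  # 1683 pulses, 841.5 /min

kept = filter_coincidences(table, 6.0, 5.0)  # drop simultaneous-translocation candidates
est = classify_pulses(kept, ClassThresholds((3.0,), ("300nm", "500nm")))
print(round(100 * est.fractions[1], 1))  # 10.6 (% of 500 nm beads; truth 10.0)
```

The 182.3 nA is the closed-form open-pore current; 841.5 pulses/min is
the detected event rate (≈ 2.15×10⁻⁷ min⁻¹ per beads/mL × 4×10⁹/mL); the
10.6 % estimate of the designed 10.0 % fraction is the *k/N* counting
estimator after classifying each pulse at the 3 nA amplitude cut.

The same workflows are available from a shell:

```sh
porepulse simulate --config run.json --seed 7 --out trace.bin
porepulse detect --input trace.bin --out pulses.tsv
porepulse quantify-mixture --input pulses.tsv --out mixture.json
porepulse lod --simulate-fixture --seed 1 --out lod.json
```

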