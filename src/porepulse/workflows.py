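"""End-to-end study pipelines: simulate -> detect -> quantify.

These wire the generator, detector and assay statistics into the two
benchmark experiments the toolkit reproduces at desk scale:

* ``mixture_ratio_study`` — two-bead (300/500 nm) and three-bead
  (300/500/600 nm) mixing-ratio estimation by amplitude thresholds, with
  coincidence exclusion, reporting per-run counting errors;
* ``dose_response_study`` — an antigen dilution ladder measured in
  replicate modules, yielding pulse frequencies and aggregation degrees
  for the blank-referenced limit-of-detection rule.

Simulated traces here use 20 kHz sampling (>= 20 samples per pulse FWHM);
dose-response modules are 60 s at 2.4e9 beads/mL, which preserves the
per-module event count of a 10-min module at the assay's working bead
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pore_physics import (
    DEFAULT_CALIBRATION,
    DEFAULT_PORE,
    MeasurementConfig,
)
from .pulse_detection import DetectorSettings, PulseTable, detect
from .quantify import (
    ClassThresholds,
    DoseResponse,
    classify_pulses,
    coincidence_fraction,
    filter_coincidences,
    lod_from_dose_response,
    mixture_error,
    pulse_frequency,
    aggregation_degree,
)
from .trace_sim import (
    AggregationParams,
    BeadSpec,
    OffAxisModel,
    aggregation_state,
    event_rate,
    predicted_pulse_moments,
    synth_trace,
)

__all__ = [
    "TWO_BEAD_FRACTIONS",
    "THREE_BEAD_RATIOS",
    "PSA_LADDER_MOLAR",
    "MixtureRun",
    "MixtureStudyResult",
    "mixture_ratio_study",
    "dose_response_study",
    "designed_lod",
    "derive_seed",
]

#: Designed 500-nm fractions of the two-bead runs.
TWO_BEAD_FRACTIONS = (0.0, 0.01, 0.025, 0.05, 0.10, 0.20, 0.40)

#: Designed 300:500:600 nm ratios of the three-bead runs.
THREE_BEAD_RATIOS = ((1, 3, 2), (2, 3, 1), (3, 1, 2), (3, 2, 1))

#: Antigen dilution ladder: blank plus 2.94 fM .. 29.4 pM in decade steps.
PSA_LADDER_MOLAR = (0.0, 2.94e-15, 2.94e-14, 2.94e-13, 2.94e-12, 2.94e-11)

TWO_BEAD_TOTAL_PER_ML = 4e9
THREE_BEAD_TOTAL_PER_ML = 1e9
TWO_BEAD_CUTS = ClassThresholds((3.0,), ("300nm", "500nm"))
THREE_BEAD_CUTS = ClassThresholds((3.0, 5.9), ("300nm", "500nm", "600nm"))
TWO_BEAD_COINCIDENCE = (6.0, 5.0)   # Ip nA, td ms
THREE_BEAD_COINCIDENCE = (10.0, 7.0)


def derive_seed(base_seed: int, index: int) -> int:
    """Per-run seed derived from one top-level seed; stays below 2^31."""
    return (base_seed * 1009 + index) % (2**31)


@dataclass(frozen=True)
class MixtureRun:
    kind: str
    actual_pct: tuple
    estimated_pct: tuple
    errors_pp: tuple
    n_pulses: int
    coincidence_fraction: float
    seed: int


@dataclass
class MixtureStudyResult:
    runs: list = field(default_factory=list)

    @property
    def max_error_pp(self) -> float:
        return max(max(r.errors_pp) for r in self.runs)

    @property
    def mean_error_pp(self) -> float:
        return float(np.mean([e for r in self.runs for e in r.errors_pp]))

    @property
    def total_pulses(self) -> int:
        return sum(r.n_pulses for r in self.runs)


def _simulate_mixture_table(
    beads, duration_s, seed, sampling_rate_hz, settings
) -> PulseTable:
    cfg = MeasurementConfig(duration_s=duration_s, sampling_rate_hz=sampling_rate_hz)
    trace = synth_trace(cfg, DEFAULT_PORE, beads, DEFAULT_CALIBRATION, seed=seed)
    return detect(trace, settings)


def mixture_ratio_study(
    seed: int = 1,
    *,
    sampling_rate_hz: float = 20_000.0,
    two_bead_duration_s: float = 240.0,
    three_bead_duration_s: float = 960.0,
    settings: DetectorSettings | None = None,
) -> MixtureStudyResult:
    """Run all eleven mixture benchmarks and their counting analysis.

    Two-bead runs mix 300/500 nm beads at a total of 4e9 beads/mL with
    500-nm fractions 0–40 %; three-bead runs mix 300/500/600 nm at 1e9
    beads/mL in four designed ratios.  Durations are sized so each run
    yields well over 2000 detected pulses.  Coincidence candidates
    (I_p >= 6 nA or t_d >= 5 ms for two beads; >= 10 nA or >= 7 ms for
    three) are excluded before classification at the 3.0 / 5.9 nA cuts.
    """
    settings = settings or DetectorSettings()
    result = MixtureStudyResult()
    run_index = 0
    for frac in TWO_BEAD_FRACTIONS:
        run_seed = derive_seed(seed, run_index)
        beads = [
            BeadSpec(300.0, (1.0 - frac) * TWO_BEAD_TOTAL_PER_ML, "300nm"),
            BeadSpec(500.0, frac * TWO_BEAD_TOTAL_PER_ML, "500nm"),
        ]
        table = _simulate_mixture_table(
            beads, two_bead_duration_s, run_seed, sampling_rate_hz, settings
        )
        coinc = coincidence_fraction(table, *TWO_BEAD_COINCIDENCE)
        kept = filter_coincidences(table, *TWO_BEAD_COINCIDENCE)
        est = classify_pulses(kept, TWO_BEAD_CUTS)
        actual = (100.0 * (1.0 - frac), 100.0 * frac)
        estimated = tuple(100.0 * est.fractions)
        err = mixture_error(estimated, actual)
        result.runs.append(
            MixtureRun(
                kind="two-bead",
                actual_pct=actual,
                estimated_pct=estimated,
                errors_pp=tuple(err.per_class_pp),
                n_pulses=len(table),
                coincidence_fraction=coinc,
                seed=run_seed,
            )
        )
        run_index += 1
    for ratio in THREE_BEAD_RATIOS:
        run_seed = derive_seed(seed, run_index)
        total = sum(ratio)
        beads = [
            BeadSpec(d, r / total * THREE_BEAD_TOTAL_PER_ML, f"{d:g}nm")
            for d, r in zip((300.0, 500.0, 600.0), ratio)
        ]
        table = _simulate_mixture_table(
            beads, three_bead_duration_s, run_seed, sampling_rate_hz, settings
        )
        coinc = coincidence_fraction(table, *THREE_BEAD_COINCIDENCE)
        kept = filter_coincidences(table, *THREE_BEAD_COINCIDENCE)
        est = classify_pulses(kept, THREE_BEAD_CUTS)
        actual = tuple(100.0 * r / total for r in ratio)
        estimated = tuple(100.0 * est.fractions)
        err = mixture_error(estimated, actual)
        result.runs.append(
            MixtureRun(
                kind="three-bead",
                actual_pct=actual,
                estimated_pct=estimated,
                errors_pp=tuple(err.per_class_pp),
                n_pulses=len(table),
                coincidence_fraction=coinc,
                seed=run_seed,
            )
        )
        run_index += 1
    return result


def dose_response_study(
    seed: int = 1,
    *,
    concentrations_molar=PSA_LADDER_MOLAR,
    n_replicates: int = 3,
    bead_concentration_per_ml: float = 2.4e9,
    bead_diameter_nm: float = 300.0,
    duration_s: float = 60.0,
    sampling_rate_hz: float = 20_000.0,
    params: AggregationParams | None = None,
    off_axis: OffAxisModel | None = None,
    settings: DetectorSettings | None = None,
) -> DoseResponse:
    """Simulate an antigen dilution ladder in replicate pore modules.

    For each concentration and replicate: form the aggregation state,
    synthesise a trace, detect pulses, and record the pulse frequency and
    aggregation degree D (normalised by the monomer mode amplitude).
    """
    params = params or AggregationParams()
    off_axis = off_axis or OffAxisModel()
    settings = settings or DetectorSettings()
    beads = BeadSpec(bead_diameter_nm, bead_concentration_per_ml, "antibody-bead")
    cfg = MeasurementConfig(duration_s=duration_s, sampling_rate_hz=sampling_rate_hz)
    freqs, ds = [], []
    for i, conc in enumerate(concentrations_molar):
        state = aggregation_state(conc, beads, params)
        rep_f, rep_d = [], []
        for rep in range(n_replicates):
            run_seed = derive_seed(seed, i * n_replicates + rep)
            trace = synth_trace(
                cfg,
                DEFAULT_PORE,
                state,
                DEFAULT_CALIBRATION,
                seed=run_seed,
                aggregation_params=params,
                off_axis=off_axis,
            )
            table = detect(trace, settings)
            rep_f.append(pulse_frequency(table))
            rep_d.append(aggregation_degree(table, params.amplitude_table_na[0]))
        freqs.append(rep_f)
        ds.append(rep_d)
    return DoseResponse(
        concentrations_molar=list(concentrations_molar),
        frequencies_per_min=freqs,
        d_values=ds,
    )


def designed_lod(
    concentrations_molar=PSA_LADDER_MOLAR,
    *,
    bead_concentration_per_ml: float = 2.4e9,
    bead_diameter_nm: float = 300.0,
    duration_s: float = 60.0,
    params: AggregationParams | None = None,
    off_axis: OffAxisModel | None = None,
) -> float | None:
    """Design-level LOD of the synthetic dose ladder, no simulation involved.

    Computes each concentration's expected D and the blank's expected
    replicate-mean sampling SD in closed form from the generator model,
    applies the same (blank + 3 SD, monotone exceedance) rule as the
    pipeline, and returns the concentration the design predicts.  Serves as
    the independent expectation for end-to-end recovery checks.
    """
    params = params or AggregationParams()
    off_axis = off_axis or OffAxisModel()
    beads = BeadSpec(bead_diameter_nm, bead_concentration_per_ml)
    mono = params.amplitude_table_na[0]

    def moments(conc):
        state = aggregation_state(conc, beads, params)
        mean, var = predicted_pulse_moments(state, params, DEFAULT_CALIBRATION, off_axis)
        n_expected = event_rate(state.particle_concentration_per_ml) * duration_s / 60.0
        return mean / mono, np.sqrt(var) / mono / np.sqrt(n_expected)

    d_blank, sd_blank = moments(0.0)
    threshold = d_blank + 3.0 * sd_blank
    positives = sorted(c for c in concentrations_molar if c > 0)
    exceeds = [moments(c)[0] > threshold for c in positives]
    for i, conc in enumerate(positives):
        if all(exceeds[i:]):
            return conc
    return None


def lod_study(seed: int = 1, **kwargs):
    """Dose-response simulation followed by the LOD rule; convenience."""
    dr = dose_response_study(seed, **kwargs)
    return lod_from_dose_response(dr), dr
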