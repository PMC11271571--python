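"""Assay statistics for resistive-pulse bead counting.

Covers the quantitative analyses of the bead-counting immunoassay:

* pulse frequency and its proportional calibration against particle
  concentration (one pulse = one particle, so frequency counts beads);
* amplitude-threshold classification of mixtures (the k/N estimator with
  Wilson binomial intervals) and its error metrics;
* coincidence filtering by joint I_p / t_d cuts (simultaneous translocations
  produce single oversized waveforms);
* the aggregation degree D — mean pulse amplitude normalised by the monomer
  mode amplitude, 1 for an ideal pure-monomer sample and strictly increasing
  as events shift into larger cluster classes;
* the blank-referenced limit of detection: the smallest tested antigen
  concentration whose replicate-mean D exceeds (blank mean + 3 SD), with
  every larger tested concentration also exceeding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .pulse_detection import PulseTable

__all__ = [
    "ClassThresholds",
    "MixtureEstimate",
    "MixtureError",
    "DoseResponse",
    "LODResult",
    "pulse_frequency",
    "fit_frequency_calibration",
    "estimate_concentration",
    "classify_pulses",
    "mixture_error",
    "coincidence_fraction",
    "filter_coincidences",
    "aggregation_degree",
    "lod_from_dose_response",
]


def pulse_frequency(table: PulseTable) -> float:
    """Events per minute: count / duration."""
    if table.duration_s <= 0:
        raise ValueError("table duration must be > 0")
    return len(table) * 60.0 / table.duration_s


def fit_frequency_calibration(pairs) -> float:
    """Slope alpha of frequency = alpha * concentration, through the origin.

    ``pairs`` are (concentration per mL, frequency per min) points; at least
    one, not all concentrations zero.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("at least one (concentration, frequency) pair required")
    c = np.asarray([p[0] for p in pairs], dtype=float)
    f = np.asarray([p[1] for p in pairs], dtype=float)
    if np.all(c == 0):
        raise ValueError("all-zero concentrations cannot be fitted")
    return float(np.sum(c * f) / np.sum(c**2))


def estimate_concentration(frequency_per_min: float, rate_coeff: float) -> float:
    """Invert the proportional calibration: concentration = frequency / alpha."""
    if rate_coeff <= 0:
        raise ValueError("rate coefficient must be > 0")
    return frequency_per_min / rate_coeff


@dataclass(frozen=True)
class ClassThresholds:
    """Ascending amplitude cut points (nA) separating size classes.

    ``len(labels) == len(cut_points) + 1``.  An amplitude exactly equal to a
    cut point is assigned to the upper class (deterministic tie-break).
    """

    cut_points: tuple
    labels: tuple = ()

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cut_points, dtype=float)
        if cuts.size and np.any(np.diff(cuts) <= 0):
            raise ValueError("cut_points must be strictly ascending")
        if self.labels and len(self.labels) != cuts.size + 1:
            raise ValueError("need exactly one more label than cut point")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"class{i}" for i in range(cuts.size + 1))
            )


@dataclass(frozen=True)
class MixtureEstimate:
    """Per-class counts, fractions and Wilson 95% intervals; k_i sum to N."""

    counts: np.ndarray
    total: int
    fractions: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    labels: tuple


def classify_pulses(table: PulseTable, thresholds: ClassThresholds) -> MixtureEstimate:
    """Assign every pulse to an amplitude class and estimate class fractions.

    The fraction of class i is the k/N counting estimator; intervals are
    Wilson score intervals (stable at small k).  An empty table returns zero
    counts with NaN fractions.
    """
    cuts = np.asarray(thresholds.cut_points, dtype=float)
    n_classes = cuts.size + 1
    ip = table.ip_na
    n = len(ip)
    if n == 0:
        nan = np.full(n_classes, np.nan)
        return MixtureEstimate(
            counts=np.zeros(n_classes, dtype=int),
            total=0,
            fractions=nan,
            ci_low=nan.copy(),
            ci_high=nan.copy(),
            labels=thresholds.labels,
        )
    idx = np.digitize(ip, cuts)  # boundary value -> upper class
    counts = np.bincount(idx, minlength=n_classes)
    low, high = proportion_confint(counts, n, alpha=0.05, method="wilson")
    return MixtureEstimate(
        counts=counts,
        total=n,
        fractions=counts / n,
        ci_low=np.asarray(low, dtype=float),
        ci_high=np.asarray(high, dtype=float),
        labels=thresholds.labels,
    )


@dataclass(frozen=True)
class MixtureError:
    """Absolute per-class mixing-ratio errors, in percentage points."""

    per_class_pp: np.ndarray
    max_pp: float
    mean_pp: float


def mixture_error(estimated_pct, actual_pct) -> MixtureError:
    """Elementwise |estimated - actual| of class percentages."""
    est = np.asarray(estimated_pct, dtype=float)
    act = np.asarray(actual_pct, dtype=float)
    if est.shape != act.shape:
        raise ValueError("estimated and actual fraction vectors differ in length")
    err = np.abs(est - act)
    return MixtureError(per_class_pp=err, max_pp=float(err.max()), mean_pp=float(err.mean()))


def coincidence_fraction(table: PulseTable, ip_cut_na: float, td_cut_ms: float) -> float:
    """Share of events with I_p >= ip_cut OR t_d >= td_cut.

    Events beyond both single-particle ranges are simultaneous-translocation
    candidates; this fraction quantifies how rare they are.
    """
    if len(table) == 0:
        raise ValueError("coincidence fraction is undefined for an empty table")
    mask = (table.ip_na >= ip_cut_na) | (table.td_ms >= td_cut_ms)
    return float(mask.mean())


def filter_coincidences(table: PulseTable, ip_cut_na: float, td_cut_ms: float) -> PulseTable:
    """Copy of the table with coincidence candidates removed."""
    keep = [
        r for r in table.records if not (r.ip_na >= ip_cut_na or r.td_ms >= td_cut_ms)
    ]
    meta = dict(table.metadata)
    meta["coincidence_filter"] = {"ip_cut_na": ip_cut_na, "td_cut_ms": td_cut_ms}
    return PulseTable(records=keep, duration_s=table.duration_s, metadata=meta)


def aggregation_degree(table: PulseTable, mono_amplitude_na: float) -> float:
    """Aggregation degree D: mean pulse amplitude over the monomer mode.

    D = 1 for an ideal pure-monomer table and increases strictly whenever
    any pulse amplitude increases; invariant to pulse order and to
    duplication of the whole table.
    """
    if mono_amplitude_na <= 0:
        raise ValueError("mono_amplitude_na must be > 0")
    if len(table) == 0:
        raise ValueError("aggregation degree is undefined for an empty table")
    return float(table.ip_na.mean() / mono_amplitude_na)


@dataclass
class DoseResponse:
    """Replicate frequencies and D values per antigen concentration.

    ``concentrations_molar`` must be unique and >= 0; a 0 M entry holds the
    blank (negative-control) replicates.
    """

    concentrations_molar: list
    frequencies_per_min: list  # list of per-concentration replicate lists
    d_values: list

    def __post_init__(self) -> None:
        c = list(self.concentrations_molar)
        if len(set(c)) != len(c):
            raise ValueError("concentrations must be unique")
        if any(x < 0 for x in c):
            raise ValueError("concentrations must be >= 0")
        if not (len(c) == len(self.frequencies_per_min) == len(self.d_values)):
            raise ValueError("per-concentration lists must align")

    def to_csv(self, path) -> None:
        rows = []
        for conc, freqs, ds in zip(
            self.concentrations_molar, self.frequencies_per_min, self.d_values
        ):
            for rep, (f, d) in enumerate(zip(freqs, ds)):
                rows.append(
                    {"conc_molar": conc, "replicate_id": rep, "frequency_per_min": f, "D": d}
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseResponse":
        df = pd.read_csv(path)
        required = {"conc_molar", "replicate_id", "frequency_per_min", "D"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        concs, freqs, ds = [], [], []
        for conc, grp in df.groupby("conc_molar", sort=True):
            grp = grp.sort_values("replicate_id")
            concs.append(float(conc))
            freqs.append(list(grp["frequency_per_min"].astype(float)))
            ds.append(list(grp["D"].astype(float)))
        return cls(concentrations_molar=concs, frequencies_per_min=freqs, d_values=ds)


@dataclass(frozen=True)
class LODResult:
    """Blank-referenced detection threshold and the resulting LOD."""

    threshold_d: float
    blank_mean: float
    blank_sd: float
    lod_molar: float | None  # None = not detected within the tested range
    per_concentration: tuple = field(default_factory=tuple)


def lod_from_dose_response(dr: DoseResponse) -> LODResult:
    """Limit of detection from a dose-response table.

    The detection threshold is the blank mean plus three sample standard
    deviations (n-1) of the blank replicates; the LOD is the smallest tested
    concentration whose replicate-mean D exceeds the threshold with every
    larger tested concentration also exceeding it (a single-point excursion
    does not qualify).  Requires at least two blank replicates and one
    positive concentration.
    """
    try:
        i_blank = dr.concentrations_molar.index(0.0)
    except ValueError:
        raise ValueError("dose response must include a 0 M blank") from None
    blanks = np.asarray(dr.d_values[i_blank], dtype=float)
    if blanks.size < 2:
        raise ValueError("at least two blank replicates required")
    positives = sorted(
        (c, np.mean(dr.d_values[i]))
        for i, c in enumerate(dr.concentrations_molar)
        if c > 0
    )
    if not positives:
        raise ValueError("at least one positive concentration required")
    blank_mean = float(blanks.mean())
    blank_sd = float(blanks.std(ddof=1))
    threshold = blank_mean + 3.0 * blank_sd
    exceeds = [mean_d > threshold for _, mean_d in positives]
    lod = None
    for i in range(len(positives)):
        if all(exceeds[i:]):
            lod = positives[i][0]
            break
    per_conc = tuple(
        {"conc_molar": c, "mean_D": float(m), "exceeds": bool(e)}
        for (c, m), e in zip(positives, exceeds)
    )
    return LODResult(
        threshold_d=threshold,
        blank_mean=blank_mean,
        blank_sd=blank_sd,
        lod_molar=lod,
        per_concentration=per_conc,
    )
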