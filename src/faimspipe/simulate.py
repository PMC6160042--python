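"""Synthetic FAIMS cohort generator.

The clinical cohort this pipeline was designed around is not publicly
deposited, so development and testing run on synthetic cohorts that
reproduce the *structure* of the real data:

* per sample, three consecutive runs of two polarity grids
  (512 compensation-voltage rows × 51 dispersion-field columns);
* each grid is a low baseline plus a high-intensity reactant-ion ridge
  plus a handful of analyte peaks — anisotropic Gaussians whose row
  centre drifts linearly with the dispersion-field column, mimicking
  the curved traces of real dispersion plots;
* a subset of peaks ("markers") carries the class signal: case samples
  multiply those peak amplitudes by ``1 + effect_size``;
* a subset of peaks is volatile: their amplitude decays by
  ``run_decay`` per successive run, emulating sample degradation over
  the three measurements;
* demographics are drawn with class-dependent moments matching the
  pilot cohort (case BMI 38.3 ± 10.5 vs control 28.1 ± 5.96; mean ages
  57 vs 45; mean alcohol 2 vs 5 units/week; male fractions 43/72 vs
  17/43), interpolated toward the pooled moments by the ``confounding``
  knob so demographic confounding can be switched off.

Everything is determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import DEFAULT_COLS, DEFAULT_ROWS, FAIMSRun, IonMatrix, SampleRecord

__all__ = ["SynthSpec", "MarkerWindow", "generate_cohort", "planted_truth"]


# Pooled vs per-class demographic moments of the pilot cohort.
_DEMO = {
    "case": dict(age=57.0, bmi=38.3, bmi_sd=10.5, alcohol=2.0, male=43 / 72),
    "control": dict(age=45.0, bmi=28.1, bmi_sd=5.96, alcohol=5.0, male=17 / 43),
    "pooled": dict(age=53.0, bmi=34.5, bmi_sd=10.3, alcohol=3.0, male=60 / 115),
}
_AGE_SD = 12.0  # not reported for the cohort; a typical adult-cohort spread


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic cohort.

    effect_size is the fractional amplitude increment of marker peaks in
    cases; run_decay the per-run multiplicative attenuation of volatile
    peaks; confounding ∈ [0, 1] scales the class separation of the
    demographic covariates (1 reproduces the pilot cohort's mismatch,
    0 removes it).
    """

    n_case: int = 60
    n_control: int = 60
    rows: int = DEFAULT_ROWS
    cols: int = DEFAULT_COLS
    n_peaks: int = 6
    marker_peaks: tuple[int, ...] = (0, 1)
    volatile_peaks: tuple[int, ...] = (0, 1)
    effect_size: float = 0.5
    drift_slope: float = 1.5  # rows of CV shift per dispersion-field column
    peak_width: tuple[float, float] = (12.0, 6.0)  # Gaussian sigma (rows, cols)
    run_decay: float = 0.85
    noise_sd: float = 0.05
    amp_cv: float = 0.15  # per-sample lognormal amplitude variability
    baseline: float = 0.02
    confounding: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")
        if not 0 <= self.run_decay <= 1:
            raise ValueError("run_decay must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(m >= self.n_peaks or m < 0 for m in self.marker_peaks):
            raise ValueError("marker peak index out of range")
        if any(v >= self.n_peaks or v < 0 for v in self.volatile_peaks):
            raise ValueError("volatile peak index out of range")


@dataclass(frozen=True)
class MarkerWindow:
    """Grid window covering one marker peak (±2σ around its trace)."""

    peak_index: int
    polarity: str
    row_lo: int
    row_hi: int  # exclusive
    col_lo: int
    col_hi: int  # exclusive, in single-polarity column coordinates

    def grid_cols(self, cols: int) -> tuple[int, int]:
        """Column window on the combined rows × 2·cols grid."""
        offset = 0 if self.polarity == "positive" else cols
        return self.col_lo + offset, self.col_hi + offset


def _peak_layout(spec: SynthSpec) -> dict:
    """Cohort-level chemistry: peak centres, polarities, base amplitudes.

    Drawn from a dedicated stream so grids and demographics stay
    reproducible independently of cohort size.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    rows, cols = spec.rows, spec.cols
    drift_span = spec.drift_slope * cols
    lo = 0.1 * rows
    hi = max(lo + 1, 0.85 * rows - drift_span)
    return {
        "row0": rng.uniform(lo, hi, size=spec.n_peaks),
        "col0": rng.uniform(0.2 * cols, 0.8 * cols, size=spec.n_peaks),
        "polarity": rng.integers(0, 2, size=spec.n_peaks),  # 0=positive
        "amp": rng.uniform(0.8, 1.5, size=spec.n_peaks),
        "rip_row": 0.9 * rows,
    }


def _render_grid(
    spec: SynthSpec,
    layout: dict,
    peak_amps: np.ndarray,
    polarity_code: int,
    rng: np.random.Generator,
) -> np.ndarray:
    rows, cols = spec.rows, spec.cols
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    sig_r, sig_c = spec.peak_width
    grid = np.full((rows, cols), spec.baseline)
    # reactant-ion ridge: strong, class-independent, present in both polarities
    rip_centre = layout["rip_row"] - spec.drift_slope * c
    grid += 5.0 * np.exp(-0.5 * ((r - rip_centre) / (2.0 * sig_r)) ** 2)
    for k in range(spec.n_peaks):
        if layout["polarity"][k] != polarity_code:
            continue
        centre = layout["row0"][k] + spec.drift_slope * c
        gauss = np.exp(
            -0.5 * ((r - centre) / sig_r) ** 2 - 0.5 * ((c - layout["col0"][k]) / sig_c) ** 2
        )
        grid += peak_amps[k] * gauss
    grid += rng.normal(0.0, spec.noise_sd, size=grid.shape)
    return np.clip(grid, 0.0, None)


def generate_cohort(spec: SynthSpec) -> tuple[list[FAIMSRun], list[SampleRecord]]:
    """Three runs per sample plus metadata, fully determined by the seed."""
    layout = _peak_layout(spec)
    n = spec.n_case + spec.n_control
    labels = ["case"] * spec.n_case + ["control"] * spec.n_control
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    runs: list[FAIMSRun] = []
    records: list[SampleRecord] = []
    demo_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    for i, (sid, label) in enumerate(zip(sample_ids, labels)):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303, i]))
        amps = layout["amp"] * rng.lognormal(0.0, spec.amp_cv, size=spec.n_peaks)
        if label == "case":
            for m in spec.marker_peaks:
                amps[m] *= 1.0 + spec.effect_size
        for run_index in (1, 2, 3):
            run_amps = amps.copy()
            for v in spec.volatile_peaks:
                run_amps[v] *= spec.run_decay ** (run_index - 1)
            pos = IonMatrix("positive", _render_grid(spec, layout, run_amps, 0, rng))
            neg = IonMatrix("negative", _render_grid(spec, layout, run_amps, 1, rng))
            runs.append(FAIMSRun(sid, run_index, pos, neg))
        records.append(_draw_record(sid, label, spec.confounding, demo_rng))
    return runs, records


def _interp(pooled: float, group: float, c: float) -> float:
    return pooled + c * (group - pooled)


def _draw_record(
    sid: str, label: str, confounding: float, rng: np.random.Generator
) -> SampleRecord:
    g, p = _DEMO[label], _DEMO["pooled"]
    age = rng.normal(_interp(p["age"], g["age"], confounding), _AGE_SD)
    bmi_sd = _interp(p["bmi_sd"], g["bmi_sd"], confounding)
    bmi = rng.normal(_interp(p["bmi"], g["bmi"], confounding), bmi_sd)
    alcohol_mean = _interp(p["alcohol"], g["alcohol"], confounding)
    # gamma with shape 2: right-skewed weekly units, mean as specified
    alcohol = rng.gamma(2.0, alcohol_mean / 2.0)
    male_p = _interp(p["male"], g["male"], confounding)
    sex = "M" if rng.random() < male_p else "F"
    return SampleRecord(
        sample_id=sid,
        label=label,
        sex=sex,
        age=float(np.clip(age, 18.0, 95.0)),
        alcohol=float(alcohol),
        bmi=float(np.clip(bmi, 15.0, 70.0)),
    )


def planted_truth(spec: SynthSpec) -> list[MarkerWindow]:
    """Grid windows of the marker peaks, for selection-recovery checks.

    Each window covers the peak's drifting Gaussian trace ±2σ in both
    grid dimensions.  The descriptor always lists the marker peaks;
    whether an effect is present (effect_size) is a separate question.
    """
    layout = _peak_layout(spec)
    sig_r, sig_c = spec.peak_width
    windows = []
    for k in spec.marker_peaks:
        c_lo = max(0, int(np.floor(layout["col0"][k] - 2 * sig_c)))
        c_hi = min(spec.cols, int(np.ceil(layout["col0"][k] + 2 * sig_c)) + 1)
        r_base = layout["row0"][k]
        r_lo = max(0, int(np.floor(r_base + spec.drift_slope * c_lo - 2 * sig_r)))
        r_hi = min(spec.rows, int(np.ceil(r_base + spec.drift_slope * (c_hi - 1) + 2 * sig_r)) + 1)
        windows.append(
            MarkerWindow(
                peak_index=k,
                polarity="positive" if layout["polarity"][k] == 0 else "negative",
                row_lo=r_lo,
                row_hi=r_hi,
                col_lo=c_lo,
                col_hi=c_hi,
            )
        )
    return windows
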