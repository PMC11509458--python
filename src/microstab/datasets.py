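"""Synthetic study generator and bundled reference tables.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable without instrument data:

* calibration standards — linear response over the study's eight levels
  (1-3000 ng/mL) with heteroscedastic (constant-CV) noise,
* replicate QC sets at the four study levels (LLOQ 1, LQC 3, MQC 900,
  HQC 2400 ng/mL),
* first-order depletion time-courses on the study's ten-point grid
  (0-60 min) with an optional non-depleting fraction that reproduces the
  late-time flattening real microsomal curves show, and
* a no-cofactor negative control with no depletion.

Noise is lognormal with a stated coefficient of variation by default,
keeping concentrations positive.  A fixed seed gives byte-identical
output.

:func:`load_reference_tables` returns the published dovitinib (DVB)
study tables — back-calculated calibration standards, intra-/inter-day
QC summaries, stability-condition QCs, the twelve greenness principle
scores, and the depletion time-course — as DataFrames, together with the
study's reported headline constants.
"""

from __future__ import annotations

import zlib
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "simulate_calibration",
    "simulate_qc",
    "simulate_depletion",
    "simulate_negative_control",
    "load_reference_tables",
    "QC_LABELS",
]

#: QC level labels in ascending concentration order.
QC_LABELS = ("LLOQ", "LQC", "MQC", "HQC")


class NoiseModel(BaseModel):
    """Replicate noise specification.

    ``constant_cv`` multiplies by a lognormal factor with unit mean and
    the given CV; ``additive`` adds Gaussian noise with standard
    deviation ``sd`` (response/concentration units); ``mixed`` applies
    both.
    """

    kind: Literal["constant_cv", "additive", "mixed"] = "constant_cv"
    cv: float = Field(default=0.05, ge=0)
    sd: float = Field(default=0.0, ge=0)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(values, dtype=float).copy()
        if self.kind in ("constant_cv", "mixed") and self.cv > 0:
            sigma = np.sqrt(np.log1p(self.cv**2))
            mu = -0.5 * sigma**2  # unit-mean lognormal factor
            out = out * rng.lognormal(mu, sigma, size=out.shape)
        if self.kind in ("additive", "mixed") and self.sd > 0:
            out = out + rng.normal(0.0, self.sd, size=out.shape)
        return out


class SimulationConfig(BaseModel):
    """Ground truth and design of a synthetic study.

    Defaults mirror the study design this package reproduces: eight
    calibration levels over 1-3000 ng/mL, four QC levels, the 1.035x +
    0.8911 response line, a 15.48 min true half-life sampled on the
    0-60 min grid with three replicates, and 5% CV lognormal noise.
    """

    seed: int = 0
    calibration_levels: tuple[float, ...] = (1, 15, 40, 100, 250, 500, 2000, 3000)
    qc_levels: tuple[float, ...] = (1, 3, 900, 2400)
    replicates: int = Field(default=3, ge=1)
    response_slope: float = 1.035
    response_intercept: float = 0.8911
    noise_model: NoiseModel = NoiseModel()
    true_t_half: float = Field(default=15.48, gt=0)   # minutes
    t0_conc: float = Field(default=380.45, gt=0)      # ng/mL
    plateau_fraction: float = Field(default=0.0, ge=0, lt=1)
    timepoints: tuple[float, ...] = (0, 2.5, 5, 7.5, 15, 20, 25, 30, 45, 60)

    @model_validator(mode="after")
    def _check_design(self):
        if any(c <= 0 for c in self.calibration_levels + self.qc_levels):
            raise ValueError("concentration levels must be > 0")
        t = np.asarray(self.timepoints, float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must start at 0 and strictly increase")
        return self


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per generator (stable across
    processes, unlike builtin ``hash``)."""
    ss = np.random.SeedSequence(
        config.seed, spawn_key=(zlib.crc32(stream.encode()),)
    )
    return np.random.default_rng(ss)


def simulate_calibration(config: SimulationConfig) -> pd.DataFrame:
    """Generate calibration rows ``nominal_ng_per_ml, replicate,
    response_ratio`` from the true line plus the configured noise."""
    rng = _rng(config, "calibration")
    rows = []
    for conc in config.calibration_levels:
        true_resp = config.response_slope * conc + config.response_intercept
        noisy = config.noise_model.apply(
            np.full(config.replicates, true_resp), rng
        )
        for rep, r in enumerate(noisy, start=1):
            rows.append((float(conc), rep, float(r)))
    return pd.DataFrame(
        rows, columns=["nominal_ng_per_ml", "replicate", "response_ratio"]
    )


def simulate_qc(config: SimulationConfig, n_sets: int | None = None) -> pd.DataFrame:
    """Generate back-calculated QC rows ``level_label, nominal_ng_per_ml,
    replicate, conc_ng_per_ml`` with zero true bias."""
    rng = _rng(config, "qc")
    n = n_sets if n_sets is not None else config.replicates
    levels = sorted(config.qc_levels)
    labels = QC_LABELS[: len(levels)]
    rows = []
    for label, conc in zip(labels, levels):
        noisy = config.noise_model.apply(np.full(n, float(conc)), rng)
        for rep, c in enumerate(noisy, start=1):
            rows.append((label, float(conc), rep, float(c)))
    return pd.DataFrame(
        rows,
        columns=["level_label", "nominal_ng_per_ml", "replicate", "conc_ng_per_ml"],
    )


def depletion_curve(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free depletion curve C(t) = C0 * ((1-f) e^{-kt} + f)."""
    k = np.log(2) / config.true_t_half
    f = config.plateau_fraction
    return config.t0_conc * ((1 - f) * np.exp(-k * np.asarray(t, float)) + f)


def simulate_depletion(config: SimulationConfig) -> pd.DataFrame:
    """Generate depletion rows ``time_min, replicate, conc_ng_per_ml``.

    First-order decay at ``true_t_half`` with an optional non-depleting
    fraction ``plateau_fraction`` producing late-time curvature.
    """
    rng = _rng(config, "depletion")
    t = np.asarray(config.timepoints, float)
    clean = depletion_curve(config, t)
    rows = []
    for rep in range(1, config.replicates + 1):
        noisy = config.noise_model.apply(clean, rng)
        for time, c in zip(t, noisy):
            rows.append((float(time), rep, float(c)))
    df = pd.DataFrame(rows, columns=["time_min", "replicate", "conc_ng_per_ml"])
    return df.sort_values(["time_min", "replicate"], ignore_index=True)


def simulate_negative_control(config: SimulationConfig) -> pd.DataFrame:
    """No-cofactor control: constant mean concentration plus noise."""
    rng = _rng(config, "negative_control")
    t = np.asarray(config.timepoints, float)
    rows = []
    for rep in range(1, config.replicates + 1):
        noisy = config.noise_model.apply(np.full(t.shape, config.t0_conc), rng)
        for time, c in zip(t, noisy):
            rows.append((float(time), rep, float(c)))
    df = pd.DataFrame(rows, columns=["time_min", "replicate", "conc_ng_per_ml"])
    return df.sort_values(["time_min", "replicate"], ignore_index=True)


# ---------------------------------------------------------------------------
# Bundled reference tables (published dovitinib study)
# ---------------------------------------------------------------------------

def load_reference_tables() -> dict:
    """Published dovitinib study tables as DataFrames, plus reported
    headline constants.

    Keys
    ----
    calibration_backcalc : DataFrame
        Back-calculation of six calibration-standard replicates: nominal,
        mean, SD, printed accuracy/%RSD/recovery.
    qc_summary : DataFrame
        Intra-day (12 sets) and inter-day (6 sets) QC summaries at the
        four levels, with the printed precision/accuracy/recovery.
    stability_qc : DataFrame
        QC summaries under four storage conditions (replicate count not
        printed; the battery's six-set convention is assumed for ``n``).
    greenness : DataFrame
        Twelve principle sub-scores and weights.
    depletion : DataFrame
        Mean depletion time-course (average of 3 repeats) with the
        printed percent-remaining and ln columns.
    reported : dict
        Headline constants as printed (regression line, t1/2, Clint,
        CSL, matrix effects, overall greenness).
    """
    calibration_backcalc = pd.DataFrame(
        {
            "nominal_ng_per_ml": [1, 15, 40, 100, 250, 500, 2000, 3000],
            "mean_ng_per_ml": [1.07, 14.73, 40.93, 100.96, 254.41, 508.02,
                               1966.90, 2997.38],
            "sd_ng_per_ml": [0.08, 0.09, 0.28, 1.57, 1.90, 5.97, 21.08, 13.60],
            "accuracy_pct": [7.18, -1.83, 2.32, 0.96, 1.77, 1.60, -1.65, -0.09],
            "rsd_pct": [7.28, 0.64, 0.69, 1.56, 0.75, 1.18, 1.07, 0.45],
            "recovery_pct": [107.18, 98.17, 102.32, 100.96, 101.77, 101.60,
                             98.35, 99.91],
            "n": [6] * 8,
        }
    )

    qc_summary = pd.DataFrame(
        {
            "series": ["intra_day"] * 4 + ["inter_day"] * 4,
            "level_label": list(QC_LABELS) * 2,
            "nominal_ng_per_ml": [1.0, 3.0, 900.0, 2400.0] * 2,
            "mean_ng_per_ml": [1.07, 3.10, 902.61, 2406.71,
                               1.09, 3.05, 894.99, 2389.57],
            "sd_ng_per_ml": [0.08, 0.03, 7.54, 10.10, 0.03, 0.06, 5.18, 5.74],
            "n": [12] * 4 + [6] * 4,
            "rsd_pct": [7.28, 0.81, 0.83, 0.42, 2.30, 2.00, 0.58, 0.24],
            "accuracy_pct": [7.18, 3.19, 0.29, 0.28, 9.33, 1.68, -0.56, -0.43],
            "recovery_pct": [107.18, 103.19, 100.29, 100.28,
                             109.33, 101.68, 99.44, 99.57],
        }
    )

    stability_qc = pd.DataFrame(
        {
            "condition_label": (
                ["long_term"] * 2 + ["auto_sampler"] * 2
                + ["freeze_thaw"] * 2 + ["short_term"] * 2
            ),
            "level_label": ["LQC", "HQC"] * 4,
            "nominal_ng_per_ml": [3.0, 2400.0] * 4,
            "mean_ng_per_ml": [2.91, 2388.44, 3.01, 2406.68,
                               3.06, 2414.45, 2.95, 2390.13],
            "sd_ng_per_ml": [0.05, 5.52, 0.12, 7.77, 0.08, 14.51, 0.11, 6.38],
            "n": [6] * 8,
            "rsd_pct": [1.82, 0.23, 4.13, 0.32, 2.72, 0.60, 3.59, 0.27],
            "accuracy_pct": [-3.00, -0.48, 0.22, 0.28, 2.11, 0.60, -1.56, -0.41],
        }
    )

    greenness = pd.DataFrame(
        {
            "principle_id": list(range(1, 13)),
            "score": [0.3, 0.75, 0.66, 1.0, 0.75, 1.0, 0.88, 1.0, 0.0, 0.5,
                      1.0, 1.0],
            "weight": [2, 3, 2, 3, 2, 2, 2, 2, 2, 1, 2, 2],
        }
    )

    depletion = pd.DataFrame(
        {
            "time_min": [0.0, 2.5, 5.0, 7.5, 15.0, 20.0, 25.0, 30.0, 45.0, 60.0],
            "mean_conc_ng_per_ml": [380.45, 321.44, 279.33, 252.96, 195.86,
                                    143.62, 120.75, 101.88, 94.28, 71.30],
            "pct_remaining_printed": [100, 84.49, 73.42, 66.49, 51.48, 37.75,
                                      31.74, 26.78, 24.78, 18.74],
            "ln_pct_printed": [4.61, 4.44, 4.30, 4.20, 3.94, 3.63, 3.46, 3.29,
                               3.21, 2.93],
        }
    )

    reported = {
        "regression_slope": -0.04479,
        "regression_intercept": 4.563,
        "regression_r_squared": 0.9920,
        "t_half_min": 15.48,
        "clint_ml_min_kg": 52.39,
        "linear_window_min": (0.0, 25.0),
        "csl": 0.9995,
        "calibration_slope": 1.035,
        "calibration_intercept": 0.8911,
        "calibration_r_squared": 0.9997,
        "mean_cs_recovery_pct": 101.28,
        "me_analyte_pct": 102.39,
        "me_is_pct": 99.74,
        "normalized_me": 1.03,
        "overall_greenness": 0.77,
    }

    return {
        "calibration_backcalc": calibration_backcalc,
        "qc_summary": qc_summary,
        "stability_qc": stability_qc,
        "greenness": greenness,
        "depletion": depletion,
        "reported": reported,
    }
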