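"""End-to-end study runner: calibration -> validation -> metabolic
stability -> greenness, with a single JSON-serializable report.

Every number in the report is traceable to one library operation;
rounding (half-up, 2 decimals by default) happens exactly once, at
report emission.  Identical configuration and inputs produce identical
report bytes — the report carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as mio
from .calibration import fit_calibration, CalibrationStandard
from .exceptions import MicrostabError, StageError
from .greenness import GreennessPrinciple, aggregate_greenness
from .stability import (
    ClearanceBands,
    DepletionKinetics,
    MicrosomalScaling,
    check_negative_control,
    composite_site_lability,
    percent_remaining,
)
from .validation import (
    QCThresholds,
    assess_matrix_effect,
    evaluate_qc_battery,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "round_half_up"]

logger = logging.getLogger("microstab")

TableLike = Union[str, Path, pd.DataFrame, None]


class StudyConfig(BaseModel):
    """Inputs and tunables of a full study run.

    Table fields accept a CSV path (validated against the module's
    schema) or an in-memory DataFrame; absent tables simply skip their
    report section.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    calibration: TableLike = None
    qc: TableLike = None                    # replicate or summary schema
    matrix_effect: TableLike = None
    depletion: TableLike = None             # replicate or mean schema
    negative_control: TableLike = None
    greenness: TableLike = None
    stability_conditions: TableLike = None  # qc_summary + condition_label

    weighting: str = "1/x"
    qc_thresholds: QCThresholds = QCThresholds()
    segment_mode: str = "fixed_window"
    window: tuple[float, float] = (0.0, 25.0)
    scaling: MicrosomalScaling = MicrosomalScaling()
    clearance_bands: ClearanceBands = ClearanceBands()
    csl_rates: Optional[tuple[float, float]] = None  # (k_total, k_w)
    seed: int = 0
    report_decimals: int = Field(default=2, ge=0)


@dataclasses.dataclass(frozen=True)
class StudyReport:
    """Structured study report; ``to_json`` applies the rounding
    convention once, at emission."""

    sections: dict
    decimals: int = 2

    def rounded(self) -> dict:
        return _round_tree(self.sections, self.decimals)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.rounded(), **kwargs)

    def summary(self) -> str:
        """Short human-readable digest of the main results."""
        lines = []
        r = self.rounded()
        if "calibration" in r:
            c = r["calibration"]
            lines.append(
                f"calibration: y = {c['slope']}x + {c['intercept']} "
                f"(r2={c['r_squared']}, LOD={c['lod']}, LOQ={c['loq']} ng/mL)"
            )
        if "qc" in r:
            n_pass = sum(1 for lv in r["qc"]["levels"] if lv["passes"])
            lines.append(f"qc: {n_pass}/{len(r['qc']['levels'])} levels pass")
        if "matrix_effect" in r:
            m = r["matrix_effect"]
            lines.append(f"matrix effect: normalized ME = {m['normalized_me']}")
        if "metabolic_stability" in r:
            s = r["metabolic_stability"]
            lines.append(
                f"stability: slope {s['slope']}/min, t1/2 {s['t_half_min']} min, "
                f"Clint {s['clint_ml_min_kg']} mL/min/kg ({s['clearance_class']})"
            )
        if "greenness" in r:
            g = r["greenness"]
            lines.append(f"greenness: {g['overall']} ({g['band']})")
        return "\n".join(lines)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding used only at the reporting layer."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# dimensionless sub-unit statistics keep two extra decimals so the report
# does not erase them (a depletion slope is ~0.04/min)
_PRECISE_KEYS = {"slope", "intercept", "r_squared", "sd_intercept", "csl"}


def _round_tree(obj: Any, decimals: int, key: str | None = None) -> Any:
    if isinstance(obj, bool) or obj is None or isinstance(obj, (int, str)):
        return obj
    if isinstance(obj, float):
        d = decimals + 2 if key in _PRECISE_KEYS else decimals
        return round_half_up(obj, d)
    if isinstance(obj, dict):
        return {k: _round_tree(v, decimals, k) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v, decimals, key) for v in obj]
    return obj


def _load(table: TableLike, schemas: tuple[str, ...]) -> pd.DataFrame | None:
    """Resolve a table argument to a DataFrame, trying schemas in order."""
    if table is None or isinstance(table, pd.DataFrame):
        return table
    last = None
    for schema in schemas:
        try:
            return mio.read_table(table, schema)
        except MicrostabError as exc:
            last = exc
    raise last


def run_study(config: StudyConfig) -> StudyReport:
    """Execute every stage for which the configuration provides a table.

    Stage order mirrors the bench workflow: calibrate, back-calculate
    QCs, matrix effect, stability-condition QCs, depletion kinetics plus
    negative control, greenness.  A failing stage raises
    :class:`StageError` naming the stage.
    """
    sections: dict[str, Any] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                logger.info("stage %s: done", name)
                return False

        return _Ctx()

    if config.calibration is not None:
        with stage("calibration"):
            df = _load(config.calibration, ("calibration",))
            standards = [
                CalibrationStandard(conc, tuple(grp["response_ratio"]))
                for conc, grp in df.groupby("nominal_ng_per_ml", sort=True)
            ]
            logger.info("calibration: %d levels, %d points",
                        len(standards), len(df))
            fit = fit_calibration(standards, config.weighting)
            sections["calibration"] = {
                "weighting": fit.weighting_,
                "slope": fit.slope_,
                "intercept": fit.intercept_,
                "r_squared": fit.r_squared_,
                "sd_intercept": fit.sd_intercept_,
                "lod": fit.lod_,
                "loq": fit.loq_,
                "n_points": fit.n_points_,
            }

    if config.qc is not None:
        with stage("qc"):
            df = _load(config.qc, ("qc", "qc_summary"))
            evals = evaluate_qc_battery(df, thresholds=config.qc_thresholds)
            logger.info("qc: %d levels", len(evals))
            sections["qc"] = {"levels": [dataclasses.asdict(e) for e in evals]}

    if config.matrix_effect is not None:
        with stage("matrix_effect"):
            df = _load(config.matrix_effect, ("matrix_effect",))
            me = assess_matrix_effect(df)
            sections["matrix_effect"] = dataclasses.asdict(me)

    if config.stability_conditions is not None:
        with stage("stability_conditions"):
            df = config.stability_conditions
            if not isinstance(df, pd.DataFrame):
                df = pd.read_csv(df)
            out = []
            for cond, grp in df.groupby("condition_label", sort=False):
                evals = evaluate_qc_battery(
                    grp.drop(columns=["condition_label"]),
                    thresholds=config.qc_thresholds,
                )
                out.append(
                    {
                        "condition_label": str(cond),
                        "levels": [dataclasses.asdict(e) for e in evals],
                    }
                )
            sections["stability_conditions"] = out

    if config.depletion is not None:
        with stage("metabolic_stability"):
            df = _load(config.depletion, ("depletion", "depletion_mean"))
            est = DepletionKinetics(
                segment_mode=config.segment_mode,
                window=config.window,
                scaling=config.scaling,
                bands=config.clearance_bands,
            ).fit(df)
            logger.info(
                "stability: window %s, slope %.5f/min", est.window_, est.slope_
            )
            sections["metabolic_stability"] = {
                "slope": est.slope_,
                "intercept": est.intercept_,
                "r_squared": est.r_squared_,
                "window_min": list(est.window_),
                "n_points": est.fit_.n_points,
                "t_half_min": est.t_half_,
                "clint_ml_min_kg": est.clint_,
                "clearance_class": est.clearance_class_,
            }

    if config.negative_control is not None:
        with stage("negative_control"):
            df = _load(config.negative_control, ("depletion", "depletion_mean"))
            profile = percent_remaining(df)
            flag = check_negative_control(profile)
            sections.setdefault("metabolic_stability", {})[
                "negative_control_non_depleting"
            ] = bool(flag)

    if config.csl_rates is not None:
        with stage("composite_site_lability"):
            k_total, k_w = config.csl_rates
            sections.setdefault("metabolic_stability", {})["csl"] = (
                composite_site_lability(k_total, k_w)
            )

    if config.greenness is not None:
        with stage("greenness"):
            df = _load(config.greenness, ("agree",))
            principles = [
                GreennessPrinciple(int(r.principle_id), float(r.score),
                                   int(r.weight))
                for r in df.itertuples()
            ]
            assessment = aggregate_greenness(principles)
            sections["greenness"] = {
                "overall": assessment.overall,
                "band": assessment.band,
            }

    return StudyReport(sections=sections, decimals=config.report_decimals)
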