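"""Bioanalytical validation battery: accuracy, precision, recovery,
matrix effect, and stability-condition evaluation with guideline pass flags.

Conventions (FDA bioanalytical guideline style):

* accuracy  %E   = 100 * (mean - nominal) / nominal
* precision %RSD = 100 * sample SD (n-1) / mean
* recovery  %    = 100 * mean(measured) / mean(reference)   [or /nominal]
* matrix effect  = 100 * mean(matrix areas) / mean(neat areas); the
  IS-normalized matrix effect is ME(analyte) / ME(internal standard).

A quality-control level passes when |%E| and %RSD are within the
threshold: 15% by default, relaxed to 20% at the LLOQ.  Thresholds are
configurable; the printed tables this package reproduces carry no
explicit thresholds, only the guideline citation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError, InsufficientReplicatesError, SchemaError

__all__ = [
    "QCThresholds",
    "QCEvaluation",
    "MatrixEffectAssessment",
    "StabilityConditionResult",
    "accuracy_pct_error",
    "precision_pct_rsd",
    "recovery_pct",
    "matrix_effect",
    "normalized_matrix_effect",
    "evaluate_qc_battery",
    "assess_matrix_effect",
    "evaluate_stability_conditions",
]


def accuracy_pct_error(mean_conc: float, nominal_conc: float) -> float:
    """Percent relative error, 100*(mean - nominal)/nominal."""
    if nominal_conc == 0:
        raise InputError("nominal concentration must be nonzero for %E")
    return 100.0 * (mean_conc - nominal_conc) / nominal_conc


def precision_pct_rsd(
    values: Sequence[float] | None = None,
    *,
    sd: float | None = None,
    mean: float | None = None,
) -> float:
    """Percent relative standard deviation.

    Either pass replicate ``values`` (sample SD, n-1 denominator) or the
    summary form ``sd=..., mean=...`` as printed in validation tables.
    """
    if values is not None:
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise InsufficientReplicatesError("%RSD needs at least 2 replicates")
        sd = float(np.std(arr, ddof=1))
        mean = float(np.mean(arr))
    elif sd is None or mean is None:
        raise InputError("pass replicate values or both sd= and mean=")
    if mean == 0:
        raise InputError("mean is zero; %RSD undefined")
    return 100.0 * sd / mean


def _mean_of(x) -> float:
    arr = np.asarray(list(x) if np.ndim(x) > 0 else [x], dtype=float).reshape(-1)
    if arr.size == 0:
        raise InputError("empty group")
    return float(np.mean(arr))


def recovery_pct(measured, reference=None, *, nominal: float | None = None) -> float:
    """Percent recovery.

    ``recovery_pct(B, A)`` gives 100*mean(B)/mean(A) for extracted-vs-neat
    comparisons; ``recovery_pct(values, nominal=c)`` gives 100*mean/nominal
    for back-calculated standards.  Scalars are accepted where means are
    already summarized.
    """
    num = _mean_of(measured)
    if reference is not None:
        den = _mean_of(reference)
    elif nominal is not None:
        den = float(nominal)
    else:
        raise InputError("pass a reference group or nominal=")
    if den == 0:
        raise InputError("reference mean is zero; recovery undefined")
    return 100.0 * num / den


def matrix_effect(group1_areas, group2_areas) -> float:
    """Matrix effect in percent: 100 * mean(matrix) / mean(neat)."""
    den = _mean_of(group2_areas)
    if den == 0:
        raise InputError("neat-solvent mean is zero; matrix effect undefined")
    return 100.0 * _mean_of(group1_areas) / den


def normalized_matrix_effect(me_analyte: float, me_is: float) -> float:
    """IS-normalized matrix effect: ME(analyte) / ME(internal standard)."""
    if me_is <= 0:
        raise InputError("internal-standard matrix effect must be > 0")
    return me_analyte / me_is


@dataclass(frozen=True)
class QCThresholds:
    """Guideline pass thresholds in percent.

    ``default`` applies to |%E| and %RSD at all levels except the LLOQ,
    where ``lloq`` applies.
    """

    default: float = 15.0
    lloq: float = 20.0

    def __post_init__(self):
        if self.default <= 0 or self.lloq <= 0:
            raise InputError("thresholds must be positive")

    def limit_for(self, level_label: str) -> float:
        return self.lloq if str(level_label).strip().upper() == "LLOQ" else self.default


@dataclass(frozen=True)
class QCEvaluation:
    """Per-level QC summary with its guideline pass flag.

    ``recovery_pct - 100 == pct_error`` holds by construction since both
    derive from the same mean/nominal pair.
    """

    level_label: str
    nominal_conc: float
    n: int
    mean_conc: float
    sd_conc: float
    pct_error: float
    pct_rsd: float
    recovery_pct: float
    passes: bool


@dataclass(frozen=True)
class MatrixEffectAssessment:
    analyte_me_pct: float
    is_me_pct: float
    normalized_me: float


@dataclass(frozen=True)
class StabilityConditionResult:
    """QC battery re-evaluated under one storage condition
    (long-term, auto-sampler, freeze-thaw, short-term)."""

    condition_label: str
    levels: tuple[QCEvaluation, ...]


def _evaluate_level(
    label: str,
    nominal: float,
    *,
    values: Sequence[float] | None = None,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
    thresholds: QCThresholds,
) -> QCEvaluation:
    if values is not None:
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise InsufficientReplicatesError(
                f"level {label!r}: QC evaluation needs n >= 2"
            )
        mean = float(np.mean(arr))
        sd = float(np.std(arr, ddof=1))
        n = int(arr.size)
    if mean is None or sd is None or n is None:
        raise InputError(f"level {label!r}: need replicate values or mean/sd/n")
    if nominal is None or not np.isfinite(nominal):
        raise SchemaError(f"level {label!r}: missing nominal concentration")
    err = accuracy_pct_error(mean, nominal)
    rsd = precision_pct_rsd(sd=sd, mean=mean)
    limit = thresholds.limit_for(label)
    return QCEvaluation(
        level_label=str(label),
        nominal_conc=float(nominal),
        n=n,
        mean_conc=mean,
        sd_conc=sd,
        pct_error=err,
        pct_rsd=rsd,
        recovery_pct=err + 100.0,
        passes=bool(abs(err) <= limit and rsd <= limit),
    )


def evaluate_qc_battery(
    data,
    nominals: Mapping[str, float] | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> list[QCEvaluation]:
    """Evaluate replicate QC sets per level.

    ``data`` may be:

    * a mapping ``{level_label: replicate concentrations}`` with
      ``nominals`` mapping each label to its nominal concentration, or
    * a tidy DataFrame with columns ``level_label, nominal_ng_per_ml,
      replicate, conc_ng_per_ml``, or
    * a summary DataFrame with columns ``level_label, nominal_ng_per_ml,
      mean_ng_per_ml, sd_ng_per_ml, n`` (as printed in validation tables).

    Returns one :class:`QCEvaluation` per level, in input order.
    """
    out: list[QCEvaluation] = []
    if isinstance(data, pd.DataFrame):
        cols = set(data.columns)
        if {"level_label", "nominal_ng_per_ml", "conc_ng_per_ml"} <= cols:
            for label, grp in data.groupby("level_label", sort=False):
                out.append(
                    _evaluate_level(
                        label,
                        float(grp["nominal_ng_per_ml"].iloc[0]),
                        values=grp["conc_ng_per_ml"].to_numpy(float),
                        thresholds=thresholds,
                    )
                )
        elif {"level_label", "nominal_ng_per_ml", "mean_ng_per_ml",
              "sd_ng_per_ml", "n"} <= cols:
            for _, row in data.iterrows():
                out.append(
                    _evaluate_level(
                        row["level_label"],
                        float(row["nominal_ng_per_ml"]),
                        mean=float(row["mean_ng_per_ml"]),
                        sd=float(row["sd_ng_per_ml"]),
                        n=int(row["n"]),
                        thresholds=thresholds,
                    )
                )
        else:
            raise SchemaError(
                "QC DataFrame must carry replicate columns (level_label, "
                "nominal_ng_per_ml, replicate, conc_ng_per_ml) or summary "
                "columns (level_label, nominal_ng_per_ml, mean_ng_per_ml, "
                f"sd_ng_per_ml, n); got {sorted(cols)}"
            )
    else:
        if nominals is None:
            raise SchemaError("mapping input needs a nominals= mapping")
        for label, values in data.items():
            if label not in nominals:
                raise SchemaError(f"missing nominal for level {label!r}")
            out.append(
                _evaluate_level(
                    label, float(nominals[label]), values=values,
                    thresholds=thresholds,
                )
            )
    return out


def assess_matrix_effect(areas: pd.DataFrame) -> MatrixEffectAssessment:
    """Compute analyte and IS matrix effects and their ratio.

    ``areas`` columns: ``group`` in {matrix, neat}, ``analyte`` in
    {drug, is}, ``replicate``, ``peak_area``.
    """
    required = {"group", "analyte", "peak_area"}
    if not required <= set(areas.columns):
        raise SchemaError(
            f"matrix-effect table needs columns {sorted(required)}; "
            f"got {sorted(areas.columns)}"
        )

    def _grp(analyte, group):
        sel = areas[(areas["analyte"] == analyte) & (areas["group"] == group)]
        if sel.empty:
            raise InputError(f"no rows for analyte={analyte!r}, group={group!r}")
        return sel["peak_area"].to_numpy(float)

    me_drug = matrix_effect(_grp("drug", "matrix"), _grp("drug", "neat"))
    me_is = matrix_effect(_grp("is", "matrix"), _grp("is", "neat"))
    return MatrixEffectAssessment(
        analyte_me_pct=me_drug,
        is_me_pct=me_is,
        normalized_me=normalized_matrix_effect(me_drug, me_is),
    )


def evaluate_stability_conditions(
    conditions: Mapping[str, object],
    nominals: Mapping[str, float] | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> list[StabilityConditionResult]:
    """Run the unchanged QC battery under each storage condition.

    ``conditions`` maps a condition label (long-term, auto-sampler,
    freeze-thaw, short-term, ...) to any input accepted by
    :func:`evaluate_qc_battery`.
    """
    return [
        StabilityConditionResult(
            condition_label=str(label),
            levels=tuple(evaluate_qc_battery(data, nominals, thresholds)),
        )
        for label, data in conditions.items()
    ]
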