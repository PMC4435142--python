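"""Scoring mixture-OI predictions against panel measurements.

The primary metric is the predictive coefficient OI_pre / OI_mea per sample
(1.0 = perfect prediction) and its arithmetic mean per model.  Root-mean-
square error and mean absolute error are reported alongside as modern
diagnostics; they are extensions, not part of the original metric.

Two rounding modes exist because reference tables print predictions at one
decimal: ``"table"`` rounds each prediction half-up to one decimal *before*
taking ratios, reproducing printed-table arithmetic exactly; ``"full"``
(the default for new data) keeps full precision throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, DomainError
from .mixture_models import (
    DEFAULT_COS_ALPHA,
    MODEL_NAMES,
    MixtureSample,
    predict_sample,
)
from .psychophysics import PsychophysicalLaw

ROUNDING_MODES = ("full", "table")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (4.25 -> 4.3 at one decimal), as tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def predictive_coefficient(oi_pre: float, oi_mea: float) -> float:
    """Ratio of predicted to measured OI; requires a positive measurement."""
    if not oi_mea > 0:
        raise DomainError(
            f"predictive coefficient needs measured OI > 0, got {oi_mea!r}"
        )
    if oi_pre < 0:
        raise DomainError(f"predicted OI cannot be negative, got {oi_pre!r}")
    return oi_pre / oi_mea


@dataclass
class EvaluationReport:
    """Per-sample predictions/ratios plus per-model summary statistics."""

    rows: pd.DataFrame
    averages: Dict[str, float]
    rms_error: Dict[str, float]
    mean_abs_error: Dict[str, float]
    rounding_mode: str
    models: tuple = ()
    warnings: list = field(default_factory=list)

    def summary_dict(self) -> dict:
        """Two-decimal view of the per-model mean predictive coefficients."""
        return {
            "rounding_mode": self.rounding_mode,
            "n_samples": int(len(self.rows)),
            "mean_predictive_coefficient": {
                m: round_half_up(v, 2) for m, v in self.averages.items()
            },
            "rms_error": {m: round(v, 3) for m, v in self.rms_error.items()},
            "mean_abs_error": {m: round(v, 3) for m, v in self.mean_abs_error.items()},
        }

    def to_text_table(self) -> str:
        """Plain-text table mirroring the reference-table layout."""
        lines = []
        header = ["sample", "OI_mea"] + [f"OI_{m}" for m in self.models]
        lines.append("\t".join(header))
        for _, row in self.rows.iterrows():
            cells = [str(row["sample_id"]), f"{row['oi_measured']:.1f}"]
            for m in self.models:
                cells.append(f"{row[f'pred_{m}']:.1f}")
            lines.append("\t".join(cells))
        avg = ["mean OI_pre/OI_mea", ""] + [
            f"{round_half_up(self.averages[m], 2):.2f}" for m in self.models
        ]
        lines.append("\t".join(avg))
        return "\n".join(lines) + "\n"


def evaluate_table(
    samples: Sequence[MixtureSample],
    models: Sequence[str] = ("mvm", "scm"),
    law: Optional[PsychophysicalLaw] = None,
    cos_alpha: float = DEFAULT_COS_ALPHA,
    rounding_mode: str = "full",
    subthreshold: str = "drop",
) -> EvaluationReport:
    """Predict every sample under every model and score against panel OI.

    Every sample must carry a positive measured OI.  A failing sample aborts
    the evaluation with its sample id in the error message.
    """
    if rounding_mode not in ROUNDING_MODES:
        raise ConfigurationError(
            f"unknown rounding mode {rounding_mode!r}; choose from {ROUNDING_MODES}"
        )
    for m in models:
        if m not in MODEL_NAMES:
            raise ConfigurationError(f"unknown model {m!r}; choose from {MODEL_NAMES}")
    law = law or PsychophysicalLaw()
    records = []
    notes: list[str] = []
    for sample in samples:
        if sample.measured_oi is None or not sample.measured_oi > 0:
            raise DomainError(
                f"sample {sample.sample_id!r}: evaluation needs measured OI > 0, "
                f"got {sample.measured_oi!r}"
            )
        rec: dict = {"sample_id": sample.sample_id, "oi_measured": sample.measured_oi}
        for m in models:
            try:
                result = predict_sample(
                    sample, m, law=law, cos_alpha=cos_alpha, subthreshold=subthreshold
                )
            except Exception as exc:
                raise type(exc)(f"sample {sample.sample_id!r}: {exc}") from None
            pred = result.predicted_oi
            if rounding_mode == "table":
                pred = round_half_up(pred, 1)
            rec[f"pred_{m}"] = pred
            rec[f"ratio_{m}"] = predictive_coefficient(pred, sample.measured_oi)
            if result.warnings:
                notes.extend(f"{sample.sample_id}/{m}: {w}" for w in result.warnings)
        records.append(rec)
    if not records:
        raise DomainError("no samples to evaluate")
    rows = pd.DataFrame.from_records(records)
    averages = {m: float(rows[f"ratio_{m}"].mean()) for m in models}
    rms = {
        m: float(((rows[f"pred_{m}"] - rows["oi_measured"]) ** 2).mean() ** 0.5)
        for m in models
    }
    mae = {
        m: float((rows[f"pred_{m}"] - rows["oi_measured"]).abs().mean())
        for m in models
    }
    return EvaluationReport(
        rows=rows,
        averages=averages,
        rms_error=rms,
        mean_abs_error=mae,
        rounding_mode=rounding_mode,
        models=tuple(models),
        warnings=notes,
    )
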