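"""CSV readers/writers shared by the CLI and the bundled datasets.

Mixture samples travel in a long format, one row per component:

    sample_id,component,concentration_mg_m3,ln_oav,measured_oi

``component`` is an abbreviation (or CAS number) resolved against a
threshold registry; each component row carries a concentration, an lnOAV,
or both; ``measured_oi`` may be blank or repeated across a sample's rows.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Tuple

import pandas as pd

from .errors import ValidationError
from .mixture_models import MixtureSample, PredictionResult
from .psychophysics import ComponentExposure
from .registry import OdorantRegistry

SAMPLE_COLUMNS = ("sample_id", "component", "concentration_mg_m3", "ln_oav",
                  "measured_oi")


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    return float(value)


def read_samples_csv(path: str | Path, registry: OdorantRegistry) -> list[MixtureSample]:
    """Read long-format mixture samples, preserving file order of samples."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "component": str})
    missing = [c for c in ("sample_id", "component") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no samples")
    samples: list[MixtureSample] = []
    for sample_id, group in df.groupby("sample_id", sort=False):
        components = []
        measured: Optional[float] = None
        for idx, row in group.iterrows():
            try:
                conc = _opt_float(row.get("concentration_mg_m3"))
                lnx = _opt_float(row.get("ln_oav"))
                oi = _opt_float(row.get("measured_oi"))
                odorant = registry.get(str(row["component"]).strip())
                components.append(
                    ComponentExposure(odorant=odorant, concentration=conc, ln_oav=lnx)
                )
            except Exception as exc:
                raise ValidationError(f"{path} row {idx + 2}: {exc}") from None
            if oi is not None:
                if measured is not None and abs(measured - oi) > 1e-9:
                    raise ValidationError(
                        f"{path}: sample {sample_id!r} has conflicting measured OI"
                    )
                measured = oi
        samples.append(MixtureSample(
            sample_id=str(sample_id), components=tuple(components),
            measured_oi=measured,
        ))
    return samples


def write_predictions_csv(results: Sequence[PredictionResult], path: str | Path) -> None:
    """Fixed column order, dot decimals, trailing newline — golden-file stable."""
    from .evaluation import round_half_up

    records = [
        {
            "sample_id": r.sample_id,
            "model": r.model_name,
            "predicted_oi": repr(r.predicted_oi),
            "predicted_oi_1dp": f"{round_half_up(r.predicted_oi, 1):.1f}",
            "clamped": str(r.clamped).lower(),
            "warnings": "; ".join(r.warnings),
        }
        for r in results
    ]
    pd.DataFrame.from_records(
        records,
        columns=["sample_id", "model", "predicted_oi", "predicted_oi_1dp",
                 "clamped", "warnings"],
    ).to_csv(path, index=False)


def read_individual_csv(path: str | Path) -> list[Tuple[float, float]]:
    """Calibration input: columns odorant, ln_oav, oi_measured."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("ln_oav", "oi_measured"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return list(zip(df["ln_oav"].astype(float), df["oi_measured"].astype(float)))


def read_binary_csv(path: str | Path) -> list[Tuple[float, float]]:
    """Calibration input: columns sample_id, oi_sum, oi_measured."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("oi_sum", "oi_measured"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return list(zip(df["oi_sum"].astype(float), df["oi_measured"].astype(float)))
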