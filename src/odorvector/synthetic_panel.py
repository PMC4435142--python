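"""Synthetic sensory-panel studies for testing calibration and evaluation.

A real study rates each odor sample on an odor intensity referencing scale
(OIRS): each assessor picks the best-matching discrete scale point, and the
sample's OI is the panel mean.  The generator emulates exactly that
structure:

    score_j = clamp_0( round_to_step( true_OI + N(0, sd) ) ),  j = 1..n
    panel OI = mean_j score_j

with defaults of nine assessors, Gaussian rating noise of sd 0.25 OIRS
units (a +/-2 sd band of about 0.5, the fluctuation typically acknowledged
for repeated sensory tests) and a 0.5-unit rating step.  ``rating_step = 0``
disables discretization and gives continuous ratings — useful for exact
noiseless round-trip checks, where step quantization would otherwise leave
a small floor error.

Mixture "truth" is the modified Vector Model itself, so parameter recovery
is testable under the model; an optional uniform +/-delta misspecification
term perturbs the true OI for robustness studies.  Binary calibration
mixtures are generated with equal-intensity constituents, mirroring the
standard preparation for determining the interaction coefficient.

What this generator does **not** emulate: assessor-specific bias or drift,
odorant-specific deviations from the pooled psychophysical slope, and
chemical families beyond a shared single cos(alpha).  Passing tests show
parameter recovery under the model's own assumptions, not robustness to
real panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .mixture_models import MixtureSample, modified_vector_model
from .psychophysics import ComponentExposure
from .registry import OdorantRegistry

DEFAULT_MIXTURE_DESIGNS: tuple[tuple[str, ...], ...] = (
    ("B", "T"), ("B", "E"), ("T", "E"), ("E", "O"),
)


@dataclass(frozen=True)
class PanelConfig:
    """Sensory-panel emulation parameters."""

    n_assessors: int = 9
    rating_noise_sd: float = 0.25
    rating_step: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_assessors < 1:
            raise ValidationError(f"need at least one assessor, got {self.n_assessors}")
        if not (math.isfinite(self.rating_noise_sd) and self.rating_noise_sd >= 0):
            raise ValidationError(f"rating noise sd must be >= 0, got {self.rating_noise_sd!r}")
        if not (math.isfinite(self.rating_step) and self.rating_step >= 0):
            raise ValidationError(
                f"rating step must be >= 0 (0 = continuous ratings), "
                f"got {self.rating_step!r}"
            )


def _round_to_step(values: np.ndarray, step: float) -> np.ndarray:
    if step == 0:
        return values
    # half-up on the step grid, deterministic across platforms
    return np.floor(values / step + 0.5) * step


def simulate_panel_mean(
    true_oi: float,
    config: PanelConfig,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Panel-mean OIRS rating of a sample with true intensity ``true_oi``."""
    if not (math.isfinite(true_oi) and true_oi >= 0):
        raise DomainError(f"true OI must be >= 0, got {true_oi!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scores = true_oi + rng.normal(0.0, config.rating_noise_sd, config.n_assessors)
    scores = np.clip(_round_to_step(scores, config.rating_step), 0.0, None)
    return float(scores.mean())


@dataclass
class SyntheticStudy:
    """A generated study: individual samples, binary-mixture table, mixtures."""

    true_k: float
    true_cos_alpha: float
    #: columns odorant, ln_oav, oi_measured (panel mean of the unmixed sample)
    individual_samples: pd.DataFrame
    #: columns sample_id, oi_sum, oi_measured — for the beta fit
    binary_table: pd.DataFrame
    mixture_samples: list[MixtureSample] = field(default_factory=list)
    config: PanelConfig = field(default_factory=PanelConfig)

    def individual_points(self) -> list[Tuple[float, float]]:
        """(lnOAV, panel OI) pairs for the k fit."""
        return list(zip(self.individual_samples["ln_oav"],
                        self.individual_samples["oi_measured"]))

    def binary_points(self) -> list[Tuple[float, float]]:
        """(OI_sum, panel OI of the mixture) pairs for the beta fit."""
        return list(zip(self.binary_table["oi_sum"],
                        self.binary_table["oi_measured"]))

    def write_individual_csv(self, path: str | Path) -> None:
        df = self.individual_samples.rename(columns={"oi_measured": "oi_measured"})
        df.to_csv(path, index=False,
                  columns=["odorant", "ln_oav", "oi_measured"])

    def write_binary_csv(self, path: str | Path) -> None:
        self.binary_table.to_csv(path, index=False,
                                 columns=["sample_id", "oi_sum", "oi_measured"])

    def write_samples_csv(self, path: str | Path) -> None:
        """Long-format mixture samples, the format ``odorvector predict`` reads."""
        records = []
        for sample in self.mixture_samples:
            for comp in sample.components:
                records.append({
                    "sample_id": sample.sample_id,
                    "component": comp.odorant.abbreviation,
                    "concentration_mg_m3": "",
                    "ln_oav": comp.ln_oav,
                    "measured_oi": sample.measured_oi,
                })
        pd.DataFrame.from_records(records).to_csv(path, index=False)


def generate_study(
    true_k: float,
    true_cos_alpha: float,
    registry: OdorantRegistry,
    n_individual_per_odorant: int = 4,
    mixture_designs: Sequence[Sequence[str]] = DEFAULT_MIXTURE_DESIGNS,
    n_samples_per_design: int = 8,
    lnoav_range: Tuple[float, float] = (1.5, 4.6),
    config: Optional[PanelConfig] = None,
    misspecification_delta: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticStudy:
    """Generate a full synthetic study, reproducible from the config seed.

    Individual samples: each registry odorant at ``n_individual_per_odorant``
    supra-threshold lnOAV values drawn uniformly from ``lnoav_range``, rated
    by the simulated panel against the true law k*lnOAV.

    Mixtures: for each design (a tuple of odorant abbreviations) and
    replicate, one shared lnOAV is drawn (equal-intensity constituents) and
    the true mixture OI comes from the modified Vector Model with
    (true_k, true_cos_alpha), optionally perturbed by a uniform
    +/-``misspecification_delta``.  Binary designs additionally contribute a
    (OI_sum, OI_mea) row, with OI_sum built from separately panel-rated
    unmixed constituents — as a real study would measure it.
    """
    lo, hi = lnoav_range
    if not (0 < lo <= hi <= 6):
        raise DomainError(f"lnOAV range must lie within (0, 6], got {lnoav_range!r}")
    if misspecification_delta < 0:
        raise DomainError("misspecification delta must be >= 0")
    config = config or PanelConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    individual_records = []
    for odorant in registry:
        for _ in range(n_individual_per_odorant):
            x = float(rng.uniform(lo, hi))
            oi_meas = simulate_panel_mean(true_k * x, config, rng)
            individual_records.append(
                {"odorant": odorant.abbreviation, "ln_oav": x, "oi_measured": oi_meas}
            )

    binary_records = []
    mixtures: list[MixtureSample] = []
    for d_idx, design in enumerate(mixture_designs):
        odorants = [registry.get(abbr) for abbr in design]  # raises on unknown
        if len({o.abbreviation for o in odorants}) != len(odorants):
            raise ValidationError(f"design {design!r} repeats an odorant")
        for rep in range(n_samples_per_design):
            x = float(rng.uniform(lo, hi))
            xs = [x] * len(odorants)
            true_oi = modified_vector_model(xs, true_k, true_cos_alpha)
            if misspecification_delta > 0:
                true_oi = max(
                    0.0,
                    true_oi + float(rng.uniform(-misspecification_delta,
                                                misspecification_delta)),
                )
            oi_meas = simulate_panel_mean(true_oi, config, rng)
            sample_id = f"D{d_idx + 1}-{rep + 1}"
            mixtures.append(MixtureSample(
                sample_id=sample_id,
                components=tuple(
                    ComponentExposure(odorant=o, ln_oav=xi)
                    for o, xi in zip(odorants, xs)
                ),
                measured_oi=oi_meas,
            ))
            if len(odorants) == 2:
                # OI_sum from panel-rated unmixed constituents
                oi_sum = math.fsum(
                    simulate_panel_mean(true_k * xi, config, rng) for xi in xs
                )
                binary_records.append(
                    {"sample_id": sample_id, "oi_sum": oi_sum, "oi_measured": oi_meas}
                )

    return SyntheticStudy(
        true_k=true_k,
        true_cos_alpha=true_cos_alpha,
        individual_samples=pd.DataFrame.from_records(
            individual_records, columns=["odorant", "ln_oav", "oi_measured"]
        ),
        binary_table=pd.DataFrame.from_records(
            binary_records, columns=["sample_id", "oi_sum", "oi_measured"]
        ),
        mixture_samples=mixtures,
        config=config,
    )
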