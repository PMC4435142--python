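"""Mixture odor-intensity models.

Four models predict the perceived intensity OI of an n-component mixture:

``mvm`` — modified Vector Model, the package's core.  With x_i = lnOAV of
component i, a shared interaction coefficient cos(alpha) and psychophysical
slope k,

    OI = k * sqrt( sum_i x_i^2  +  2*cos(alpha) * sum_{i<j} x_i x_j ).

For the aromatic reference family k = 1.07 and cos(alpha) = -0.129 (so the
cross-term coefficient is 2*cos(alpha) = -0.258: a distinct counteraction).

``vm`` — classic Vector Model on intensity units with per-pair cos(alpha):
the mixture OI is the diagonal of the parallelogram whose sides are the
components' unmixed intensities.

``scm`` — Strongest Component Model: the largest single-component intensity.

``sum`` — plain summation of component intensities, the additivity baseline
against which the counteraction factor beta is fitted.

Sub-threshold components (lnOAV < 0) were never part of the data the model
was built on; including them would let cross terms *raise* the predicted
intensity, which contradicts the model's physical reading.  The default
policy therefore drops them (configurable: ``drop``/``keep``/``error``).
A negative radicand — possible for many mutually counteracting components —
clamps the prediction to 0 and sets a flag, since OI is non-negative by
construction of the rating scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import ConfigurationError, DomainError, ValidationError
from .psychophysics import (
    DEFAULT_SLOPE_K,
    ComponentExposure,
    PsychophysicalLaw,
    oi_individual,
)

#: Shared interaction coefficient of the aromatic-compound reference family.
DEFAULT_COS_ALPHA = -0.129

MODEL_NAMES = ("mvm", "vm", "scm", "sum")
SUBTHRESHOLD_POLICIES = ("drop", "keep", "error")


def _check_cos_alpha(value: float) -> float:
    if not (math.isfinite(value) and -1.0 <= value <= 1.0):
        raise ConfigurationError(
            f"cos(alpha) must lie in [-1, 1] (cosine of a parallelogram angle), "
            f"got {value!r}"
        )
    return float(value)


class InteractionMatrix:
    """Symmetric per-pair cos(alpha) values for a set of labelled components."""

    def __init__(self, pairs: Optional[Mapping[tuple[str, str], float]] = None) -> None:
        self._values: dict[frozenset[str], float] = {}
        if pairs:
            for (a, b), v in pairs.items():
                self.set_pair(a, b, v)

    @classmethod
    def uniform(cls, labels: Iterable[str], cos_alpha: float) -> "InteractionMatrix":
        """All pairs share one coefficient (the modified-model simplification)."""
        m = cls()
        labels = list(labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                m.set_pair(a, b, cos_alpha)
        return m

    def set_pair(self, a: str, b: str, cos_alpha: float) -> None:
        if a == b:
            raise ConfigurationError(f"self-pair ({a!r}, {a!r}) is meaningless")
        self._values[frozenset((a, b))] = _check_cos_alpha(cos_alpha)

    def get(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self._values:
            raise ConfigurationError(
                f"interaction matrix has no cos(alpha) for pair ({a!r}, {b!r})"
            )
        return self._values[key]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._values


@dataclass(frozen=True)
class MixtureSample:
    """One odor sample: a set of component exposures, optionally panel-rated."""

    sample_id: str
    components: tuple[ComponentExposure, ...]
    measured_oi: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) < 1:
            raise ValidationError(f"sample {self.sample_id!r}: no components")
        abbrs = [c.odorant.abbreviation for c in self.components]
        if len(set(abbrs)) != len(abbrs):
            raise ValidationError(
                f"sample {self.sample_id!r}: duplicate component odorants {abbrs}"
            )
        if self.measured_oi is not None and not math.isfinite(self.measured_oi):
            raise ValidationError(f"sample {self.sample_id!r}: non-finite measured OI")


@dataclass
class PredictionResult:
    """Predicted OI of one sample under one model."""

    sample_id: str
    model_name: str
    predicted_oi: float
    clamped: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.predicted_oi < 0:
            raise ValidationError("predicted OI cannot be negative")


def _pair_product_sum(values: Sequence[float]) -> float:
    # sum over unordered pairs i<j of x_i * x_j
    total = math.fsum(values)
    squares = math.fsum(v * v for v in values)
    return 0.5 * (total * total - squares)


def _apply_subthreshold(values: Sequence[float], policy: str) -> tuple[list[float], list[str]]:
    if policy not in SUBTHRESHOLD_POLICIES:
        raise ConfigurationError(
            f"unknown sub-threshold policy {policy!r}; choose from {SUBTHRESHOLD_POLICIES}"
        )
    for v in values:
        if not math.isfinite(v):
            raise DomainError(f"lnOAV values must be finite, got {v!r}")
    below = [v for v in values if v < 0]
    if not below or policy == "keep":
        return list(values), []
    if policy == "error":
        raise DomainError(
            f"{len(below)} component(s) are sub-threshold (lnOAV < 0): {below}"
        )
    notes = [f"dropped {len(below)} sub-threshold component(s) (lnOAV < 0)"]
    return [v for v in values if v >= 0], notes


def _quadratic_form(values: Sequence[float], cos_alpha: float) -> tuple[float, bool]:
    """sqrt of the Vector-Model quadratic form, clamped at 0.

    Returns (value, clamped).  The radicand sum_i x_i^2 + 2 c sum_{i<j} x_i x_j
    can go negative once counteraction outweighs the squares (with c = -0.129
    this happens for 9 or more equal components); the square root is then
    clamped to 0 and flagged.
    """
    radicand = math.fsum(v * v for v in values) + 2.0 * cos_alpha * _pair_product_sum(values)
    if radicand < 0:
        return 0.0, True
    return math.sqrt(radicand), False


def vector_model(
    oi_values: Sequence[float],
    interactions: Union[InteractionMatrix, float],
    labels: Optional[Sequence[str]] = None,
) -> float:
    """Classic Vector Model: mixture OI from unmixed component intensities.

    ``interactions`` is either an :class:`InteractionMatrix` covering every
    pair (components identified by ``labels``, positional indices by
    default) or a single shared cos(alpha).
    """
    if len(oi_values) < 1:
        raise DomainError("vector model needs at least one component OI")
    for v in oi_values:
        if not (math.isfinite(v) and v >= 0):
            raise DomainError(f"component OIs must be >= 0, got {v!r}")
    if isinstance(interactions, InteractionMatrix):
        if labels is None:
            labels = [str(i) for i in range(len(oi_values))]
        if len(labels) != len(oi_values):
            raise ConfigurationError("labels and oi_values lengths differ")
        radicand = math.fsum(v * v for v in oi_values)
        for i in range(len(oi_values)):
            for j in range(i + 1, len(oi_values)):
                if len(oi_values) > 1:
                    c = interactions.get(labels[i], labels[j])
                    radicand += 2.0 * c * oi_values[i] * oi_values[j]
        if radicand < 0:
            warnings.warn("vector model radicand negative; clamping OI to 0")
            return 0.0
        return math.sqrt(radicand)
    value, clamped = _quadratic_form(oi_values, _check_cos_alpha(interactions))
    if clamped:
        warnings.warn("vector model radicand negative; clamping OI to 0")
    return value


def modified_vector_model(
    ln_oavs: Sequence[float],
    k: float = DEFAULT_SLOPE_K,
    cos_alpha: float = DEFAULT_COS_ALPHA,
    subthreshold: str = "drop",
) -> float:
    """Modified Vector Model: mixture OI directly from component lnOAVs.

    OI = k * sqrt(sum x_i^2 + 2 cos(alpha) sum_{i<j} x_i x_j) over the
    retained (supra-threshold, under the default policy) components.  For a
    single component this reduces to the individual law k*x.
    """
    value, _clamped, _notes = _modified_vector_model_detailed(
        ln_oavs, k, cos_alpha, subthreshold
    )
    return value


def _modified_vector_model_detailed(
    ln_oavs: Sequence[float],
    k: float = DEFAULT_SLOPE_K,
    cos_alpha: float = DEFAULT_COS_ALPHA,
    subthreshold: str = "drop",
) -> tuple[float, bool, list[str]]:
    if len(ln_oavs) < 1:
        raise DomainError("modified vector model needs at least one component")
    if not (math.isfinite(k) and k > 0):
        raise DomainError(f"slope k must be positive, got {k!r}")
    _check_cos_alpha(cos_alpha)
    retained, notes = _apply_subthreshold(ln_oavs, subthreshold)
    if not retained:
        notes.append("all components sub-threshold; predicted OI set to 0")
        return 0.0, False, notes
    value, clamped = _quadratic_form(retained, cos_alpha)
    if clamped:
        notes.append("negative radicand; predicted OI clamped to 0")
        warnings.warn(
            f"modified vector model radicand negative for {len(retained)} "
            "components; clamping OI to 0"
        )
    return k * value, clamped, notes


def strongest_component_model(
    ln_oavs: Sequence[float],
    k: float = DEFAULT_SLOPE_K,
    subthreshold: str = "drop",
) -> float:
    """Strongest Component Model: OI of the single most intense component."""
    if len(ln_oavs) < 1:
        raise DomainError("strongest component model needs at least one component")
    if not (math.isfinite(k) and k > 0):
        raise DomainError(f"slope k must be positive, got {k!r}")
    retained, _ = _apply_subthreshold(ln_oavs, subthreshold)
    if not retained:
        return 0.0
    return max(0.0, k * max(retained))


def summation_model(ln_oavs: Sequence[float], k: float = DEFAULT_SLOPE_K) -> float:
    """Additivity baseline: sum of the components' (non-negative) intensities."""
    if len(ln_oavs) < 1:
        raise DomainError("summation model needs at least one component")
    if not (math.isfinite(k) and k > 0):
        raise DomainError(f"slope k must be positive, got {k!r}")
    for v in ln_oavs:
        if not math.isfinite(v):
            raise DomainError(f"lnOAV values must be finite, got {v!r}")
    return math.fsum(k * max(v, 0.0) for v in ln_oavs)


def cos_alpha_from_pair(oi_ab: float, oi_a: float, oi_b: float) -> float:
    """Per-pair interaction coefficient from a measured binary-mixture OI.

    Inverts the classic Vector Model for one pair:
    cos(alpha) = (OI_ab^2 - OI_a^2 - OI_b^2) / (2 OI_a OI_b).
    """
    for label, v in (("OI_ab", oi_ab), ("OI_a", oi_a), ("OI_b", oi_b)):
        if not math.isfinite(v):
            raise DomainError(f"{label} must be finite")
    if oi_a <= 0 or oi_b <= 0:
        raise DomainError("component OIs must be positive to derive cos(alpha)")
    if oi_ab < 0:
        raise DomainError("mixture OI cannot be negative")
    return (oi_ab * oi_ab - oi_a * oi_a - oi_b * oi_b) / (2.0 * oi_a * oi_b)


def predict_sample(
    sample: MixtureSample,
    model_name: str,
    law: Optional[PsychophysicalLaw] = None,
    cos_alpha: float = DEFAULT_COS_ALPHA,
    interactions: Optional[InteractionMatrix] = None,
    subthreshold: str = "drop",
) -> PredictionResult:
    """Predict one sample's OI under a named model.

    Components resolve to lnOAV either directly or from concentration via
    their odorant's threshold; zero-concentration components are dropped
    with a warning (their logarithm is undefined).
    """
    if model_name not in MODEL_NAMES:
        raise ConfigurationError(
            f"unknown model {model_name!r}; choose from {MODEL_NAMES}"
        )
    law = law or PsychophysicalLaw()
    notes: list[str] = []
    ln_oavs: list[float] = []
    kept_labels: list[str] = []
    for comp in sample.components:
        x = comp.resolved_ln_oav()
        if x is None:
            notes.append(
                f"component {comp.odorant.abbreviation} has zero concentration; dropped"
            )
            continue
        ln_oavs.append(x)
        kept_labels.append(comp.odorant.abbreviation)
    if not ln_oavs:
        notes.append("no resolvable components; predicted OI set to 0")
        return PredictionResult(sample.sample_id, model_name, 0.0, False, notes)

    clamped = False
    if model_name == "mvm":
        value, clamped, more = _modified_vector_model_detailed(
            ln_oavs, law.slope_k, cos_alpha, subthreshold
        )
        notes.extend(more)
    elif model_name == "scm":
        value = strongest_component_model(ln_oavs, law.slope_k, subthreshold)
    elif model_name == "sum":
        value = summation_model(ln_oavs, law.slope_k)
    else:  # classic vector model on intensity units
        pairs = list(zip(kept_labels, ln_oavs))
        below = [x for x in ln_oavs if x < 0]
        if below:
            if subthreshold == "error":
                raise DomainError(
                    f"{len(below)} component(s) are sub-threshold (lnOAV < 0): {below}"
                )
            if subthreshold == "drop":
                notes.append(
                    f"dropped {len(below)} sub-threshold component(s) (lnOAV < 0)"
                )
                pairs = [(l, x) for l, x in pairs if x >= 0]
        if not pairs:
            notes.append("all components sub-threshold; predicted OI set to 0")
            return PredictionResult(sample.sample_id, model_name, 0.0, False, notes)
        labels = [l for l, _ in pairs]
        # classic model is defined on non-negative intensities
        ois = [max(0.0, oi_individual(law, x)) for _, x in pairs]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if interactions is None:
                value = vector_model(ois, cos_alpha)
            else:
                value = vector_model(ois, interactions, labels)
        if caught:
            clamped = True
            notes.append("negative radicand; predicted OI clamped to 0")
    return PredictionResult(sample.sample_id, model_name, value, clamped, notes)
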