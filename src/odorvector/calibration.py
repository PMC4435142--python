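"""Fitting the two model constants from sensory-panel data.

Two proportional (through-origin) regressions give everything the modified
Vector Model needs:

* slope ``k`` of panel OI on lnOAV over individual (unmixed) odor samples
  — the psychophysical law OI = k*lnOAV;
* slope ``beta`` of measured binary-mixture OI on the sum of the unmixed
  constituents' intensities (OI_sum) — the counteraction factor.

Substituting OI_mix = beta*(OI_a + OI_b) with equal-intensity constituents
(OI_a = OI_b, the standard preparation for determining the interaction
coefficient) into the classic Vector Model's cosine formula collapses to a
closed form:

    cos(alpha) = 2*beta**2 - 1.

For the aromatic reference family beta = 0.66, hence cos(alpha) = -0.129
(three decimals).  Both regressions are forced through the origin because
the laws they estimate have none: OI vanishes at the perception threshold
(lnOAV = 0), and a mixture of components with zero intensity has zero
intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence, Tuple

from .errors import DegenerateFitError, DomainError, ValidationError


class OriginFit(NamedTuple):
    """Least-squares slope of y on x through the origin, with diagnostics."""

    slope: float
    residual_rms: float
    n_points: int


def fit_origin_slope(points: Sequence[Tuple[float, float]]) -> OriginFit:
    """Least squares through the origin: slope = sum(xy) / sum(x^2)."""
    if len(points) < 2:
        raise DegenerateFitError(
            f"need at least 2 points for a through-origin fit, got {len(points)}"
        )
    for x, y in points:
        if not (math.isfinite(x) and math.isfinite(y)):
            raise DegenerateFitError(f"non-finite point ({x!r}, {y!r})")
    sxx = math.fsum(x * x for x, _ in points)
    if sxx <= 0:
        raise DegenerateFitError("all x values are zero; slope is undefined")
    sxy = math.fsum(x * y for x, y in points)
    slope = sxy / sxx
    rms = math.sqrt(
        math.fsum((y - slope * x) ** 2 for x, y in points) / len(points)
    )
    return OriginFit(slope=slope, residual_rms=rms, n_points=len(points))


def derive_cos_alpha(beta: float) -> float:
    """Interaction coefficient from the counteraction factor: 2*beta^2 - 1.

    beta must lie in [0, 1]; beta > 1 would imply cos(alpha) > 1, which no
    parallelogram angle permits.
    """
    if not (math.isfinite(beta) and 0.0 <= beta <= 1.0):
        raise DomainError(
            f"counteraction factor beta must lie in [0, 1], got {beta!r}"
        )
    return 2.0 * beta * beta - 1.0


def beta_from_cos_alpha(cos_alpha: float) -> float:
    """Inverse of :func:`derive_cos_alpha`: beta = sqrt((1 + cos(alpha)) / 2)."""
    if not (math.isfinite(cos_alpha) and -1.0 <= cos_alpha <= 1.0):
        raise DomainError(f"cos(alpha) must lie in [-1, 1], got {cos_alpha!r}")
    return math.sqrt((1.0 + cos_alpha) / 2.0)


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted constants with fit diagnostics.

    ``cos_alpha`` is always the closed form 2*beta^2 - 1 of the fitted beta,
    never an independent fit.  Full precision is kept here; reports round k
    to two decimals and cos(alpha) to three.
    """

    slope_k: float
    beta: float
    cos_alpha: float
    n_points_k: int
    n_points_beta: int
    residual_rms_k: float
    residual_rms_beta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValidationError("beta cannot be negative")
        if abs(self.cos_alpha - (2.0 * self.beta**2 - 1.0)) > 1e-12:
            raise ValidationError("cos_alpha must equal 2*beta^2 - 1")

    def summary_dict(self) -> dict:
        """Report-precision view (k two decimals, cos(alpha) three)."""
        return {
            "k": round(self.slope_k, 2),
            "beta": round(self.beta, 2),
            "cos_alpha": round(self.cos_alpha, 3),
            "n_points_k": self.n_points_k,
            "n_points_beta": self.n_points_beta,
            "residual_rms_k": round(self.residual_rms_k, 4),
            "residual_rms_beta": round(self.residual_rms_beta, 4),
        }


def calibrate(
    individual_data: Sequence[Tuple[float, float]],
    binary_data: Sequence[Tuple[float, float]],
) -> CalibrationResult:
    """Fit k and beta, derive cos(alpha).

    ``individual_data``: (lnOAV, panel OI) pairs for unmixed odor samples.
    ``binary_data``: (OI_sum, measured mixture OI) pairs for binary mixtures,
    where OI_sum is the sum of the unmixed constituents' intensities.

    Note: mixture lnOAV tables are *not* valid ``individual_data`` — the
    psychophysical slope must come from unmixed samples.
    """
    try:
        fit_k = fit_origin_slope(individual_data)
    except DegenerateFitError as exc:
        raise DegenerateFitError(f"individual (k) fit failed: {exc}") from None
    try:
        fit_beta = fit_origin_slope(binary_data)
    except DegenerateFitError as exc:
        raise DegenerateFitError(f"binary (beta) fit failed: {exc}") from None
    beta = fit_beta.slope
    if beta < 0:
        raise DomainError(
            f"fitted beta is negative ({beta:.4f}); mixture intensities "
            "cannot decrease with constituent intensity"
        )
    cos_alpha = derive_cos_alpha(min(beta, 1.0)) if beta <= 1.0 else None
    if cos_alpha is None:
        raise DomainError(
            f"fitted beta = {beta:.4f} exceeds 1; implied cos(alpha) > 1 is "
            "geometrically invalid (check that OI_sum is a true summation)"
        )
    return CalibrationResult(
        slope_k=fit_k.slope,
        beta=beta,
        cos_alpha=cos_alpha,
        n_points_k=fit_k.n_points,
        n_points_beta=fit_beta.n_points,
        residual_rms_k=fit_k.residual_rms,
        residual_rms_beta=fit_beta.residual_rms,
    )
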