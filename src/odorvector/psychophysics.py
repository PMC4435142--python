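"""Single-odorant psychophysics: OAV, lnOAV and the linear intensity law.

The perceived odor intensity (OI, on an odor intensity referencing scale)
of an individual odorant grows linearly with the natural logarithm of its
odor activity value,

    OI = k * ln(OAV),        OAV = C / C_Thr,

a Weber-Fechner-type law.  For the aromatic compounds the package ships as
its reference dataset the pooled slope is k = 1.07; other chemical families
need their own calibration (see :mod:`odorvector.calibration`).

lnOAV = 0 marks the perception threshold, so sub-threshold concentrations
(OAV < 1) have negative lnOAV and hence negative nominal OI.  This module
reports such values faithfully; what to do with them in a mixture is policy
and lives in :mod:`odorvector.mixture_models`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import DomainError, ValidationError
from .registry import Odorant

#: Pooled OI-lnOAV slope of the aromatic-compound reference panel.
DEFAULT_SLOPE_K = 1.07

# ideal-gas constant in L*atm/(mol*K); 1 mol of gas occupies 24.465 L at
# 298.15 K and 1 atm
_R_L_ATM = 0.082057


@dataclass(frozen=True)
class PsychophysicalLaw:
    """The linear OI = k*lnOAV law for one chemical family."""

    slope_k: float = DEFAULT_SLOPE_K

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope_k) and self.slope_k > 0):
            raise ValidationError(f"slope k must be positive, got {self.slope_k!r}")

    def oi(self, ln_oav_value: float) -> float:
        return oi_individual(self, ln_oav_value)


def oav(concentration: float, threshold: float) -> float:
    """Odor activity value: concentration over odor threshold (both mg/m^3)."""
    if not (math.isfinite(threshold) and threshold > 0):
        raise DomainError(f"odor threshold must be positive, got {threshold!r}")
    if not (math.isfinite(concentration) and concentration >= 0):
        raise DomainError(f"concentration must be >= 0, got {concentration!r}")
    return concentration / threshold


def ln_oav(oav_value: float) -> float:
    """Natural logarithm of an odor activity value (must be > 0).

    A zero OAV (absent component) has no logarithm; callers should treat
    the component as absent instead of calling this function.
    """
    if not (math.isfinite(oav_value) and oav_value > 0):
        raise DomainError(
            f"ln OAV requires OAV > 0, got {oav_value!r}; "
            "treat a zero-concentration component as absent"
        )
    return math.log(oav_value)


def oi_individual(law: PsychophysicalLaw, ln_oav_value: float) -> float:
    """Odor intensity of an individual odorant: k * lnOAV.

    Negative for sub-threshold input (lnOAV < 0); clamping is the caller's
    policy decision.
    """
    if not math.isfinite(ln_oav_value):
        raise DomainError(f"lnOAV must be finite, got {ln_oav_value!r}")
    return law.slope_k * ln_oav_value


def convert_units(value_ppm: float, molecular_weight: float,
                  temperature: float = 298.15, pressure: float = 1.0) -> float:
    """Convert a ppm (v/v) gas concentration to mg/m^3 by the ideal-gas law.

    mg/m^3 = ppm * MW * P / (R' * T); at 298.15 K and 1 atm this is the
    familiar ppm * MW / 24.465.
    """
    if not (math.isfinite(value_ppm) and value_ppm >= 0):
        raise DomainError(f"ppm value must be >= 0, got {value_ppm!r}")
    for label, v in (("molecular weight", molecular_weight),
                     ("temperature", temperature), ("pressure", pressure)):
        if not (math.isfinite(v) and v > 0):
            raise DomainError(f"{label} must be positive, got {v!r}")
    molar_volume = _R_L_ATM * temperature / pressure  # L/mol
    return value_ppm * molecular_weight / molar_volume


@dataclass(frozen=True)
class ComponentExposure:
    """One odorant's exposure in one sample: concentration and/or lnOAV.

    At least one of ``concentration`` (mg/m^3) and ``ln_oav`` must be given;
    if both are, they must agree through the odorant's threshold to 1e-9.
    """

    odorant: Odorant
    concentration: Optional[float] = None
    ln_oav: Optional[float] = None

    def __post_init__(self) -> None:
        if self.concentration is None and self.ln_oav is None:
            raise ValidationError(
                f"component {self.odorant.abbreviation}: need concentration or lnOAV"
            )
        if self.concentration is not None:
            if not (math.isfinite(self.concentration) and self.concentration >= 0):
                raise ValidationError(
                    f"component {self.odorant.abbreviation}: concentration must be "
                    f">= 0, got {self.concentration!r}"
                )
        if self.ln_oav is not None and not math.isfinite(self.ln_oav):
            raise ValidationError(
                f"component {self.odorant.abbreviation}: lnOAV must be finite"
            )
        if self.concentration is not None and self.ln_oav is not None:
            if self.concentration <= 0:
                raise ValidationError(
                    f"component {self.odorant.abbreviation}: zero concentration "
                    "is inconsistent with a finite lnOAV"
                )
            implied = math.log(self.concentration / self.odorant.odor_threshold)
            if abs(implied - self.ln_oav) > 1e-9:
                raise ValidationError(
                    f"component {self.odorant.abbreviation}: lnOAV {self.ln_oav} "
                    f"inconsistent with concentration (implies {implied:.9f})"
                )

    def resolved_ln_oav(self) -> Optional[float]:
        """lnOAV, computed from concentration if not given directly.

        Returns None for a zero-concentration component (ln undefined:
        the component is absent).
        """
        if self.ln_oav is not None:
            return self.ln_oav
        if self.concentration == 0:
            return None
        return ln_oav(oav(self.concentration, self.odorant.odor_threshold))
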