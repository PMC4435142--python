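"""Odorant identities and odor thresholds.

The odor threshold C_Thr of an odorant is the lowest gas-phase concentration
the human nose can perceive; it is the denominator of every odor activity
value (OAV = C / C_Thr) and therefore the anchor of all intensity
predictions in this package.  Thresholds are stored in mg/m^3 exclusively;
conversion from ppm lives in :mod:`odorvector.psychophysics`.

Abbreviations are single-letter, case-sensitive identifiers (``B`` for
benzene is not ``b``).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import UnknownOdorantError, ValidationError

_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


@dataclass(frozen=True)
class Odorant:
    """One odorant: identity plus odor threshold in mg/m^3."""

    name: str
    abbreviation: str
    cas_number: str
    odor_threshold: float

    def __post_init__(self) -> None:
        if not self.abbreviation:
            raise ValidationError(f"odorant {self.name!r}: empty abbreviation")
        if not (isinstance(self.odor_threshold, (int, float))
                and math.isfinite(self.odor_threshold)
                and self.odor_threshold > 0):
            raise ValidationError(
                f"odorant {self.name!r}: odor threshold must be a finite positive "
                f"number in mg/m^3, got {self.odor_threshold!r}"
            )
        if self.cas_number and not _CAS_RE.match(self.cas_number):
            raise ValidationError(
                f"odorant {self.name!r}: malformed CAS number {self.cas_number!r}"
            )


class OdorantRegistry:
    """Ordered collection of odorants, keyed by abbreviation or CAS number."""

    def __init__(self, odorants: Iterable[Odorant] = ()) -> None:
        self._by_abbr: dict[str, Odorant] = {}
        self._by_cas: dict[str, Odorant] = {}
        for od in odorants:
            self.add(od)

    def add(self, odorant: Odorant) -> None:
        if odorant.abbreviation in self._by_abbr:
            raise ValidationError(
                f"duplicate abbreviation {odorant.abbreviation!r} in registry"
            )
        if odorant.cas_number and odorant.cas_number in self._by_cas:
            raise ValidationError(
                f"duplicate CAS number {odorant.cas_number!r} in registry"
            )
        self._by_abbr[odorant.abbreviation] = odorant
        if odorant.cas_number:
            self._by_cas[odorant.cas_number] = odorant

    def get(self, key: str) -> Odorant:
        """Look up by abbreviation (case-sensitive) or CAS registry number."""
        if key in self._by_abbr:
            return self._by_abbr[key]
        if key in self._by_cas:
            return self._by_cas[key]
        raise UnknownOdorantError(
            f"unknown odorant {key!r}; available abbreviations: "
            f"{sorted(self._by_abbr)} and CAS numbers: {sorted(self._by_cas)}"
        )

    def __getitem__(self, key: str) -> Odorant:
        return self.get(key)

    def __contains__(self, key: str) -> bool:
        return key in self._by_abbr or key in self._by_cas

    def __iter__(self) -> Iterator[Odorant]:
        return iter(self._by_abbr.values())

    def __len__(self) -> int:
        return len(self._by_abbr)

    @property
    def abbreviations(self) -> list[str]:
        return list(self._by_abbr)


_COLUMNS = ("abbreviation", "name", "cas", "odor_threshold_mg_m3")


def load_thresholds(path: str | Path) -> OdorantRegistry:
    """Read a threshold table CSV into a registry.

    Expected columns: ``abbreviation,name,cas,odor_threshold_mg_m3`` with a
    header row, UTF-8, dot decimal separator.  Rows with missing or
    non-positive thresholds and duplicate abbreviations are rejected with an
    error naming the offending row.
    """
    path = Path(path)
    registry = OdorantRegistry()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            raw = (row["odor_threshold_mg_m3"] or "").strip()
            try:
                threshold = float(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: threshold {raw!r} is not a number"
                ) from None
            try:
                odorant = Odorant(
                    name=row["name"].strip(),
                    abbreviation=row["abbreviation"].strip(),
                    cas_number=(row["cas"] or "").strip(),
                    odor_threshold=threshold,
                )
                registry.add(odorant)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return registry


def save_thresholds(registry: OdorantRegistry, path: str | Path) -> None:
    """Write a registry back to the threshold CSV format (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for od in registry:
            writer.writerow([od.abbreviation, od.name, od.cas_number,
                             repr(od.odor_threshold)])
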