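"""Bundled reference datasets: the aromatic-compound study tables.

Three small CSVs ship with the package:

* ``thresholds.csv`` — odor thresholds (mg/m^3) of seven aromatic
  compounds: benzene, toluene, ethylbenzene, n-propylbenzene, o-xylene,
  m-xylene, styrene.
* ``mixture_reference.csv`` — fifteen panel-rated binary/ternary/quaternary
  mixture samples of those compounds, with per-component lnOAV and the
  panel-mean measured OI.
* ``reference_predictions.csv`` — the model predictions as originally
  tabulated at one decimal, used as expected values in tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_samples_csv
from .mixture_models import MixtureSample
from .registry import OdorantRegistry, load_thresholds


def _data_path(name: str):
    return resources.files("odorvector.data").joinpath(name)


def load_reference_thresholds() -> OdorantRegistry:
    """Registry of the seven aromatic reference odorants."""
    with resources.as_file(_data_path("thresholds.csv")) as path:
        return load_thresholds(path)


def load_reference_mixtures() -> list[MixtureSample]:
    """The fifteen panel-rated reference mixture samples (lnOAV encoded)."""
    registry = load_reference_thresholds()
    with resources.as_file(_data_path("mixture_reference.csv")) as path:
        return read_samples_csv(path, registry)


def load_reference_predictions() -> pd.DataFrame:
    """Originally tabulated one-decimal predictions per sample.

    Columns: sample_id, n_components, oi_measured, oi_mvm_reported,
    oi_scm_reported.  Note the three quaternary modified-Vector-Model cells
    sit about 0.1 below direct evaluation of the model formula — an
    intermediate-rounding artifact of the source table (see
    docs/methods.md); tests treat them with a +/-0.15 band.
    """
    with resources.as_file(_data_path("reference_predictions.csv")) as path:
        return pd.read_csv(path, dtype={"sample_id": str})
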