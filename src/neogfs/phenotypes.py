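"""Brain phenotype indices.

The two indices used throughout the pipeline:

* neocortex ratio ``Nr = neocortex_volume / (brain_volume - neocortex_volume)``
  (Dunbar's ratio of neocortex to rest-of-brain volume);
* encephalization index ``Ei = log(brain_mass) - b * log(body_mass)`` with an
  allometric slope ``b = 0.64``, i.e. the residual (log) brain size after
  body-size correction.

For the packaged real-data table, Ei values are consumed as given (the body
masses behind them are not part of the table and the regression intercept
convention differs between sources); ``compute_ei`` serves the synthetic
pathway.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np
import pandas as pd

from .data_io import PhenotypeTable

ALLOMETRIC_SLOPE = 0.64

Number = Union[float, np.ndarray]


def compute_nr(brain_volume: Number, neocortex_volume: Number) -> Number:
    """Neocortex ratio: neocortex volume over rest-of-brain volume.

    Both volumes in the same units (cm^3); requires
    ``0 < neocortex_volume < brain_volume``.
    """
    brain = np.asarray(brain_volume, dtype=float)
    neo = np.asarray(neocortex_volume, dtype=float)
    if np.any(brain <= 0) or np.any(neo <= 0):
        raise ValueError("volumes must be positive")
    if np.any(neo >= brain):
        raise ValueError("neocortex volume must be smaller than total brain volume")
    out = neo / (brain - neo)
    return float(out) if out.ndim == 0 else out


def compute_ei(brain_mass: Number, body_mass: Number,
               b: float = ALLOMETRIC_SLOPE, log_base: str = "e") -> Number:
    """Encephalization index ``log(brain) - b * log(body)``.

    Masses in grams; ``log_base`` is ``"e"`` (default) or ``"10"``. With
    ``b = 0`` this degenerates to the log brain mass.
    """
    brain = np.asarray(brain_mass, dtype=float)
    body = np.asarray(body_mass, dtype=float)
    if np.any(brain <= 0) or np.any(body <= 0):
        raise ValueError("masses must be positive")
    if b < 0:
        raise ValueError("allometric slope must be non-negative")
    log = np.log if log_base == "e" else np.log10
    if log_base not in ("e", "10"):
        raise ValueError("log_base must be 'e' or '10'")
    out = log(brain) - b * log(body)
    return float(out) if out.ndim == 0 else out


def validate_nr_consistency(table: PhenotypeTable, tol: float = 0.01) -> pd.DataFrame:
    """Report, per species, whether the stored Nr agrees with the Nr recomputed
    from the stored volumes.

    Status is ``consistent`` when |computed - stored| <= ``tol``,
    ``inconsistent`` otherwise, and ``printed-only`` when the volumes are
    missing or unusable. Purely diagnostic; never mutates the table.
    """
    rows = []
    for rec in table:
        try:
            computed = compute_nr(rec.brain_volume, rec.neocortex_volume)
        except (ValueError, TypeError):
            rows.append((rec.species_id, math.nan, rec.nr, "printed-only"))
            continue
        status = "consistent" if abs(computed - rec.nr) <= tol else "inconsistent"
        rows.append((rec.species_id, computed, rec.nr, status))
    return pd.DataFrame(rows, columns=["species", "computed_nr", "stored_nr", "status"])
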