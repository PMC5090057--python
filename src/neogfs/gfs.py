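"""Gene-family inclusion filters.

A family enters the analysis only if it has members in at least ``min_species``
of the analysed species (default 6 of 28) and its size varies across species
at all — constant families carry no comparative signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GeneFamilyMatrix


@dataclass(frozen=True)
class FamilyFilterReport:
    """Stage-wise family counts through the inclusion filters."""

    n_input: int
    n_present_ge_min: int
    n_nonzero_variance: int
    kept_ids: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_present_ge_min": self.n_present_ge_min,
            "n_nonzero_variance": self.n_nonzero_variance,
            "n_kept": len(self.kept_ids),
        }


def filter_families(matrix: GeneFamilyMatrix,
                    min_species: int = 6) -> tuple[GeneFamilyMatrix, FamilyFilterReport]:
    """Keep families present (size >= 1) in at least ``min_species`` species and
    with non-zero size variance across all species columns (zeros included)."""
    if min_species > matrix.n_species:
        raise ValueError(
            f"min_species ({min_species}) exceeds number of species ({matrix.n_species})"
        )
    sizes = matrix.sizes
    present = (sizes > 0).sum(axis=1) >= min_species
    variable = sizes.var(axis=1) > 0
    keep = present & variable
    kept_ids = tuple(f for f, k in zip(matrix.family_ids, keep) if k)
    report = FamilyFilterReport(
        n_input=matrix.n_families,
        n_present_ge_min=int(present.sum()),
        n_nonzero_variance=int(keep.sum()),
        kept_ids=kept_ids,
    )
    return matrix.subset(list(kept_ids)), report
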