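"""OD600 growth-curve phenotyping.

Growth on a carbohydrate is scored from the 12-h optical density.  Two
threshold schemes coexist: a three-way growth category (good > 0.5,
moderate in [0.4, 0.5], none < 0.4) and a binary call for matching
(0 below 0.3, 1 above 0.4).  The binary scheme leaves the interval
[0.3, 0.4] unassigned; such readings are surfaced as INDETERMINATE rather
than silently forced to either call, and downstream matching chooses how
to treat them (counted as 0 by default, or excluded under a strict
policy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "INDETERMINATE",
    "GOOD",
    "MODERATE",
    "NONE",
    "PhenotypeMatrix",
    "categorize_growth",
    "binarize_phenotype",
    "build_phenotype_matrix",
    "select_differential",
]

#: sentinel for 12-h readings inside the unassigned [0.3, 0.4] band
INDETERMINATE = pd.NA

GOOD = "good"
MODERATE = "moderate"
NONE = "none"

# thresholds, in OD600 units at 12 h
GOOD_GROWTH_OD = 0.5      # category: good above this
NO_GROWTH_OD = 0.4        # category: none below this
BINARY_ZERO_OD = 0.3      # binary call 0 below this
BINARY_ONE_OD = 0.4       # binary call 1 above this


def categorize_growth(od12: float) -> str:
    """Three-way growth category from the 12-h OD600."""
    if od12 < 0:
        raise ValueError(f"negative OD600: {od12}")
    if od12 > GOOD_GROWTH_OD:
        return GOOD
    if od12 >= NO_GROWTH_OD:
        return MODERATE
    return NONE


def binarize_phenotype(od12: float):
    """Binary growth call from the 12-h OD600 (0, 1, or INDETERMINATE)."""
    if od12 < 0:
        raise ValueError(f"negative OD600: {od12}")
    if od12 < BINARY_ZERO_OD:
        return 0
    if od12 > BINARY_ONE_OD:
        return 1
    return INDETERMINATE


@dataclass
class PhenotypeMatrix:
    """Carbohydrates (rows) x strains (columns) binary growth calls.

    ``calls`` holds 0/1 with ``pd.NA`` for indeterminate readings
    (nullable Int64).  ``controls`` lists carbohydrate rows flagged as
    positive controls; they are retained in the matrix but excluded from
    trait matching by default.
    """

    calls: pd.DataFrame
    controls: set[str] = field(default_factory=set)

    @property
    def carbohydrates(self) -> list[str]:
        return list(self.calls.index)

    @property
    def strains(self) -> list[str]:
        return list(self.calls.columns)

    def n_indeterminate(self) -> int:
        return int(self.calls.isna().to_numpy().sum())


def build_phenotype_matrix(
    curves: pd.DataFrame,
    time_h: float = 12,
    control: str = "lactose",
) -> PhenotypeMatrix:
    """Binarize the chosen timepoint of a long-format growth-curve table.

    ``curves`` has columns (strain, carbohydrate, time_h, od600); every
    (strain, carbohydrate) pair must include a reading at ``time_h``.
    Rows and columns come out sorted; a carbohydrate named ``control`` is
    flagged as the positive control.
    """
    required = {"strain", "carbohydrate", "time_h", "od600"}
    missing_cols = required - set(curves.columns)
    if missing_cols:
        raise ValueError(f"curve table lacks columns: {sorted(missing_cols)}")
    strains = sorted(curves["strain"].unique())
    carbs = sorted(curves["carbohydrate"].unique())
    at_t = curves[curves["time_h"] == time_h]
    lut = {
        (row.strain, row.carbohydrate): row.od600
        for row in at_t.itertuples(index=False)
    }
    calls = pd.DataFrame(index=carbs, columns=strains, dtype="Int64")
    for carb in carbs:
        for s in strains:
            if (s, carb) not in lut:
                raise ValueError(
                    f"missing {time_h} h reading for strain {s!r} on {carb!r}"
                )
            calls.at[carb, s] = binarize_phenotype(float(lut[s, carb]))
    controls = {control} if control in carbs else set()
    return PhenotypeMatrix(calls=calls, controls=controls)


def select_differential(matrix: PhenotypeMatrix) -> list[str]:
    """Carbohydrates with a differential utilization profile.

    A row qualifies when it contains at least one 0 and at least one 1
    (indeterminate calls are ignored for the criterion); all-0 and all-1
    rows carry no matching signal and are excluded, as are control rows.
    """
    out = []
    for carb in matrix.carbohydrates:
        if carb in matrix.controls:
            continue
        row = matrix.calls.loc[carb].dropna()
        if (row == 0).any() and (row == 1).any():
            out.append(carb)
    return out
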