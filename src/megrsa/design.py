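"""Factorial stimulus design: 2 (size) x 2 (clutter) x 2 (contrast) x
2 (luminance) x n exemplars.

The default design crosses two scene properties (physical size, clutter
level) with two image properties (RMS contrast, RMS luminance) and carries
three exemplar images per factor-level combination, i.e. 48 conditions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

#: Factor names in canonical order.
FACTORS: tuple[str, ...] = ("size", "clutter", "contrast", "luminance")

#: Factor levels, first level listed is the "low" pole of the factor.
LEVELS: dict[str, tuple[str, str]] = {
    "size": ("small", "large"),
    "clutter": ("low", "high"),
    "contrast": ("low", "high"),
    "luminance": ("low", "high"),
}


@dataclass(frozen=True)
class Design:
    """Condition table mapping condition ids to factor levels and exemplars.

    ``table`` has columns ``condition_id`` (1..n, dense), one column per
    factor in :data:`FACTORS`, and ``exemplar`` (1..n_exemplars).
    """

    table: pd.DataFrame

    @property
    def n_conditions(self) -> int:
        return len(self.table)

    @property
    def n_exemplars(self) -> int:
        return int(self.table["exemplar"].max())

    @property
    def condition_ids(self) -> pd.Series:
        return self.table["condition_id"]

    def levels(self, factor: str) -> pd.Series:
        """Per-condition level labels of one factor, in condition order."""
        if factor not in FACTORS:
            raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
        return self.table[factor]

    def combination_key(self) -> pd.Series:
        """Per-condition string key identifying the factor-level combination."""
        return self.table[list(FACTORS)].agg("|".join, axis=1)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Design":
        table = pd.read_csv(path)
        design = cls(table=table)
        design.validate()
        return design

    def validate(self) -> None:
        ids = self.table["condition_id"].to_numpy()
        if len(set(ids)) != len(ids) or sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValueError("condition_ids must be unique and dense starting at 1")
        counts = self.table.groupby(list(FACTORS), observed=True).size()
        if counts.nunique() != 1:
            raise ValueError("unbalanced design: unequal exemplars per combination")


def generate_design(n_exemplars: int = 3) -> Design:
    """Build the full factorial crossing of the four binary factors.

    Parameters
    ----------
    n_exemplars
        Number of exemplar images per factor-level combination (3 in the
        experimental design, giving 16 x 3 = 48 conditions).

    The ordering is deterministic: factors vary slowest-to-fastest in
    :data:`FACTORS` order, exemplar fastest.
    """
    if not isinstance(n_exemplars, int) or n_exemplars < 1:
        raise ValueError(f"n_exemplars must be a positive integer, got {n_exemplars!r}")
    rows = []
    for levels in itertools.product(*(LEVELS[f] for f in FACTORS)):
        for ex in range(1, n_exemplars + 1):
            rows.append(dict(zip(FACTORS, levels), exemplar=ex))
    table = pd.DataFrame(rows)
    table.insert(0, "condition_id", range(1, len(table) + 1))
    return Design(table=table)
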