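"""Pairwise spatial segregation: the normalised checkerboard score.

For a species pair occupying ``r1`` and ``r2`` sites with ``S`` sites shared,

    C = (r1 - S)(r2 - S) / (r1 * r2)

which is 0 under complete sympatry (both species share all their sites) and
1 under complete segregation (no shared site), the normalised form of the
Stone & Roberts checkerboard-unit count.  Sites occupied by neither species
do not enter the score.  The same formula applies at any spatial grain —
survey plots or continental atlas cells — by changing what a "site" is.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError

__all__ = ["CScoreResult", "c_score", "c_score_all_pairs", "validate_occurrence"]


@dataclass(frozen=True)
class CScoreResult:
    """C-score of one species pair plus the raw occupancy counts."""

    species_a: str
    species_b: str
    r1: int          # sites occupied by species_a
    r2: int          # sites occupied by species_b
    shared: int      # jointly occupied sites
    c_score: float

    def __post_init__(self):
        if self.shared > min(self.r1, self.r2):
            raise ValidationError("shared count exceeds a species total")
        if not 0.0 <= self.c_score <= 1.0:
            raise ValidationError("c_score out of [0, 1]")


def validate_occurrence(occ: pd.DataFrame) -> pd.DataFrame:
    """Check 0/1 entries and unique ids; return the species-only block."""
    block = occ.drop(columns=["site_id"], errors="ignore")
    vals = block.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError("occurrence entries must be 0/1")
    if "site_id" in occ.columns and occ["site_id"].duplicated().any():
        raise ValidationError("duplicate site ids")
    if block.columns.duplicated().any():
        raise ValidationError("duplicate species names")
    return block


def c_score(occ: pd.DataFrame, a: str, b: str) -> CScoreResult:
    """Normalised checkerboard score for species ``a`` and ``b``.

    Raises
    ------
    ComputationError
        If either species occupies no site (the score is undefined).
    """
    block = validate_occurrence(occ)
    for s in (a, b):
        if s not in block.columns:
            raise ValidationError(f"unknown species {s!r}")
    ya = block[a].to_numpy()
    yb = block[b].to_numpy()
    r1 = int(ya.sum())
    r2 = int(yb.sum())
    if r1 == 0 or r2 == 0:
        absent = a if r1 == 0 else b
        raise ComputationError(
            f"species {absent!r} occurs nowhere; C-score undefined")
    shared = int((ya & yb).sum())
    score = (r1 - shared) * (r2 - shared) / (r1 * r2)
    return CScoreResult(a, b, r1, r2, shared, float(score))


def c_score_all_pairs(occ: pd.DataFrame) -> list[CScoreResult]:
    """C-score for every unordered species pair in the matrix."""
    block = validate_occurrence(occ)
    species = list(block.columns)
    if len(species) < 2:
        raise ValidationError("need at least 2 species")
    return [c_score(occ, a, b) for a, b in combinations(species, 2)]
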