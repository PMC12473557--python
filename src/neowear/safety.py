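"""Paired Neonatal Skin Condition Score (NSCS) analysis.

NSCS grades neonatal skin from 3 (intact) to 9 (very poor). Skin is scored
before sensor placement and after removal on each study day; the analysis
pairs the two phases per (infant, day) and tests the paired differences
with a Wilcoxon signed-rank test under explicitly configurable
conventions:

* zeros dropped before ranking (default) or Pratt-style kept in ranking;
* mid-ranks on tied absolute differences;
* normal approximation, tie correction of the variance OFF by default and
  no continuity correction;
* test direction before-minus-after by default, so a positive statistic
  reflects skin-score decreases.

These defaults form the unique common convention set under which the
published z statistic for the pooled 73-pair table reproduces exactly;
every alternative is available through keyword arguments.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Phase",
    "ZeroHandling",
    "Direction",
    "SkinAssessment",
    "PairedDelta",
    "SignedRankResult",
    "pair_scores",
    "wilcoxon_signed_rank",
]


class Phase(str, enum.Enum):
    BEFORE = "BEFORE"
    AFTER = "AFTER"


class ZeroHandling(str, enum.Enum):
    DROP = "DROP"    # discard zero differences before ranking (Wilcoxon)
    PRATT = "PRATT"  # rank zeros, then drop them from the statistic


class Direction(str, enum.Enum):
    BEFORE_MINUS_AFTER = "BEFORE_MINUS_AFTER"
    AFTER_MINUS_BEFORE = "AFTER_MINUS_BEFORE"


@dataclass(frozen=True)
class SkinAssessment:
    infant_id: str
    day_index: int
    phase: Phase
    nscs: int

    def __post_init__(self):
        if not 3 <= self.nscs <= 9:
            raise ValueError(f"NSCS {self.nscs} outside [3, 9]")
        if not 1 <= self.day_index <= 4:
            raise ValueError("day_index must be 1..4")


@dataclass(frozen=True)
class PairedDelta:
    """After-minus-before score change for one infant-day."""

    infant_id: str
    day_index: int
    delta: int

    def __post_init__(self):
        if not -6 <= self.delta <= 6:
            raise ValueError("delta outside [-6, 6]")


def pair_scores(
    assessments: list[SkinAssessment],
) -> tuple[list[PairedDelta], list[SkinAssessment]]:
    """Pair before/after assessments per (infant, day).

    Returns ``(pairs, unpaired)`` where ``unpaired`` lists assessments
    lacking their counterpart. Duplicate (infant, day, phase) entries
    raise ``ValueError``.
    """
    table: dict[tuple[str, int], dict[Phase, SkinAssessment]] = {}
    for a in assessments:
        slot = table.setdefault((a.infant_id, a.day_index), {})
        if a.phase in slot:
            raise ValueError(
                f"duplicate assessment for ({a.infant_id}, day {a.day_index}, "
                f"{a.phase.value})"
            )
        slot[a.phase] = a
    pairs: list[PairedDelta] = []
    unpaired: list[SkinAssessment] = []
    for (infant, day), slot in table.items():
        if Phase.BEFORE in slot and Phase.AFTER in slot:
            pairs.append(
                PairedDelta(infant, day, slot[Phase.AFTER].nscs - slot[Phase.BEFORE].nscs)
            )
        else:
            unpaired.extend(slot.values())
    return pairs, unpaired


@dataclass(frozen=True)
class SignedRankResult:
    w_plus: float
    z: float
    p_two_sided: float
    n_used: int
    all_zero: bool = False

    def __str__(self):  # pragma: no cover - cosmetic
        if self.all_zero:
            return "signed-rank: all differences zero (no information)"
        return f"signed-rank: W+={self.w_plus:g}, z={self.z:.2f}, p={self.p_two_sided:.2g}"


def wilcoxon_signed_rank(
    deltas,
    zero_handling: ZeroHandling = ZeroHandling.DROP,
    tie_correction: bool = False,
    direction: Direction = Direction.BEFORE_MINUS_AFTER,
) -> SignedRankResult:
    """Wilcoxon signed-rank test on after-minus-before differences.

    Parameters
    ----------
    deltas
        Integer (or float) differences, oriented after-minus-before as in
        :class:`PairedDelta`. With the default ``direction`` they are
        negated before testing so the statistic is computed on
        before-minus-after differences.
    zero_handling
        ``DROP`` discards zero differences; ``PRATT`` ranks them jointly
        with the non-zeros and then removes their contribution.
    tie_correction
        When True, subtract the tied-rank term ``sum(t^3 - t)/48`` from
        the null variance.
    direction
        Orientation of the differences actually tested.

    Returns the one-sample statistic ``W+`` (sum of ranks of positive
    differences), the normal-approximation z without continuity
    correction, and the two-sided p. If every difference is zero a
    structured "no information" result is returned rather than raising.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one difference")
    if direction is Direction.BEFORE_MINUS_AFTER:
        d = -d

    nonzero = d[d != 0]
    if nonzero.size == 0:
        # no usable pairs: report total agreement rather than raising
        return SignedRankResult(w_plus=0.0, z=0.0, p_two_sided=1.0,
                                n_used=0, all_zero=True)

    if zero_handling is ZeroHandling.DROP:
        ranked = nonzero
        n = ranked.size
        ranks = stats.rankdata(np.abs(ranked))
        w_plus = float(ranks[ranked > 0].sum())
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        tie_source = ranked
    elif zero_handling is ZeroHandling.PRATT:
        n_all = d.size
        n0 = n_all - nonzero.size
        ranks = stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        mean = (n_all * (n_all + 1) - n0 * (n0 + 1)) / 4.0
        var = (n_all * (n_all + 1) * (2 * n_all + 1)
               - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0
        n = nonzero.size
        tie_source = nonzero
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(zero_handling)

    if tie_correction:
        _, counts = np.unique(np.abs(tie_source), return_counts=True)
        var -= float(((counts.astype(float) ** 3 - counts).sum()) / 48.0)

    if var <= 0:
        return SignedRankResult(w_plus=w_plus, z=float("nan"),
                                p_two_sided=float("nan"), n_used=int(n))
    z = (w_plus - mean) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return SignedRankResult(w_plus=w_plus, z=float(z), p_two_sided=float(p),
                            n_used=int(n))
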