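"""Recover replacement-pattern parameters from per-locus observations.

Mirrors, as explicit statistics, the qualitative readings made from the
scanned jaws: which wave spacing best explains the set of actively replacing
loci (every second vs every third tooth), which way the wave runs (the more
distal replacement being further developed implies back-to-front), and how
synchronized the left and right sides of a jaw are.  All scores are
descriptive match fractions — no likelihoods, matching how the anatomical
argument is actually made.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .records import LocusObservation, ToothClass

__all__ = [
    "Direction",
    "DirectionResult",
    "PatternReport",
    "development_ordinal",
    "score_spacing",
    "infer_direction",
    "synchrony_score",
    "synchrony_mismatches",
    "infer_pattern",
]


class Direction(str, Enum):
    BACK_TO_FRONT = "back_to_front"
    FRONT_TO_BACK = "front_to_back"
    INDETERMINATE = "indeterminate"


def development_ordinal(obs: LocusObservation) -> int | None:
    """Ordinal development score of the replacement at a locus.

    1 = crypt only, 2 = mineralized replacement tooth, 3 = replacement far
    enough along that the incumbent's root is resorbing.  None when the locus
    shows no replacement activity.
    """
    if "replacement_present" in obs.flags:
        return 3 if "resorbing" in obs.flags else 2
    if "crypt_present" in obs.flags:
        return 1
    return None


def _active_positions(obs: Iterable[LocusObservation] | Iterable[int]) -> list[int]:
    positions = []
    for item in obs:
        if isinstance(item, LocusObservation):
            if item.replacement_active:
                positions.append(item.locus_index)
        else:
            positions.append(int(item))
    return sorted(set(positions))


def score_spacing(obs: Iterable[LocusObservation] | Iterable[int], k: int) -> float:
    """Fraction of actively replacing loci explained by one wave of period k.

    Over all residue offsets r mod k, the best-covered residue class's share
    of the active loci; 1.0 means the activity is perfectly periodic with
    period k (e.g. loci {1, 4, 7} at k = 3).
    """
    if k < 2:
        raise ValueError("candidate spacing must be at least 2")
    active = _active_positions(obs)
    if len(active) < 2:
        raise ValueError("need at least 2 active loci to score a spacing")
    best = max(sum(1 for p in active if p % k == r) for r in range(k))
    return best / len(active)


@dataclass(frozen=True)
class DirectionResult:
    direction: Direction
    statistic: int      # concordant minus discordant pairs (exact, small n)
    n_pairs: int


def infer_direction(
    obs: Iterable[LocusObservation] | Mapping[int, int],
    floor: int = 0,
) -> DirectionResult:
    """Wave direction from the development gradient along the row.

    Uses an exact Kendall-style count of concordant vs discordant
    (locus index, development ordinal) pairs: replacements growing more
    developed distally indicate a back-to-front wave.  When the absolute
    statistic does not exceed ``floor`` (default 0: any nonzero gradient
    counts) the direction is reported as indeterminate rather than guessed.
    """
    if isinstance(obs, Mapping):
        ordinals = {int(k): int(v) for k, v in obs.items()}
    else:
        ordinals = {}
        for o in obs:
            rank = development_ordinal(o)
            if rank is not None:
                ordinals[o.locus_index] = rank
    loci = sorted(ordinals)
    if len(loci) < 2:
        raise ValueError("need at least 2 active loci with development ordinals")
    concordant = discordant = 0
    for i, a in enumerate(loci):
        for b in loci[i + 1:]:
            diff = ordinals[b] - ordinals[a]  # b is the more distal locus
            if diff > 0:
                concordant += 1
            elif diff < 0:
                discordant += 1
    statistic = concordant - discordant
    n_pairs = len(loci) * (len(loci) - 1) // 2
    if statistic > floor:
        direction = Direction.BACK_TO_FRONT
    elif statistic < -floor:
        direction = Direction.FRONT_TO_BACK
    else:
        direction = Direction.INDETERMINATE
    return DirectionResult(direction=direction, statistic=statistic, n_pairs=n_pairs)


def _activity_map(obs: Iterable[LocusObservation]) -> dict[int, bool]:
    actives: dict[int, bool] = {}
    for o in obs:
        actives[o.locus_index] = actives.get(o.locus_index, False) or o.replacement_active
    return actives


def synchrony_mismatches(
    left: Iterable[LocusObservation],
    right: Iterable[LocusObservation],
) -> tuple[float, list[int]]:
    """Synchrony score plus the loci where the two sides disagree."""
    lmap, rmap = _activity_map(left), _activity_map(right)
    union = sorted(set(lmap) | set(rmap))
    if not union:
        raise ValueError("no observed loci on either side")
    mismatched = [p for p in union if lmap.get(p, False) != rmap.get(p, False)]
    return 1.0 - len(mismatched) / len(union), mismatched


def synchrony_score(
    left: Iterable[LocusObservation],
    right: Iterable[LocusObservation],
) -> float:
    """Fraction of loci (union of observed) with matching left/right activity.

    Activity means replacement evidence (a replacement tooth or crypt); a
    locus observed on one side only is compared against inactivity on the
    other.  Symmetric in its arguments.
    """
    score, _ = synchrony_mismatches(list(left), list(right))
    return score


@dataclass
class PatternReport:
    """Pooled pattern inference across quadrants of an observation set."""

    best_spacing_k: int
    spacing_scores: dict[int, float]
    direction: Direction
    direction_statistic: int
    synchrony: float | None
    n_quadrants: int
    quadrant_scores: dict[tuple, dict[int, float]] = field(default_factory=dict)


def infer_pattern(
    observations: Sequence[LocusObservation],
    candidate_ks: Sequence[int] = (2, 3, 4),
    tooth_class: ToothClass = ToothClass.POSTCANINE,
    min_active: int = 2,
) -> PatternReport:
    """Score wave spacing, direction and synchrony over all quadrants.

    Quadrants (specimen x jaw x side) are scored independently and pooled by
    averaging the spacing match fractions and summing the direction pair
    counts; synchrony averages over specimen-jaws with both sides observed.
    """
    ks = sorted(set(int(k) for k in candidate_ks))
    if any(k < 2 for k in ks):
        raise ValueError("candidate spacings must be at least 2")

    quadrants: dict[tuple, list[LocusObservation]] = defaultdict(list)
    for o in observations:
        if o.tooth_class is tooth_class:
            quadrants[(o.specimen_id, o.jaw, o.side)].append(o)

    per_quadrant: dict[tuple, dict[int, float]] = {}
    statistic = 0
    for key, obs in quadrants.items():
        if sum(o.replacement_active for o in obs) < min_active:
            continue
        per_quadrant[key] = {k: score_spacing(obs, k) for k in ks}
        ordinals = {o.locus_index: development_ordinal(o) for o in obs
                    if development_ordinal(o) is not None}
        if len(ordinals) >= 2:
            statistic += infer_direction(ordinals).statistic
    if not per_quadrant:
        raise ValueError("no quadrant has enough replacement activity to score")

    spacing_scores = {
        k: sum(scores[k] for scores in per_quadrant.values()) / len(per_quadrant)
        for k in ks
    }
    best_k = max(ks, key=lambda k: spacing_scores[k])

    if statistic > 0:
        direction = Direction.BACK_TO_FRONT
    elif statistic < 0:
        direction = Direction.FRONT_TO_BACK
    else:
        direction = Direction.INDETERMINATE

    sync_scores = []
    sides: dict[tuple, dict] = defaultdict(dict)
    for (specimen, jaw, side), obs in quadrants.items():
        sides[(specimen, jaw)][side] = obs
    for pair in sides.values():
        if len(pair) == 2:
            left, right = pair.values()
            try:
                sync_scores.append(synchrony_score(left, right))
            except ValueError:
                continue
    synchrony = sum(sync_scores) / len(sync_scores) if sync_scores else None

    return PatternReport(
        best_spacing_k=best_k,
        spacing_scores=spacing_scores,
        direction=direction,
        direction_statistic=statistic,
        synchrony=synchrony,
        n_quadrants=len(per_quadrant),
        quadrant_scores=per_quadrant,
    )
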