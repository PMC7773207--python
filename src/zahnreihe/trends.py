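"""Count-versus-size trend analysis and replacement-wave arithmetic.

Postcanine tooth counts are regressed against (optionally min-max normalized)
basal skull length to compare the direction of ontogenetic change between
taxa: *Galesaurus* lengthens its postcanine series with size, *Thrinaxodon*
shortens it.  The module also houses the small arithmetic identities of the
wave model: the minimum number of replacement waves separating two counts
(each wave adds one distal locus), the canine-replacement cessation threshold,
and integer size-ratio percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

from .records import (
    DEFAULT_BSL_RANGES,
    BslRange,
    Jaw,
    SpecimenRecord,
    Taxon,
    normalize_bsl,
)

__all__ = [
    "TrendFit",
    "CessationReport",
    "fit_count_trend",
    "min_replacement_waves",
    "canine_cessation_threshold",
    "size_ratio_percent",
]


@dataclass(frozen=True)
class TrendFit:
    """An ordinary-least-squares line through (size, count) points."""

    taxon: Taxon
    jaw: Jaw
    slope: float
    intercept: float
    n: int
    residuals: np.ndarray
    normalized: bool

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def fit_count_trend(
    records: Sequence[SpecimenRecord],
    jaw: Jaw | str,
    normalize: bool = True,
    include_uncertain: bool = True,
    bsl_range: BslRange | None = None,
) -> TrendFit:
    """OLS fit of per-specimen summary count against (normalized) BSL.

    All records must belong to one taxon; when ``normalize`` is set, that
    taxon's own sample span is used for the min-max scaling unless an explicit
    ``bsl_range`` is given.  Uncertain ("?") counts are included at face value
    by default; ``include_uncertain=False`` is the strict mode.
    """
    jaw = Jaw.coerce(jaw)
    taxa = {r.taxon for r in records}
    if len(taxa) != 1:
        raise ValueError(f"records must belong to a single taxon, got {sorted(t.value for t in taxa)}")
    taxon = taxa.pop()

    points = [
        (r.bsl_mm, r.summary_count(jaw, include_uncertain=include_uncertain))
        for r in records
    ]
    points = [(x, y) for x, y in points if y is not None]
    if len(points) < 2:
        raise ValueError(f"need at least 2 usable points, got {len(points)}")

    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if normalize:
        rng = bsl_range or DEFAULT_BSL_RANGES[taxon]
        x = np.array([normalize_bsl(v, rng) for v in x])

    result = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = result.params
    return TrendFit(
        taxon=taxon,
        jaw=jaw,
        slope=float(slope),
        intercept=float(intercept),
        n=len(points),
        residuals=np.asarray(result.resid),
        normalized=normalize,
    )


def min_replacement_waves(count_small: int, count_large: int) -> int:
    """Minimum number of replacement waves linking two series lengths.

    Each wave adds exactly one locus to the distal margin of the series, so
    growing from ``count_small`` to ``count_large`` teeth needs at least their
    difference in waves (7 -> 12 maxillary postcanines implies five waves).
    """
    if count_small < 0:
        raise ValueError("counts are non-negative")
    if count_large < count_small:
        raise ValueError(
            f"count_large ({count_large}) must be >= count_small ({count_small})")
    return count_large - count_small


class CessationReport(NamedTuple):
    """Canine replacement stops between these two skull sizes."""

    threshold_mm: float        # smallest BSL with no replacement evidence
    max_replacement_mm: float  # largest BSL that still shows replacement


def canine_cessation_threshold(
    records: Sequence[SpecimenRecord],
    canine_flags: Mapping[str, bool],
) -> CessationReport:
    """Bracket the size at which canine replacement ceases.

    ``canine_flags`` maps specimen id to True where the specimen shows canine
    replacement evidence; specimens without an annotation are ignored.  With
    the packaged annotations the threshold resolves to 90 mm (the smallest
    adult) and the largest replacement-bearing skull to 88 mm.
    """
    with_evidence = [r.bsl_mm for r in records
                     if canine_flags.get(r.specimen_id) is True]
    without_evidence = [r.bsl_mm for r in records
                        if canine_flags.get(r.specimen_id) is False]
    if not with_evidence or not without_evidence:
        raise ValueError(
            "need at least one specimen with and one without canine-replacement evidence")
    return CessationReport(
        threshold_mm=min(without_evidence),
        max_replacement_mm=max(with_evidence),
    )


def size_ratio_percent(bsl_a: float, bsl_b: float) -> int:
    """round(100 * a / b) with half-up rounding, as an integer percent."""
    if bsl_b <= 0:
        raise ValueError("reference length must be positive")
    ratio = Decimal(100) * Decimal(str(bsl_a)) / Decimal(str(bsl_b))
    return int(ratio.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
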