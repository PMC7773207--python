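"""Specimen tables and per-locus replacement observations.

The central dataset is a table of museum specimens of the Early Triassic
cynodont *Galesaurus planiceps*: one row per skull, with basal skull length
(BSL, the ontogenetic size proxy, in mm), an ontogenetic stage class, and
left/right postcanine tooth counts for maxilla and mandible.  Counts carry the
table's printed conventions: a question mark marks a count that is uncertain
because of damage, and a dash marks a quadrant that is not preserved (or is
locked in occlusion and unobservable).

A second table records per-locus replacement evidence from micro-CT scans:
for a given tooth position in one quadrant of one specimen, whether a
replacement tooth, a crypt, an open or closed root, or a remnant root was
observed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Taxon",
    "Stage",
    "Jaw",
    "Side",
    "ToothClass",
    "CountValue",
    "SpecimenRecord",
    "LocusObservation",
    "BslRange",
    "GALESAURUS_BSL_RANGE",
    "THRINAXODON_BSL_RANGE",
    "OBSERVATION_FLAGS",
    "parse_count",
    "format_count",
    "parse_bsl",
    "format_bsl",
    "load_specimen_table",
    "load_observation_table",
    "load_galesaurus_table",
    "load_galesaurus_observations",
    "load_canine_annotations",
    "load_literature_counts",
    "normalize_bsl",
    "classify_stage",
    "count_range",
    "specimens_to_frame",
]

MISSING_TOKEN = "–"  # en dash as printed; ASCII "-" accepted on read

SPECIMEN_COLUMNS = [
    "specimen_id", "taxon", "bsl_mm", "stage",
    "max_l", "max_r", "mand_l", "mand_r", "source",
]
OBSERVATION_COLUMNS = [
    "specimen_id", "jaw", "side", "tooth_class", "locus_index", "flags",
]

OBSERVATION_FLAGS = frozenset({
    "functional_present", "replacement_present", "crypt_present",
    "root_open", "root_closed", "remnant_root", "empty_alveolus", "resorbing",
})


class Taxon(str, Enum):
    GALESAURUS = "galesaurus"
    THRINAXODON = "thrinaxodon"


class Stage(str, Enum):
    JUVENILE = "juvenile"
    SUBADULT = "subadult"
    ADULT = "adult"


class Jaw(str, Enum):
    UPPER = "upper"
    LOWER = "lower"

    @classmethod
    def coerce(cls, value: "Jaw | str") -> "Jaw":
        if isinstance(value, cls):
            return value
        aliases = {"maxilla": cls.UPPER, "mandible": cls.LOWER,
                   "maxillary": cls.UPPER, "mandibular": cls.LOWER}
        token = str(value).lower()
        if token in aliases:
            return aliases[token]
        return cls(token)


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class ToothClass(str, Enum):
    INCISOR = "incisor"
    CANINE = "canine"
    POSTCANINE = "postcanine"


class CountParseError(ValueError):
    """A count cell did not follow the table's printing conventions."""


@dataclass(frozen=True)
class CountValue:
    """One tooth-count cell: an integer, possibly uncertain or missing."""

    value: int | None = None
    uncertain: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing and self.value is not None:
            raise ValueError("a missing count cannot carry a value")
        if self.value is not None and self.value < 0:
            raise ValueError("counts are non-negative")

    @property
    def present(self) -> bool:
        return self.value is not None


def parse_count(token: str) -> CountValue:
    """Parse a count cell string such as ``"10"``, ``"11?"``, ``"–"`` or ``"?"``.

    ``"N?"`` is an uncertain count of N; a dash means the quadrant is not
    preserved; a bare ``"?"`` means a quadrant is present but its count could
    not be established.
    """
    token = token.strip()
    if token in (MISSING_TOKEN, "-"):
        return CountValue(missing=True)
    if token == "?":
        return CountValue(value=None, uncertain=True)
    match = re.fullmatch(r"(\d+)(\?)?", token)
    if match is None:
        raise CountParseError(f"unrecognized count token: {token!r}")
    return CountValue(value=int(match.group(1)), uncertain=match.group(2) is not None)


def format_count(count: CountValue) -> str:
    """Inverse of :func:`parse_count` (uses the printed en dash for missing)."""
    if count.missing:
        return MISSING_TOKEN
    if count.value is None:
        return "?"
    return f"{count.value}?" if count.uncertain else str(count.value)


def parse_bsl(token: str) -> tuple[float, bool]:
    """Parse a BSL cell; a leading ``~`` marks an approximate measurement."""
    token = str(token).strip()
    approximate = token.startswith("~")
    if approximate:
        token = token[1:]
    try:
        value = float(token)
    except ValueError as exc:
        raise ValueError(f"malformed basal skull length: {token!r}") from exc
    if value <= 0:
        raise ValueError(f"basal skull length must be positive, got {value}")
    return value, approximate


def format_bsl(bsl_mm: float, approximate: bool = False) -> str:
    text = f"{bsl_mm:g}"
    return f"~{text}" if approximate else text


@dataclass(frozen=True)
class BslRange:
    """A basal-skull-length span used for min-max normalization."""

    min_mm: float
    max_mm: float

    def __post_init__(self) -> None:
        if not self.min_mm < self.max_mm:
            raise ValueError(
                f"degenerate BSL range: min {self.min_mm} !< max {self.max_mm}")

    @property
    def span(self) -> float:
        return self.max_mm - self.min_mm

    def contains(self, bsl_mm: float) -> bool:
        return self.min_mm <= bsl_mm <= self.max_mm


#: Sample span of the packaged Galesaurus table (62 mm .. 114 mm).
GALESAURUS_BSL_RANGE = BslRange(62.0, 114.0)
#: Published span of the Thrinaxodon comparator series (~30 mm .. 96 mm).
THRINAXODON_BSL_RANGE = BslRange(30.0, 96.0)

DEFAULT_BSL_RANGES: Mapping[Taxon, BslRange] = {
    Taxon.GALESAURUS: GALESAURUS_BSL_RANGE,
    Taxon.THRINAXODON: THRINAXODON_BSL_RANGE,
}

#: Stage-class boundaries in mm: juvenile below 69, adult at and above 90.
SUBADULT_MIN_BSL_MM = 69.0
ADULT_MIN_BSL_MM = 90.0


@dataclass(frozen=True)
class SpecimenRecord:
    """One museum specimen: size, stage, and four quadrant tooth counts."""

    specimen_id: str
    taxon: Taxon
    bsl_mm: float
    stage: Stage
    maxilla_left: CountValue
    maxilla_right: CountValue
    mandible_left: CountValue
    mandible_right: CountValue
    source: str = ""
    bsl_approximate: bool = False

    def __post_init__(self) -> None:
        if self.bsl_mm <= 0:
            raise ValueError("bsl_mm must be positive")

    def counts(self, jaw: Jaw | str) -> tuple[CountValue, CountValue]:
        jaw = Jaw.coerce(jaw)
        if jaw is Jaw.UPPER:
            return self.maxilla_left, self.maxilla_right
        return self.mandible_left, self.mandible_right

    def summary_count(self, jaw: Jaw | str, include_uncertain: bool = True) -> int | None:
        """Per-specimen count for one jaw: the larger of the two sides.

        Damage can only remove teeth from observation, so when the sides
        disagree the larger present value is the better estimate of the true
        series length.  Returns None when neither side has a usable value.
        """
        values = [c.value for c in self.counts(jaw)
                  if c.present and (include_uncertain or not c.uncertain)]
        return max(values) if values else None


@dataclass(frozen=True)
class LocusObservation:
    """Replacement evidence at one tooth position of one jaw quadrant."""

    specimen_id: str
    jaw: Jaw
    side: Side
    tooth_class: ToothClass
    locus_index: int
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.locus_index < 1:
            raise ValueError("locus_index is 1-based")
        unknown = self.flags - OBSERVATION_FLAGS
        if unknown:
            raise ValueError(f"unknown observation flags: {sorted(unknown)}")
        if {"root_open", "root_closed"} <= self.flags:
            raise ValueError("root_open and root_closed are mutually exclusive")
        if self.tooth_class is ToothClass.CANINE and self.locus_index != 1:
            raise ValueError("the canine occupies a single locus per quadrant")

    @property
    def replacement_active(self) -> bool:
        """Replacement evidence: a replacement tooth or a crypt is present."""
        return bool(self.flags & {"replacement_present", "crypt_present"})


def _specimen_from_row(row: Mapping[str, str]) -> SpecimenRecord:
    bsl, approx = parse_bsl(row["bsl_mm"])
    try:
        stage = Stage(str(row["stage"]).strip().lower())
    except ValueError as exc:
        raise ValueError(
            f"unknown stage token {row['stage']!r} for {row['specimen_id']!r}") from exc
    return SpecimenRecord(
        specimen_id=str(row["specimen_id"]).strip(),
        taxon=Taxon(str(row["taxon"]).strip().lower()),
        bsl_mm=bsl,
        bsl_approximate=approx,
        stage=stage,
        maxilla_left=parse_count(row["max_l"]),
        maxilla_right=parse_count(row["max_r"]),
        mandible_left=parse_count(row["mand_l"]),
        mandible_right=parse_count(row["mand_r"]),
        source=str(row.get("source", "")).strip(),
    )


def load_specimen_table(path) -> list[SpecimenRecord]:
    """Read a specimen CSV into validated records.

    Raises ValueError on duplicate specimen ids, unknown stage tokens, or
    malformed BSL/count cells.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(SPECIMEN_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"specimen table missing columns: {sorted(missing_cols)}")
    dupes = frame["specimen_id"][frame["specimen_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate specimen ids: {sorted(set(dupes))}")
    return [_specimen_from_row(row) for row in frame.to_dict("records")]


def specimens_to_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    """Serialize records back to the CSV schema (round-trips the fixture)."""
    rows = []
    for r in records:
        rows.append({
            "specimen_id": r.specimen_id,
            "taxon": r.taxon.value,
            "bsl_mm": format_bsl(r.bsl_mm, r.bsl_approximate),
            "stage": r.stage.value,
            "max_l": format_count(r.maxilla_left),
            "max_r": format_count(r.maxilla_right),
            "mand_l": format_count(r.mandible_left),
            "mand_r": format_count(r.mandible_right),
            "source": r.source,
        })
    return pd.DataFrame(rows, columns=SPECIMEN_COLUMNS)


def load_observation_table(path) -> list[LocusObservation]:
    """Read a per-locus observation CSV (flags are semicolon-joined tokens)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(OBSERVATION_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"observation table missing columns: {sorted(missing_cols)}")
    observations = []
    for row in frame.to_dict("records"):
        tokens = [t for t in str(row["flags"]).split(";") if t]
        observations.append(LocusObservation(
            specimen_id=str(row["specimen_id"]).strip(),
            jaw=Jaw(str(row["jaw"]).strip().lower()),
            side=Side(str(row["side"]).strip().lower()),
            tooth_class=ToothClass(str(row["tooth_class"]).strip().lower()),
            locus_index=int(row["locus_index"]),
            flags=frozenset(tokens),
        ))
    return observations


def _data_path(name: str):
    return resources.files("zahnreihe.data").joinpath(name)


def load_galesaurus_table() -> list[SpecimenRecord]:
    """The packaged 17-specimen Galesaurus growth series."""
    with resources.as_file(_data_path("galesaurus_specimens.csv")) as p:
        return load_specimen_table(p)


def load_galesaurus_observations() -> list[LocusObservation]:
    """Per-locus replacement evidence transcribed from the scanned skulls."""
    with resources.as_file(_data_path("galesaurus_observations.csv")) as p:
        return load_observation_table(p)


def load_canine_annotations() -> dict[str, bool]:
    """Per-specimen canine-replacement evidence flags (True = replacing)."""
    with resources.as_file(_data_path("canine_annotations.csv")) as p:
        frame = pd.read_csv(p, dtype=str)
    return {row["specimen_id"]: row["replacement_evidence"].strip().lower() == "true"
            for row in frame.to_dict("records")}


def load_literature_counts() -> pd.DataFrame:
    """Supplementary literature-only counts (specimens absent from the table)."""
    with resources.as_file(_data_path("galesaurus_literature.csv")) as p:
        return pd.read_csv(p)


def normalize_bsl(bsl_mm: float, bsl_range: BslRange) -> float:
    """Min-max (unity-based) normalization of a BSL onto [0, 1].

    Values outside the range are allowed (they map outside [0, 1]); callers
    can check ``bsl_range.contains``.
    """
    return (bsl_mm - bsl_range.min_mm) / bsl_range.span


def classify_stage(bsl_mm: float) -> Stage:
    """Ontogenetic stage from skull size: <69 juvenile, <90 subadult, else adult."""
    if bsl_mm <= 0:
        raise ValueError("bsl_mm must be positive")
    if bsl_mm < SUBADULT_MIN_BSL_MM:
        return Stage.JUVENILE
    if bsl_mm < ADULT_MIN_BSL_MM:
        return Stage.SUBADULT
    return Stage.ADULT


def count_range(records: Sequence[SpecimenRecord], jaw: Jaw | str,
                include_uncertain: bool = True) -> tuple[int, int]:
    """(min, max) of all present per-side counts for one jaw."""
    jaw = Jaw.coerce(jaw)
    values = [
        c.value
        for record in records
        for c in record.counts(jaw)
        if c.present and (include_uncertain or not c.uncertain)
    ]
    if not values:
        raise ValueError(f"no usable counts for jaw {jaw.value!r}")
    return min(values), max(values)
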