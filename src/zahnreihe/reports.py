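"""One-shot reproduction of the in-scope published numbers.

Recomputes, from the packaged fixtures and the simulator, the quantities the
study prints — the specimen count, count ranges, wave arithmetic, cycle
dynamics, canine cessation threshold and size ratios — and checks each
against a versioned expectations file.  Acceptance is data, not code: the
expected values live in ``data/expectations.json`` next to the fixtures.
"""

from __future__ import annotations

import json
from importlib import resources

from .model import ModelParams, affected_positions, simulate_ontogeny, steady_cycle_gain
from .records import (
    classify_stage,
    count_range,
    load_canine_annotations,
    load_galesaurus_table,
    load_literature_counts,
)
from .trends import canine_cessation_threshold, min_replacement_waves, size_ratio_percent

__all__ = ["reproduce_report", "load_expectations"]

# Published comparator sizes: the largest Thrinaxodon still replacing its
# canines (87 mm) against the largest in that sample (96 mm).
THRINAXODON_LARGEST_REPLACING_MM = 87.0
THRINAXODON_LARGEST_MM = 96.0


def load_expectations() -> dict:
    path = resources.files("zahnreihe.data").joinpath("expectations.json")
    return json.loads(path.read_text())


def reproduce_report() -> dict:
    """Recompute every expected quantity; returns entries with pass/fail."""
    expectations = load_expectations()
    records = load_galesaurus_table()
    flags = load_canine_annotations()

    computed: dict[str, object] = {}
    computed["specimen_count"] = len(records)
    computed["stage_classification_mismatches"] = sum(
        1 for r in records if classify_stage(r.bsl_mm) is not r.stage)
    computed["maxillary_count_range"] = list(count_range(records, "maxilla"))
    computed["mandibular_count_range"] = list(count_range(records, "mandible"))

    smallest_maxillary = count_range(records, "maxilla")[0]
    largest_maxillary = int(load_literature_counts()["max_count"].max())
    computed["min_replacement_waves"] = min_replacement_waves(
        smallest_maxillary, largest_maxillary)

    computed["net_gain_per_cycle"] = steady_cycle_gain()
    computed["adult_net_gain_per_cycle"] = steady_cycle_gain(adult=True)
    computed["triplet_wave_loci"] = sorted(affected_positions(8, k=3, offset=1))

    cessation = canine_cessation_threshold(records, flags)
    computed["canine_cessation_threshold_mm"] = cessation.threshold_mm
    computed["max_replacement_bsl_mm"] = cessation.max_replacement_mm

    largest = max(r.bsl_mm for r in records)
    computed["size_ratio_subadult_pct"] = size_ratio_percent(
        cessation.max_replacement_mm, largest)
    computed["size_ratio_thrinaxodon_pct"] = size_ratio_percent(
        THRINAXODON_LARGEST_REPLACING_MM, THRINAXODON_LARGEST_MM)

    computed["stage8_maxillary_count"] = simulate_ontogeny(
        ModelParams()).functional_at(8)

    entries = {}
    for key, spec in expectations.items():
        value = computed[key]
        entries[key] = {
            "value": value,
            "expected": spec["expected"],
            "passed": value == spec["expected"],
            "source": spec["source"],
        }
    return {"entries": entries, "all_passed": all(e["passed"] for e in entries.values())}
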