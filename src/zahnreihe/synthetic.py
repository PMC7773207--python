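"""Synthetic ontogenetic series with the statistical structure of the data.

The generator emulates what a museum growth series looks like downstream of
the wave model: specimens sampled along a monotone stage->size map with
Gaussian measurement noise, per-quadrant tooth counts read off the simulator
(or, for the *Thrinaxodon*-like comparator, off its published count rules),
and the table's observation pathologies — unpreserved quadrants ("–"),
damage-reduced uncertain counts ("?"), and unobservable loci.  Every run also
returns the generating ground truth, so the inference layer can be tested by
parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import records as rec
from .inference import Direction, infer_pattern
from .model import ModelParams, linear_stage_to_bsl, simulate_ontogeny
from .records import CountValue, LocusObservation, classify_stage, format_count
from .trends import canine_cessation_threshold, fit_count_trend

__all__ = [
    "GeneratorConfig",
    "SyntheticSeries",
    "generate_series",
    "corrupt_counts",
    "recovery_experiment",
]

#: Mandibular rows carry roughly two more postcanines than maxillary ones;
#: realized as a longer initial lattice for the lower quadrant.
MANDIBLE_EXTRA_LOCI = 2

#: Thrinaxodon-grade count rules: series shortens across the juvenile/adult
#: transition (7 -> 6 maxillary; 8 -> 7-8 mandibular), switching near 56 mm.
THRINAXODON_COUNT_SWITCH_MM = 56.0
THRINAXODON_JUVENILE_MAX_MM = 42.0
THRINAXODON_SUBADULT_MAX_MM = 68.0


class GeneratorConfig(BaseModel):
    """Configuration of one synthetic growth series."""

    model_config = {"frozen": True}

    taxon_template: Literal["galesaurus_like", "thrinaxodon_like"] = "galesaurus_like"
    n_specimens: int = Field(default=17, ge=1)
    bsl_min_mm: float | None = None
    bsl_max_mm: float | None = None
    stage_noise_sd_mm: float = Field(default=2.0, ge=0)
    p_missing_quadrant: float = Field(default=0.2, ge=0, le=1)
    p_uncertain_count: float = Field(default=0.15, ge=0, le=1)
    p_unobserved_locus: float = Field(default=0.0, ge=0, le=1)
    model: ModelParams = Field(default_factory=ModelParams)
    n_stages: int = Field(default=13, ge=2)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _fill_range(self) -> "GeneratorConfig":
        default = (rec.GALESAURUS_BSL_RANGE
                   if self.taxon_template == "galesaurus_like"
                   else rec.THRINAXODON_BSL_RANGE)
        if self.bsl_min_mm is None:
            object.__setattr__(self, "bsl_min_mm", default.min_mm)
        if self.bsl_max_mm is None:
            object.__setattr__(self, "bsl_max_mm", default.max_mm)
        if not self.bsl_min_mm < self.bsl_max_mm:
            raise ValueError("bsl_min_mm must be below bsl_max_mm")
        return self

    @property
    def bsl_range(self) -> rec.BslRange:
        return rec.BslRange(self.bsl_min_mm, self.bsl_max_mm)


@dataclass
class SyntheticSeries:
    """One generated series: tables in the packaged CSV schemas plus truth."""

    specimens: pd.DataFrame
    observations: pd.DataFrame
    truth: dict

    def specimen_records(self) -> list[rec.SpecimenRecord]:
        return [rec._specimen_from_row(row) for row in self.specimens.to_dict("records")]

    def observation_records(self) -> list[LocusObservation]:
        out = []
        for row in self.observations.to_dict("records"):
            tokens = [t for t in str(row["flags"]).split(";") if t]
            out.append(LocusObservation(
                specimen_id=row["specimen_id"],
                jaw=rec.Jaw(row["jaw"]),
                side=rec.Side(row["side"]),
                tooth_class=rec.ToothClass(row["tooth_class"]),
                locus_index=int(row["locus_index"]),
                flags=frozenset(tokens),
            ))
        return out

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "specimens": out_dir / "specimens.csv",
            "observations": out_dir / "observations.csv",
            "truth": out_dir / "truth.json",
        }
        self.specimens.to_csv(paths["specimens"], index=False)
        self.observations.to_csv(paths["observations"], index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return paths


def corrupt_counts(
    true_counts: Sequence[int],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    uncertain_perturbation: int | None = None,
) -> list[CountValue]:
    """Apply the table's observation pathologies to true counts.

    Each cell independently becomes "–" with ``p_missing_quadrant``;
    otherwise, with ``p_uncertain_count`` it is reduced by 0 or 1 (equal
    odds — damage removes teeth from observation, never adds them) and
    flagged "?".  ``uncertain_perturbation`` pins the reduction for testing.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cells = []
    for value in true_counts:
        if rng.random() < config.p_missing_quadrant:
            cells.append(CountValue(missing=True))
            continue
        if rng.random() < config.p_uncertain_count:
            perturb = (uncertain_perturbation if uncertain_perturbation is not None
                       else int(rng.integers(0, 2)))
            cells.append(CountValue(value=max(0, int(value) - perturb), uncertain=True))
        else:
            cells.append(CountValue(value=int(value)))
    return cells


_ORDINAL_FLAGS = {
    1: "crypt_present",
    2: "functional_present;replacement_present",
    3: "functional_present;replacement_present;resorbing",
}


def _snapshot_rows(specimen_id: str, jaw: str, snapshot: list[dict],
                   rng: np.random.Generator, p_drop: float) -> list[dict]:
    rows = []
    for side in ("left", "right"):
        for item in snapshot:
            if p_drop and rng.random() < p_drop:
                continue
            rows.append({
                "specimen_id": specimen_id,
                "jaw": jaw,
                "side": side,
                "tooth_class": "postcanine",
                "locus_index": int(item["position"]),
                "flags": _ORDINAL_FLAGS[int(item["ordinal"])],
            })
    return rows


def _canine_rows(specimen_id: str, bsl: float, replacing: bool) -> list[dict]:
    flags = ("functional_present;replacement_present;root_closed" if replacing
             else "functional_present;root_open")
    return [
        {"specimen_id": specimen_id, "jaw": jaw, "side": side,
         "tooth_class": "canine", "locus_index": 1, "flags": flags}
        for jaw in ("upper", "lower") for side in ("left", "right")
    ]


def _generate_galesaurus_like(config: GeneratorConfig) -> SyntheticSeries:
    rng = np.random.default_rng(config.seed)
    stage_lo, stage_hi = 8, config.n_stages
    stage_map = linear_stage_to_bsl((stage_lo, config.bsl_min_mm),
                                    (stage_hi, config.bsl_max_mm))
    stages = np.round(np.linspace(stage_lo, stage_hi, config.n_specimens)).astype(int)

    upper = simulate_ontogeny(config.model, n_stages=config.n_stages,
                              stage_to_bsl=stage_map, jaw="upper",
                              capture_snapshots=True)
    lower_params = config.model.model_copy(update={
        "initial_locus_count": config.model.initial_locus_count + MANDIBLE_EXTRA_LOCI})
    lower = simulate_ontogeny(lower_params, n_stages=config.n_stages,
                              stage_to_bsl=stage_map, jaw="lower",
                              capture_snapshots=True)

    spec_rows, obs_rows = [], []
    true_counts = {"maxilla": [], "mandible": []}
    bsls = []
    for i, stage in enumerate(stages):
        specimen_id = f"SYN-GAL-{i + 1:02d}"
        bsl = float(np.clip(stage_map(int(stage))
                            + rng.normal(0.0, config.stage_noise_sd_mm),
                            config.bsl_min_mm, config.bsl_max_mm))
        bsls.append(bsl)
        max_count = upper.functional_at(int(stage))
        mand_count = lower.functional_at(int(stage))
        true_counts["maxilla"].append(int(max_count))
        true_counts["mandible"].append(int(mand_count))
        cells = corrupt_counts([max_count, max_count, mand_count, mand_count],
                               config, rng=rng)
        spec_rows.append({
            "specimen_id": specimen_id,
            "taxon": "galesaurus",
            "bsl_mm": f"{bsl:.1f}",
            "stage": classify_stage(bsl).value,
            "max_l": format_count(cells[0]),
            "max_r": format_count(cells[1]),
            "mand_l": format_count(cells[2]),
            "mand_r": format_count(cells[3]),
            "source": "synthetic",
        })
        obs_rows.extend(_snapshot_rows(specimen_id, "upper",
                                       upper.snapshots.get(int(stage), []),
                                       rng, config.p_unobserved_locus))
        obs_rows.extend(_snapshot_rows(specimen_id, "lower",
                                       lower.snapshots.get(int(stage), []),
                                       rng, config.p_unobserved_locus))
        obs_rows.extend(_canine_rows(
            specimen_id, bsl, replacing=bsl < config.model.canine_cessation_bsl_mm))

    truth = {
        "template": "galesaurus_like",
        "taxon": "galesaurus",
        "wave_spacing_k": config.model.wave_spacing_k,
        "wave_direction": config.model.wave_direction,
        "canine_cessation_bsl_mm": config.model.canine_cessation_bsl_mm,
        "count_trend": "increasing",
        "stages": [int(s) for s in stages],
        "bsl_mm": [round(b, 3) for b in bsls],
        "true_counts": true_counts,
        "model_params": json.loads(config.model.model_dump_json()),
        "seed": config.seed,
    }
    return SyntheticSeries(
        specimens=pd.DataFrame(spec_rows, columns=rec.SPECIMEN_COLUMNS),
        observations=pd.DataFrame(obs_rows, columns=rec.OBSERVATION_COLUMNS),
        truth=truth,
    )


def _thrinaxodon_stage(bsl: float) -> str:
    if bsl <= THRINAXODON_JUVENILE_MAX_MM:
        return "juvenile"
    if bsl <= THRINAXODON_SUBADULT_MAX_MM:
        return "subadult"
    return "adult"


def _generate_thrinaxodon_like(config: GeneratorConfig) -> SyntheticSeries:
    """Rule-based comparator series: the postcanine row shortens with size.

    Counts follow the published adult stabilization (6 maxillary, 7-8
    mandibular) with juveniles one tooth longer; replacement observations
    alternate every second locus (wave spacing 2), most developed distally.
    """
    rng = np.random.default_rng(config.seed)
    base = np.linspace(config.bsl_min_mm, config.bsl_max_mm, config.n_specimens)
    spec_rows, obs_rows = [], []
    true_counts = {"maxilla": [], "mandible": []}
    bsls = []
    for i, b in enumerate(base):
        specimen_id = f"SYN-THR-{i + 1:02d}"
        bsl = float(np.clip(b + rng.normal(0.0, config.stage_noise_sd_mm),
                            config.bsl_min_mm, config.bsl_max_mm))
        bsls.append(bsl)
        if bsl < THRINAXODON_COUNT_SWITCH_MM:
            max_count, mand_count = 7, 8
        else:
            max_count, mand_count = 6, 7 + int(rng.integers(0, 2))
        true_counts["maxilla"].append(max_count)
        true_counts["mandible"].append(mand_count)
        cells = corrupt_counts([max_count, max_count, mand_count, mand_count],
                               config, rng=rng)
        spec_rows.append({
            "specimen_id": specimen_id,
            "taxon": "thrinaxodon",
            "bsl_mm": f"{bsl:.1f}",
            "stage": _thrinaxodon_stage(bsl),
            "max_l": format_count(cells[0]),
            "max_r": format_count(cells[1]),
            "mand_l": format_count(cells[2]),
            "mand_r": format_count(cells[3]),
            "source": "synthetic",
        })
        # one alternating wave per quadrant: every 2nd locus, distal most advanced
        for jaw, count in (("upper", max_count), ("lower", mand_count)):
            offset = 1 + (i % 2)
            active = [p for p in range(1, count + 1) if p % 2 == offset % 2][-3:]
            for side in ("left", "right"):
                for ordinal, pos in enumerate(sorted(active), start=1):
                    if config.p_unobserved_locus and rng.random() < config.p_unobserved_locus:
                        continue
                    obs_rows.append({
                        "specimen_id": specimen_id, "jaw": jaw, "side": side,
                        "tooth_class": "postcanine", "locus_index": pos,
                        "flags": _ORDINAL_FLAGS[min(ordinal, 3)],
                    })
        obs_rows.extend(_canine_rows(specimen_id, bsl, replacing=True))

    truth = {
        "template": "thrinaxodon_like",
        "taxon": "thrinaxodon",
        "wave_spacing_k": 2,
        "wave_direction": "back_to_front",
        "canine_cessation_bsl_mm": None,
        "count_trend": "decreasing",
        "bsl_mm": [round(b, 3) for b in bsls],
        "true_counts": true_counts,
        "seed": config.seed,
    }
    return SyntheticSeries(
        specimens=pd.DataFrame(spec_rows, columns=rec.SPECIMEN_COLUMNS),
        observations=pd.DataFrame(obs_rows, columns=rec.OBSERVATION_COLUMNS),
        truth=truth,
    )


def generate_series(config: GeneratorConfig | None = None) -> SyntheticSeries:
    """Generate one synthetic growth series (deterministic for a fixed seed)."""
    config = config or GeneratorConfig()
    if config.taxon_template == "galesaurus_like":
        return _generate_galesaurus_like(config)
    return _generate_thrinaxodon_like(config)


def recovery_experiment(config: GeneratorConfig, n_replicates: int = 20) -> dict:
    """Generate-and-recover: how often inference finds the generating pattern.

    For each replicate (fresh seed derived from the config seed) the series
    is generated, the inference and trend layers are run on the noisy tables,
    and the results are compared with the generating truth.  Reports recovery
    rates for wave spacing, wave direction, canine cessation threshold
    (bracketed by the adjacent specimen sizes), and trend-slope sign.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    hits = {"spacing": 0, "direction": 0, "cessation": 0, "trend_sign": 0}
    cessation_applicable = 0
    for i in range(n_replicates):
        cfg = config.model_copy(update={"seed": (config.seed + 7919 * i) % (2 ** 31)})
        series = generate_series(cfg)
        truth = series.truth

        report = infer_pattern(series.observation_records(), candidate_ks=(2, 3, 4))
        if report.best_spacing_k == truth["wave_spacing_k"]:
            hits["spacing"] += 1
        if report.direction == Direction(truth["wave_direction"]):
            hits["direction"] += 1

        specimens = series.specimen_records()
        canine_flags: dict[str, bool] = {}
        for o in series.observation_records():
            if o.tooth_class is rec.ToothClass.CANINE:
                canine_flags[o.specimen_id] = (canine_flags.get(o.specimen_id, False)
                                               or o.replacement_active)
        if truth.get("canine_cessation_bsl_mm") is not None:
            cessation_applicable += 1
            try:
                est = canine_cessation_threshold(specimens, canine_flags)
                if est.max_replacement_mm < truth["canine_cessation_bsl_mm"] <= est.threshold_mm:
                    hits["cessation"] += 1
            except ValueError:
                pass  # all specimens on one side of the threshold: no bracket

        fit = fit_count_trend(specimens, "maxilla", normalize=True,
                              bsl_range=cfg.bsl_range)
        want_positive = truth["count_trend"] == "increasing"
        if (fit.slope > 0) == want_positive and fit.slope != 0:
            hits["trend_sign"] += 1

    rates = {key: hits[key] / n_replicates for key in ("spacing", "direction", "trend_sign")}
    rates["cessation"] = (hits["cessation"] / cessation_applicable
                          if cessation_applicable else None)
    return {"n_replicates": n_replicates, "rates": rates, "hits": hits}
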