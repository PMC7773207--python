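{
  "specimen_count": {
    "expected": 17,
    "source": "museum specimen table (prepared Galesaurus planiceps sample)"
  },
  "stage_classification_mismatches": {
    "expected": 0,
    "source": "ontogenetic stage column of the specimen table vs. BSL thresholds"
  },
  "maxillary_count_range": {
    "expected": [7, 11],
    "source": "specimen table, maxillary postcanine counts"
  },
  "mandibular_count_range": {
    "expected": [9, 15],
    "source": "specimen table, mandibular postcanine counts"
  },
  "min_replacement_waves": {
    "expected": 5,
    "source": "wave-count arithmetic: smallest (7) to largest (12) maxillary count"
  },
  "net_gain_per_cycle": {
    "expected": 2,
    "source": "+3:-1 replacement triplet (one distal locus per wave, one mesial locus per cycle)"
  },
  "adult_net_gain_per_cycle": {
    "expected": 1,
    "source": "+2:-1 adult regime"
  },
  "triplet_wave_loci": {
    "expected": [1, 4, 7],
    "source": "every-third-locus wave at offset 1 on an 8-locus lattice"
  },
  "canine_cessation_threshold_mm": {
    "expected": 90,
    "source": "smallest specimen with no canine-replacement evidence"
  },
  "max_replacement_bsl_mm": {
    "expected": 88,
    "source": "largest specimen with canine-replacement evidence"
  },
  "size_ratio_subadult_pct": {
    "expected": 77,
    "source": "88 mm largest replacing specimen vs 114 mm largest specimen"
  },
  "size_ratio_thrinaxodon_pct": {
    "expected": 91,
    "source": "87 mm largest replacing Thrinaxodon vs 96 mm largest in that sample"
  },
  "stage8_maxillary_count": {
    "expected": 7,
    "source": "simulator calibration anchor: stage 8 matches the smallest specimen (7 maxillary postcanines)"
  }
}
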