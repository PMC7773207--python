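"""Replacement-wave simulator: lattice dynamics, canine and incisor rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from conftest import random_model_params
from tests_support_legal import LEGAL_TRANSITIONS
from zahnreihe.model import (
    ModelParams,
    advance_stage,
    affected_positions,
    canine_update,
    incisor_activity,
    initialize,
    initiate_wave,
    simulate_ontogeny,
    steady_cycle_gain,
)

class TestInitialize:
    def test_initial_state_contract(self):
        params = ModelParams()
        state = initialize(params)
        assert state.active_locus_count == params.initial_locus_count
        assert state.functional_count == params.initial_locus_count - 2
        assert state.canine.root == "closed"
        assert state.canine.generation == 1

    def test_zero_initial_loci_rejected(self):
        with pytest.raises(ValidationError):
            ModelParams(initial_locus_count=0)

    def test_stage_eight_matches_smallest_specimen(self):
        # calibration anchor: 7 functional maxillary postcanines at stage 8
        assert simulate_ontogeny(ModelParams()).functional_at(8) == 7


class TestWaveGeometry:
    def test_every_third_locus_from_offset_one(self):
        assert affected_positions(8, k=3, offset=1) == {1, 4, 7}

    def test_every_second_locus_from_offset_zero(self):
        assert affected_positions(6, k=2, offset=0) == {2, 4, 6}

    @given(st.integers(2, 6), st.integers(4, 20))
    def test_k_consecutive_waves_cover_each_locus_exactly_once(self, k, n):
        cover = [affected_positions(n, k, offset) for offset in range(1, k + 1)]
        counts = {p: sum(p in s for s in cover) for p in range(1, n + 1)}
        assert set(counts.values()) == {1}

    def test_wave_offsets_cycle_with_ordinal(self):
        state = initialize(ModelParams(initial_locus_count=8))
        offsets = [initiate_wave(state).offset for _ in range(6)]
        assert offsets == [1, 2, 3, 1, 2, 3]


class TestCycleDynamics:
    def test_subadult_triplet_gains_two_per_cycle(self):
        assert steady_cycle_gain(n_cycles=5) == 2

    def test_adult_regime_gains_one_per_cycle(self):
        assert steady_cycle_gain(n_cycles=5, adult=True) == 1

    def test_single_wave_adds_one_active_locus(self):
        params = ModelParams()
        state = initialize(params)
        before = state.active_locus_count
        row = advance_stage(state, bsl_mm=70.0)  # first wave, no cycle boundary
        assert row["wave_initiated"] == 1
        assert row["retired"] == 0
        assert state.active_locus_count - before == 1

    def test_locus_count_conservation(self):
        traj = simulate_ontogeny(ModelParams(), n_stages=20, stage_to_bsl=75.0)
        rows = traj.rows
        for prev, row in zip(rows, rows[1:]):
            assert (row["active_loci"] - prev["active_loci"]
                    == row["added"] - row["retired"])

    def test_retired_cause_annotated(self):
        traj = simulate_ontogeny(ModelParams(), n_stages=10, stage_to_bsl=75.0)
        state = traj.final_state
        retired = [l for l in state.loci.values() if l.retired]
        assert retired and all(l.retire_cause == "canine_alveolus_invasion"
                               for l in retired)


class TestRandomizedRuns:
    def test_lifecycle_legality_and_conservation(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            params = random_model_params(rng)
            traj = simulate_ontogeny(params, n_stages=15,
                                     stage_to_bsl=lambda s: 60.0 + 4.0 * s)
            for prev, row in zip(traj.rows, traj.rows[1:]):
                assert (row["active_loci"] - prev["active_loci"]
                        == row["added"] - row["retired"])
            for _, _, track, old, new in traj.final_state.log:
                if track == "locus":
                    assert new == "retired"
                else:
                    assert (track, old, new) in LEGAL_TRANSITIONS

    def test_retirement_is_absorbing(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            traj = simulate_ontogeny(random_model_params(rng), n_stages=18,
                                     stage_to_bsl=70.0)
            log = traj.final_state.log
            retired_at = {}
            for stage, locus, track, _, new in log:
                if track == "locus" and new == "retired":
                    retired_at[locus] = stage
            for stage, locus, track, _, _ in log:
                if locus in retired_at and track != "locus":
                    assert stage <= retired_at[locus]


class TestDeterminismAndDirection:
    def test_identical_runs_identical_trajectories(self):
        a = simulate_ontogeny(ModelParams(), n_stages=13)
        b = simulate_ontogeny(ModelParams(), n_stages=13)
        assert a.rows == b.rows

    def test_direction_flip_leaves_counts_unchanged(self):
        fwd = simulate_ontogeny(ModelParams(wave_direction="back_to_front"), n_stages=13)
        rev = simulate_ontogeny(ModelParams(wave_direction="front_to_back"), n_stages=13)
        for ra, rb in zip(fwd.rows, rev.rows):
            assert ra["functional_pc"] == rb["functional_pc"]
            assert ra["active_loci"] == rb["active_loci"]

    def test_direction_flip_mirrors_within_wave_ordering(self):
        fwd = simulate_ontogeny(ModelParams(wave_direction="back_to_front"),
                                n_stages=10, stage_to_bsl=75.0,
                                capture_snapshots=True)
        rev = simulate_ontogeny(ModelParams(wave_direction="front_to_back"),
                                n_stages=10, stage_to_bsl=75.0,
                                capture_snapshots=True)
        sf = {o["position"]: o["ordinal"] for o in fwd.snapshots[9]}
        sr = {o["position"]: o["ordinal"] for o in rev.snapshots[9]}
        assert len(sf) >= 2 and len(sr) >= 2
        # distal-most is most advanced under back-to-front, least under the mirror
        assert sf[max(sf)] == max(sf.values())
        assert sr[max(sr)] == min(sr.values())


class TestSimulateOntogeny:
    def test_single_stage_trajectory(self):
        traj = simulate_ontogeny(ModelParams(), n_stages=1)
        assert len(traj.rows) == 1
        assert traj.rows[0]["functional_pc"] == 2

    def test_final_count_within_published_sample_range(self):
        traj = simulate_ontogeny(ModelParams(), n_stages=13)
        assert 7 <= traj.rows[-1]["functional_pc"] <= 12

    def test_non_monotone_bsl_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            simulate_ontogeny(ModelParams(), n_stages=3, stage_to_bsl=[70, 80, 75])

    def test_mandibular_row_runs_two_ahead(self):
        upper = simulate_ontogeny(ModelParams(initial_locus_count=4))
        lower = simulate_ontogeny(ModelParams(initial_locus_count=6))
        assert lower.functional_at(8) == upper.functional_at(8) + 2 == 9


class TestCanineRule:
    def test_below_threshold_keeps_replacing_with_closed_roots(self):
        state = initialize(ModelParams())
        canine_update(state, 88.0)
        assert state.canine.replacement_active and state.canine.root == "closed"

    def test_at_and_above_threshold_stops_with_open_root(self):
        state = initialize(ModelParams())
        canine_update(state, 94.0)
        assert not state.canine.replacement_active and state.canine.root == "open"

    def test_single_step_transition_across_growth_series(self):
        traj = simulate_ontogeny(ModelParams(), n_stages=13)
        replacing = [row["canine_replacing"] for row in traj.rows]
        flips = sum(a != b for a, b in zip(replacing, replacing[1:]))
        assert flips == 1 and replacing[0] and not replacing[-1]
        roots = [row["canine_root"] for row in traj.rows]
        assert roots[-1] == "open"

    def test_generation_count_depends_only_on_crossing_stage(self):
        slow = simulate_ontogeny(ModelParams(), n_stages=13,
                                 stage_to_bsl=lambda s: 50 + 4 * s)
        fast = simulate_ontogeny(ModelParams(), n_stages=13,
                                 stage_to_bsl=lambda s: 58 + 3.2 * s)
        # both cross 90 mm between stages 10 and 11
        assert slow.rows[-1]["canine_generation"] == fast.rows[-1]["canine_generation"]


class TestIncisorRule:
    def test_upper_even_wave_activates_loci_two_and_four(self):
        state = initialize(ModelParams())
        active = incisor_activity(state, parity="even")
        assert set(active) == {2, 4}
        assert active[4] > active[2]  # distal member more advanced

    def test_lower_even_wave_activates_locus_two_only(self):
        state = initialize(ModelParams(), jaw="lower")
        assert set(incisor_activity(state, parity="even")) == {2}

    def test_odd_wave_is_antiphase(self):
        state = initialize(ModelParams())
        assert set(incisor_activity(state, parity="odd")) == {1, 3}

    def test_front_to_back_mirrors_development_order(self):
        state = initialize(ModelParams(wave_direction="front_to_back"))
        active = incisor_activity(state, parity="even")
        assert active[2] > active[4]


def test_adult_regime_cannot_outpace_subadult():
    with pytest.raises(ValidationError):
        ModelParams(waves_per_cycle=2, adult_waves_per_cycle=3)
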