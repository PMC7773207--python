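"""Pattern inference: wave spacing, direction and left/right synchrony."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zahnreihe.inference import (
    Direction,
    development_ordinal,
    infer_direction,
    infer_pattern,
    score_spacing,
    synchrony_mismatches,
    synchrony_score,
)
from zahnreihe.model import ModelParams, simulate_ontogeny
from zahnreihe.records import Jaw, LocusObservation, Side, ToothClass


def obs(specimen, locus, flags, jaw=Jaw.UPPER, side=Side.LEFT):
    return LocusObservation(specimen_id=specimen, jaw=jaw, side=side,
                            tooth_class=ToothClass.POSTCANINE,
                            locus_index=locus, flags=frozenset(flags))


class TestScoreSpacing:
    def test_every_third_pattern_is_perfect_at_three(self):
        assert score_spacing([1, 4, 7], k=3) == 1.0

    def test_every_third_pattern_is_partial_at_two(self):
        assert score_spacing([1, 4, 7], k=2) == pytest.approx(2 / 3)

    @given(st.integers(2, 6), st.integers(0, 5), st.integers(2, 6))
    def test_single_residue_class_scores_one_at_its_period(self, k, start, n):
        positions = [start + 1 + i * k for i in range(n)]
        assert score_spacing(positions, k=k) == 1.0

    def test_observation_flags_define_activity(self):
        quadrant = [
            obs("X", 1, {"crypt_present"}),
            obs("X", 2, {"functional_present"}),
            obs("X", 4, {"functional_present", "replacement_present"}),
            obs("X", 7, {"functional_present", "replacement_present", "resorbing"}),
        ]
        assert score_spacing(quadrant, k=3) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            score_spacing([1, 4, 7], k=1)
        with pytest.raises(ValueError):
            score_spacing([1], k=3)


class TestInferDirection:
    def test_distally_increasing_development_is_back_to_front(self):
        result = infer_direction({1: 1, 4: 2, 7: 3})
        assert result.direction is Direction.BACK_TO_FRONT
        assert result.statistic == 3

    def test_reversed_gradient_is_front_to_back(self):
        assert infer_direction({1: 3, 4: 2, 7: 1}).direction is Direction.FRONT_TO_BACK

    def test_flat_gradient_is_indeterminate(self):
        assert infer_direction({1: 2, 4: 2, 7: 2}).direction is Direction.INDETERMINATE

    def test_floor_suppresses_weak_gradients(self):
        result = infer_direction({1: 1, 4: 2}, floor=1)
        assert result.direction is Direction.INDETERMINATE

    def test_ordinals_from_flags(self):
        assert development_ordinal(obs("X", 1, {"crypt_present"})) == 1
        assert development_ordinal(
            obs("X", 4, {"replacement_present", "functional_present"})) == 2
        assert development_ordinal(
            obs("X", 7, {"replacement_present", "resorbing"})) == 3
        assert development_ordinal(obs("X", 2, {"functional_present"})) is None

    @given(st.dictionaries(st.integers(1, 12), st.integers(1, 3),
                           min_size=3, max_size=8))
    def test_sign_agrees_with_scipy_kendall(self, ordinals):
        """The exact pair-count statistic matches Kendall's tau in sign."""
        from scipy.stats import kendalltau
        loci = sorted(ordinals)
        tau = kendalltau(loci, [ordinals[l] for l in loci]).statistic
        statistic = infer_direction(ordinals).statistic
        if np.isnan(tau) or tau == 0:
            assert statistic == 0
        else:
            assert np.sign(statistic) == np.sign(tau)

    def test_bp_4602_mandible_reads_back_to_front(self, galesaurus_observations):
        quadrant = [o for o in galesaurus_observations
                    if o.specimen_id == "BP/1/4602" and o.jaw is Jaw.LOWER
                    and o.side is Side.LEFT and o.tooth_class is ToothClass.POSTCANINE]
        assert score_spacing(quadrant, k=3) == 1.0
        assert infer_direction(quadrant).direction is Direction.BACK_TO_FRONT


class TestSynchrony:
    def test_identical_sides_score_one(self):
        side = [obs("X", 2, {"replacement_present"}), obs("X", 5, {"functional_present"})]
        assert synchrony_score(side, side) == 1.0

    def test_sam_pk_k10468_maxillae(self, galesaurus_observations):
        left = [o for o in galesaurus_observations
                if o.specimen_id == "SAM-PK-K10468" and o.jaw is Jaw.UPPER
                and o.side is Side.LEFT and o.tooth_class is ToothClass.POSTCANINE]
        right = [o for o in galesaurus_observations
                 if o.specimen_id == "SAM-PK-K10468" and o.jaw is Jaw.UPPER
                 and o.side is Side.RIGHT and o.tooth_class is ToothClass.POSTCANINE]
        score, mismatched = synchrony_mismatches(left, right)
        assert score < 1.0
        assert [p for p in mismatched if p <= 9] == [8]

    def test_symmetry(self, galesaurus_observations):
        left = [o for o in galesaurus_observations if o.side is Side.LEFT]
        right = [o for o in galesaurus_observations if o.side is Side.RIGHT]
        assert synchrony_score(left, right) == synchrony_score(right, left)

    def test_phase_offset_lowers_synchrony(self):
        def side_obs(first_wave_stage, side):
            traj = simulate_ontogeny(ModelParams(first_wave_stage=first_wave_stage),
                                     n_stages=10, stage_to_bsl=75.0,
                                     capture_snapshots=True)
            return [obs("S", o["position"],
                        {"crypt_present"} if o["ordinal"] == 1 else {"replacement_present"},
                        side=side)
                    for o in traj.snapshots[9]]

        left = side_obs(2, Side.LEFT)
        in_phase = side_obs(2, Side.RIGHT)
        offset = side_obs(3, Side.RIGHT)
        assert synchrony_score(left, offset) < synchrony_score(left, in_phase) == 1.0


class TestSimulatorRecovery:
    def test_noise_free_spacing_recovery(self):
        traj = simulate_ontogeny(ModelParams(), n_stages=12, stage_to_bsl=75.0,
                                 capture_snapshots=True)
        snapshot = traj.snapshots[12]
        positions = [o["position"] for o in snapshot]
        assert len(positions) >= 3
        assert score_spacing(positions, k=3) == 1.0
        assert score_spacing(positions, k=3) > score_spacing(positions, k=2)

    @pytest.mark.parametrize("direction", ["back_to_front", "front_to_back"])
    def test_direction_recovery(self, direction):
        traj = simulate_ontogeny(ModelParams(wave_direction=direction),
                                 n_stages=12, stage_to_bsl=75.0,
                                 capture_snapshots=True)
        ordinals = {o["position"]: o["ordinal"] for o in traj.snapshots[12]}
        assert infer_direction(ordinals).direction is Direction(direction)


class TestInferPattern:
    def test_fixture_pool_prefers_spacing_three(self, galesaurus_observations):
        report = infer_pattern(galesaurus_observations, candidate_ks=(2, 3, 4))
        assert report.best_spacing_k == 3
        assert report.direction is Direction.BACK_TO_FRONT
        assert 0.0 <= report.synchrony <= 1.0
        assert all(0.0 <= v <= 1.0 for v in report.spacing_scores.values())

    def test_rejects_bad_candidates(self, galesaurus_observations):
        with pytest.raises(ValueError):
            infer_pattern(galesaurus_observations, candidate_ks=(1, 2))
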