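import numpy as np
import pytest

from ivote import (
    GradientField,
    ImageGrid,
    cast_votes,
    collect_votes_oracle,
    iterative_vote,
    make_schedule,
    update_directions,
)
from tests.conftest import random_gradient_field

UNIT2 = (1.0, 1.0)


def single_voter_field(shape, pos, direction, magnitude=1.0, spacing=None):
    ndim = len(shape)
    spacing = (1.0,) * ndim if spacing is None else spacing
    mag = np.zeros(shape)
    mag[pos] = magnitude
    vec = np.zeros(shape + (ndim,))
    d = np.asarray(direction, dtype=float)
    vec[pos] = d / np.linalg.norm(d)
    return GradientField(magnitude=mag, vectors=vec, spacing=spacing)


class TestCastVotes:
    def test_single_voter_exact_footprint(self):
        field = single_voter_field((8, 8), (0, 0), (0, 1), magnitude=2.0)
        votes = cast_votes(field, r_um=2.5, phi=np.pi / 2)
        expected = np.zeros((8, 8))
        for site in [(0, 1), (0, 2), (1, 2)]:  # (-1, 2) clipped off-lattice
            expected[site] = 2.0
        np.testing.assert_array_equal(votes.scores, expected)

    def test_zero_field_casts_nothing(self):
        field = GradientField(magnitude=np.zeros((6, 6)),
                              vectors=np.zeros((6, 6, 2)), spacing=UNIT2)
        votes = cast_votes(field, r_um=3.0, phi=np.pi / 2)
        assert votes.total_mass() == 0.0

    def test_conservation_identity(self):
        rng = np.random.default_rng(0)
        field = random_gradient_field(rng, (12, 12, 12))
        votes = cast_votes(field, r_um=3.0, phi=np.pi / 4)
        expected = float((field.magnitude * votes.voter_member_counts).sum())
        assert votes.total_mass() == pytest.approx(expected, rel=1e-12)

    def test_subpixel_radius_rejected(self):
        field = single_voter_field((8, 8), (0, 0), (0, 1))
        with pytest.raises(ValueError):
            cast_votes(field, r_um=0.5, phi=np.pi / 2)


class TestOracleEquivalence:
    @pytest.mark.parametrize("shape", [(16, 16), (8, 8, 8)])
    @pytest.mark.parametrize("phi", [np.pi / 2, np.pi / 8])
    def test_project_equals_collect(self, shape, phi):
        rng = np.random.default_rng(hash((len(shape), round(phi, 3))) % 2**31)
        field = random_gradient_field(rng, shape)
        fast = cast_votes(field, r_um=4.0, phi=phi)
        slow = collect_votes_oracle(field, r_um=4.0, phi=phi)
        np.testing.assert_allclose(fast.scores, slow.scores, rtol=1e-9,
                                   atol=1e-12)

    def test_single_voter_same_field(self):
        field = single_voter_field((8, 8), (3, 3), (1, 0), magnitude=1.5)
        fast = cast_votes(field, r_um=3.0, phi=np.pi / 2)
        slow = collect_votes_oracle(field, r_um=3.0, phi=np.pi / 2)
        np.testing.assert_array_equal(fast.scores, slow.scores)

    def test_anisotropic_spacing_agrees(self):
        rng = np.random.default_rng(9)
        field = random_gradient_field(rng, (8, 8, 8), spacing=(2.0, 1.0, 1.0))
        fast = cast_votes(field, r_um=4.0, phi=np.pi / 4)
        slow = collect_votes_oracle(field, r_um=4.0, phi=np.pi / 4)
        np.testing.assert_allclose(fast.scores, slow.scores, rtol=1e-9)


class TestUpdateDirections:
    def test_voter_reorients_toward_cone_maximum(self):
        field = single_voter_field((8, 8), (0, 0), (0, 1), magnitude=2.0)
        votes = cast_votes(field, r_um=3.5, phi=np.pi / 2)
        scores = votes.scores.copy()
        scores[1, 2] = 10.0  # plant the maximum at offset (y=1, x=2)
        planted = type(votes)(scores=scores, iteration_index=0,
                              spacing=votes.spacing)
        updated = update_directions(field, planted, r_um=3.5, phi=np.pi / 2)
        expected = np.array([1.0, 2.0]) / np.sqrt(5.0)
        np.testing.assert_allclose(updated.vectors[0, 0], expected)
        assert updated.magnitude[0, 0] == 2.0  # magnitude preserved exactly

    def test_3d_reorientation_and_magnitude(self):
        field = single_voter_field((8, 8, 8), (0, 0, 0), (0, 0, 1),
                                   magnitude=5.0)
        votes = cast_votes(field, r_um=6.0, phi=np.pi / 2)
        scores = votes.scores.copy()
        scores[0, 3, 4] = 99.0
        planted = type(votes)(scores=scores, iteration_index=0,
                              spacing=votes.spacing)
        updated = update_directions(field, planted, r_um=6.0, phi=np.pi / 2)
        np.testing.assert_allclose(updated.vectors[0, 0, 0], [0.0, 0.6, 0.8])
        assert updated.magnitude[0, 0, 0] == 5.0

    def test_tie_resolves_to_lexicographically_smallest(self):
        field = single_voter_field((8, 8), (0, 0), (0, 1), magnitude=1.0)
        votes = cast_votes(field, r_um=2.5, phi=np.pi / 2)
        # constant over the cone members {(0,1),(0,2),(1,2)}
        updated = update_directions(field, votes, r_um=2.5, phi=np.pi / 2)
        np.testing.assert_allclose(updated.vectors[0, 0], [0.0, 1.0])

    def test_all_zero_scores_keep_direction(self):
        field = single_voter_field((8, 8), (4, 4), (0, 1))
        zero = cast_votes(GradientField(np.zeros((8, 8)), np.zeros((8, 8, 2)),
                                        UNIT2), r_um=3.0, phi=np.pi / 2)
        updated = update_directions(field, zero, r_um=3.0, phi=np.pi / 2)
        np.testing.assert_array_equal(updated.vectors, field.vectors)

    def test_shape_mismatch_rejected(self):
        field = single_voter_field((8, 8), (0, 0), (0, 1))
        votes = cast_votes(single_voter_field((9, 9), (0, 0), (0, 1)),
                           r_um=2.0, phi=np.pi / 2)
        with pytest.raises(ValueError):
            update_directions(field, votes, r_um=2.0, phi=np.pi / 2)


class TestSchedule:
    def test_halving_sequence_r10(self):
        s = make_schedule(10)
        np.testing.assert_allclose(
            s.phis, [np.pi / 2, np.pi / 4, np.pi / 8, np.pi / 16, np.pi / 32])
        assert s.n_iterations == 5
        assert s.phis[-1] < s.phi_t == 0.1

    def test_r1_two_steps(self):
        s = make_schedule(1)
        np.testing.assert_allclose(s.phis, [np.pi / 2, np.pi / 4])
        assert s.n_iterations == 2

    @pytest.mark.parametrize("r", [1, 2, 5, 17, 100])
    def test_strictly_decreasing_and_terminates(self, r):
        s = make_schedule(r)
        assert all(a > b for a, b in zip(s.phis, s.phis[1:]))
        assert s.phis[-1] < s.phi_t
        assert all(p >= s.phi_t for p in s.phis[:-1])

    def test_subunit_radius_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(0.5)


class TestIterativeVote:
    def test_single_disk_center_recovered(self, single_disk_phantom):
        votes = iterative_vote(single_disk_phantom.image, 7.0)
        peak = np.unravel_index(np.argmax(votes.scores), votes.shape)
        err = np.linalg.norm(peak - single_disk_phantom.centers[0])
        assert err <= 1.0

    def test_single_ball_center_recovered(self, single_ball_phantom):
        votes = iterative_vote(single_ball_phantom.image, 6.0)
        peak = np.unravel_index(np.argmax(votes.scores), votes.shape)
        err = np.linalg.norm(peak - single_ball_phantom.centers[0])
        assert err <= 1.0

    def test_blank_image_zero_votes(self):
        img = ImageGrid(np.full((24, 24), 0.5), UNIT2)
        votes = iterative_vote(img, 4.0, sigma_blur=None)
        assert votes.total_mass() == 0.0

    def test_radius_not_exceeding_spacing_rejected(self):
        img = ImageGrid(np.zeros((16, 16)), (2.0, 2.0))
        with pytest.raises(ValueError):
            iterative_vote(img, 1.5)

    def test_symmetric_blob_peak_is_stationary(self, single_disk_phantom):
        votes, diag = iterative_vote(single_disk_phantom.image, 7.0,
                                     return_diagnostics=True)
        # conservation holds at every logged iteration
        for mass, expected in zip(diag.vote_mass, diag.expected_mass):
            assert mass == pytest.approx(expected, rel=1e-9)

    def test_rotation_equivariance(self):
        # an off-center dark disk; rotating the input by 90 degrees must
        # rotate the first-pass vote field exactly and move the final
        # detection to the rotated center
        base = np.full((40, 40), 0.75)
        yy, xx = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        d = np.sqrt((yy - 14.0) ** 2 + (xx - 23.0) ** 2)
        base -= 0.5 * np.clip(1.0 - (d - 4.0), 0, 1)
        img = ImageGrid(base, UNIT2)
        rot = ImageGrid(np.rot90(base).copy(), UNIT2)

        from ivote import compute_gradient
        first = cast_votes(compute_gradient(img), 6.0, np.pi / 2).scores
        first_rot = cast_votes(compute_gradient(rot), 6.0, np.pi / 2).scores
        np.testing.assert_allclose(first_rot, np.rot90(first), atol=1e-9)

        peak = np.unravel_index(np.argmax(iterative_vote(img, 6.0).scores),
                                (40, 40))
        peak_rot = np.unravel_index(
            np.argmax(iterative_vote(rot, 6.0).scores), (40, 40))
        mapped = (40 - 1 - peak[1], peak[0])  # rot90 index map
        assert np.linalg.norm(np.subtract(peak_rot, mapped)) <= 1.0
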