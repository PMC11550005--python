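"""Latch/kink descriptors, domain partition + rotation, densities, state labels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbpconf import conformation, structio, synthetic
from sbpconf.errors import SingleRigidBodyError
from testutil import atom_line, random_rigid_transform


def apply_rigid(model, R, t):
    import copy

    moved = copy.deepcopy(model)
    for a in moved.atoms():
        a.xyz = R @ a.xyz + t
    return moved


@pytest.fixture(scope="module")
def toy_spec():
    return conformation.DescriptorSpec(
        latch_pair=((1, "CA"), (2, "CA")),
        kink_triplet=(3, 4, 5),
        contacts={"c1": ((1, "CA"), (3, "CA"))},
    )


def toy_model(positions):
    lines = [atom_line(i, "CA", "GLY", "A", i, *xyz)
             for i, xyz in enumerate(positions, start=1)]
    return structio.read_pdb("\n".join(lines))


class TestDescriptors:
    def test_latch_distance_direct(self, toy_spec):
        m = toy_model([(0, 0, 0), (10, 0, 0), (0, 5, 0), (5, 5, 0), (10, 5, 0)])
        assert conformation.latch_distance(m, toy_spec) == 10.0

    def test_kink_collinear_is_180(self, toy_spec):
        m = toy_model([(0, 0, 0), (1, 0, 0), (0, 5, 0), (5, 5, 0), (10, 5, 0)])
        assert conformation.kink_angle(m, toy_spec) == pytest.approx(180.0)

    def test_kink_right_angle(self, toy_spec):
        m = toy_model([(0, 0, 0), (1, 0, 0), (5, 5, 5), (0, 0, 5), (5, 0, 5)])
        # vertex res4 at (0,0,5); arms to res3 (5,5,5)-> (5,5,0) and res5 (5,0,5)->(5,0,0)
        v1 = np.array([5, 5, 0])
        v2 = np.array([5, 0, 0])
        expected = math.degrees(math.acos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert conformation.kink_angle(m, toy_spec) == pytest.approx(expected)

    def test_contact_distances(self, toy_spec):
        m = toy_model([(0, 0, 0), (1, 0, 0), (3, 4, 0), (5, 5, 0), (10, 5, 0)])
        assert conformation.contact_distances(m, toy_spec)["c1"] == pytest.approx(5.0)

    def test_synthetic_open_exceeds_closed(self):
        closed, t_closed = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=10.0, seed=6))
        opened, t_open = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=40.0, seed=6))
        spec = t_closed.descriptor_spec()
        assert conformation.latch_distance(opened, spec) > conformation.latch_distance(closed, spec)

    def test_kink_tracks_hinge_angle(self):
        model, truth = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=55.0, seed=6))
        measured = conformation.kink_angle(model, truth.descriptor_spec())
        assert measured == pytest.approx(truth.kink_angle, abs=1e-9)
        # opening straightens nothing here: the connector arms splay with the lobes
        _, closed_truth = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=0.0, seed=6))
        assert measured == pytest.approx(closed_truth.kink_angle + 55.0, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        model, truth = synthetic.make_two_lobe(
            synthetic.TwoLobeSpec(hinge_angle=float(rng.uniform(5, 60)), seed=seed))
        spec = truth.descriptor_spec()
        R, t = random_rigid_transform(rng)
        moved = apply_rigid(model, R, t)
        assert abs(conformation.latch_distance(moved, spec) -
                   conformation.latch_distance(model, spec)) < 1e-9
        assert abs(conformation.kink_angle(moved, spec) -
                   conformation.kink_angle(model, spec)) < 1e-9


class TestPartitionAndRotation:
    def test_global_rigid_motion_is_single_body(self, two_lobe_pair, rng):
        closed, *_ = two_lobe_pair
        R, t = random_rigid_transform(rng)
        moved = apply_rigid(closed, R, t)
        with pytest.raises(SingleRigidBodyError):
            conformation.partition_domains(closed, moved)

    def test_partition_recovers_generator_labels(self, two_lobe_pair):
        closed, truth, opened, _ = two_lobe_pair
        part = conformation.partition_domains(closed, opened, min_domain=20)
        d1 = {k[0] for k in part.domain1}
        d2 = {k[0] for k in part.domain2}
        true1, true2 = set(truth.lobe1_resseqs), set(truth.lobe2_resseqs)
        if len(d1 & true2) > len(d1 & true1):
            d1, d2 = d2, d1
        # hinge-adjacent ambiguity of up to 3 residues is allowed
        assert len(true1 - d1) <= 3 and len(true2 - d2) <= 3
        assert len(d1 - true1 - set(truth.hinge_resseqs)) <= 3
        assert len(d2 - true2 - set(truth.hinge_resseqs)) <= 3

    def test_partition_symmetric_in_order(self, two_lobe_pair):
        # Same partition up to label swap; residues exactly on the hinge axis
        # (zero residual under both fits) may tie-break either way.
        closed, _, opened, _ = two_lobe_pair
        p_ab = conformation.partition_domains(closed, opened)
        p_ba = conformation.partition_domains(opened, closed)
        ab1, ab2 = set(p_ab.domain1), set(p_ab.domain2)
        ba1, ba2 = set(p_ba.domain1), set(p_ba.domain2)
        if len(ab1 & ba1) < len(ab1 & ba2):
            ba1, ba2 = ba2, ba1
        assert len(ab1 ^ ba1) <= 3
        assert len(ab2 ^ ba2) <= 3

    def test_identity_rotation_zero(self, two_lobe_pair):
        closed, _, opened, _ = two_lobe_pair
        part = conformation.partition_domains(closed, opened)
        rot = conformation.domain_rotation(closed, closed, part)
        assert rot.angle == pytest.approx(0.0, abs=1e-9)

    def test_constructed_23_degrees(self, two_lobe_pair):
        closed, _, opened, _ = two_lobe_pair
        part = conformation.partition_domains(closed, opened)
        rot = conformation.domain_rotation(closed, opened, part)
        assert rot.angle == pytest.approx(23.0, abs=1e-6)
        assert np.linalg.norm(rot.axis) == pytest.approx(1.0, abs=1e-9)
        assert abs(rot.axis[2]) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("theta", [5.0, 12.0, 23.0, 37.0, 48.0, 60.0])
    def test_rotation_recovery_across_angles(self, theta):
        closed, _ = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=0.0, seed=9))
        opened, _ = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=theta, seed=9))
        part = conformation.partition_domains(closed, opened)
        rot = conformation.domain_rotation(closed, opened, part)
        assert rot.angle == pytest.approx(theta, abs=1e-6)


class TestSeries:
    def test_single_frame_matches_direct_calls(self):
        model, truth = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=20.0, seed=2))
        spec = truth.descriptor_spec()
        series = conformation.descriptor_series([model], spec)
        assert len(series) == 1
        assert series.latch[0] == conformation.latch_distance(model, spec)
        assert series.kink[0] == conformation.kink_angle(model, spec)

    def test_constant_ensemble_constant_series(self):
        frames, _ = synthetic.make_ensemble(
            synthetic.TwoLobeSpec(seed=2),
            synthetic.EnsembleSpec(n_frames=10, dynamics=synthetic.ConstantDynamics(25.0), seed=2))
        _, truth = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=25.0, seed=2))
        series = conformation.descriptor_series(frames, truth.descriptor_spec())
        assert np.ptp(series.latch) == 0.0

    def test_ou_ensemble_mean_recovery(self):
        dyn = synthetic.OUProcess(mean=25.0, relaxation=5.0, sd=3.0)
        frames, truth_df = synthetic.make_ensemble(
            synthetic.TwoLobeSpec(seed=8),
            synthetic.EnsembleSpec(n_frames=400, dynamics=dyn, seed=8))
        _, t = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=25.0, seed=8))
        series = conformation.descriptor_series(frames, t.descriptor_spec())
        # effective sample size reduced by OU autocorrelation
        n_eff = 400 / (2 * dyn.relaxation)
        se = series.latch.std(ddof=1) / math.sqrt(n_eff)
        # 0.1 A allowance for the (small) Jensen gap of the nonlinear
        # angle -> distance map at sd = 3 deg
        assert abs(series.latch.mean() - t.latch_gap) < 3 * se + 0.1


class TestDensity:
    def test_standard_normal_peak(self, rng):
        x = rng.normal(size=10_000)
        grid, dens = conformation.probability_density(x, "kde")
        at0 = dens[np.argmin(np.abs(grid))]
        assert at0 == pytest.approx(1 / math.sqrt(2 * math.pi), rel=0.05)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_density_level(self, rng):
        x = rng.uniform(size=50_000)
        grid, dens = conformation.probability_density(x, "kde")
        inner = (grid > 0.1) & (grid < 0.9)
        assert np.all(np.abs(dens[inner] - 1.0) < 0.05)
        ghist, dhist = conformation.probability_density(x, "histogram")
        width = ghist[1] - ghist[0]
        assert (dhist * width).sum() == pytest.approx(1.0, abs=1e-9)

    def test_bimodal_modes_recovered(self, rng):
        x = np.concatenate([rng.normal(20.0, 1.0, 5000), rng.normal(30.0, 1.0, 5000)])
        grid, dens = conformation.probability_density(x, "kde")
        from scipy.signal import argrelmax

        peaks = grid[argrelmax(dens, order=5)[0]]
        assert np.min(np.abs(peaks - 20.0)) < 0.5
        assert np.min(np.abs(peaks - 30.0)) < 0.5

    def test_identical_values_fall_back_with_warning(self):
        with pytest.warns(UserWarning):
            grid, dens = conformation.probability_density(np.full(50, 7.0), "kde")
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, rel=1e-6)


class TestClassifyState:
    def test_all_at_closed_ref(self):
        labels, frac = conformation.classify_state(np.full(20, 15.0), 15.0, 30.0)
        assert frac["closed"] == 1.0

    def test_alternating_half_half(self):
        vals = np.array([15.0, 30.0] * 10)
        _, frac = conformation.classify_state(vals, 15.0, 30.0)
        assert frac["closed"] == 0.5 and frac["open"] == 0.5

    def test_fractions_sum_to_one(self, rng):
        vals = rng.uniform(10, 40, 101)
        _, frac = conformation.classify_state(vals, 15.0, 30.0)
        assert sum(frac.values()) == 1.0

    def test_two_state_ensemble_occupancy(self):
        dyn = synthetic.TwoStateDynamics(angles=(10.0, 40.0), occupancies=(0.1, 0.9))
        frames, truth_df = synthetic.make_ensemble(
            synthetic.TwoLobeSpec(seed=7),
            synthetic.EnsembleSpec(n_frames=300, dynamics=dyn, seed=7))
        _, t_c = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=10.0, seed=7))
        _, t_o = synthetic.make_two_lobe(synthetic.TwoLobeSpec(hinge_angle=40.0, seed=7))
        series = conformation.descriptor_series(frames, t_c.descriptor_spec())
        _, frac = conformation.classify_state(series, t_c.latch_gap, t_o.latch_gap, margin=1.0)
        # binomial 95% bounds around p = 0.1 with n = 300
        bound = 1.96 * math.sqrt(0.1 * 0.9 / 300)
        assert abs(frac["closed"] - 0.1) < bound + 1e-9

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            conformation.classify_state(np.arange(10.0), 15.0, 16.0, margin=1.0)
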