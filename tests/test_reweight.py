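"""Work accumulation, Jarzynski averaging, WHAM frame weights, state ΔF/ΔΔF."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import logsumexp

import pullfe as pf
from pullfe.constants import kt
from pullfe.errors import ConventionError, DegeneratePartitionError, ShapeError

KBT = kt(300.0)
BETA = 1.0 / KBT


def ensemble_from_works(works, positions=None, lam=None, nhb=None):
    """Hand-built ensemble on a shared grid from a (N, T) work matrix."""
    works = np.asarray(works, dtype=float)
    n, t = works.shape
    time = np.arange(t, dtype=float)
    lam = np.zeros(t) if lam is None else np.asarray(lam, dtype=float)
    trajs = []
    for i in range(n):
        trajs.append(pf.WorkTrajectory(
            time=time,
            position=np.zeros(t) if positions is None else np.asarray(positions[i], float),
            lam=lam,
            work=works[i],
            nhb=None if nhb is None else np.asarray(nhb[i]),
        ))
    return pf.WorkEnsemble(trajectories=tuple(trajs))


class TestAccumulateWork:
    def test_constant_lambda_gives_zero(self):
        w = pf.accumulate_work(np.random.default_rng(0).normal(size=10),
                               np.full(10, 0.2), 3.9e4)
        np.testing.assert_array_equal(w, np.zeros(10))

    def test_single_step_hand_value(self):
        # x = 0 throughout, lambda 0 -> 0.1 nm at k = 3.9e4: ΔW = k/2 * 0.01 = 195
        w = pf.accumulate_work([0.0, 0.0], [0.0, 0.1], 3.9e4)
        assert w[1] == pytest.approx(195.0)

    def test_tracking_restraint_pays_half_k_delta_sq_per_step(self):
        lam = np.linspace(0.0, 0.1, 11)
        delta = lam[1] - lam[0]
        w = pf.accumulate_work(lam, lam, 3.9e4)
        np.testing.assert_allclose(np.diff(w), 0.5 * 3.9e4 * delta**2)

    def test_length_mismatch_raises(self):
        with pytest.raises(ShapeError):
            pf.accumulate_work([0.0, 1.0], [0.0, 0.1, 0.2], 1.0)

    def test_matches_simulator_convention(self, apo_landscape):
        # at save_stride=1 the recorded grid is the integration grid, so the
        # recomputation reproduces the simulator's work series exactly
        prot = pf.PullingProtocol(velocity=0.35 / (500 * 5e-3), save_stride=1)
        tr = pf.simulate_trajectory(apo_landscape, prot, seed=8)
        w = pf.accumulate_work(tr.position, tr.lam, prot.spring_constant)
        np.testing.assert_allclose(w, tr.work, rtol=1e-10, atol=1e-10)


class TestJarzynskiProfile:
    def test_zero_works_give_zero_profile(self):
        ens = ensemble_from_works(np.zeros((5, 4)))
        np.testing.assert_allclose(
            pf.jarzynski_profile(ens, 300.0).values, 0.0, atol=1e-12)

    def test_single_replica_returns_its_work(self):
        w = np.array([[0.0, 1.5, -2.0, 4.0]])
        ens = ensemble_from_works(w)
        np.testing.assert_allclose(pf.jarzynski_profile(ens, 300.0).values, w[0])

    def test_two_sample_exponential_average(self):
        ens = ensemble_from_works([[0.0, 0.0], [0.0, KBT * np.log(2)]])
        f = pf.jarzynski_profile(ens, 300.0).values
        assert f[1] == pytest.approx(-KBT * np.log(0.75), rel=1e-12)
        assert f[1] == pytest.approx(0.717, abs=2e-3)

    def test_log_sum_exp_handles_extreme_works(self):
        # βW spanning ±1e4 must neither overflow nor underflow to -inf
        big = 1e4 * KBT
        ens = ensemble_from_works([[0.0, big], [0.0, -big]])
        f = pf.jarzynski_profile(ens, 300.0).values
        assert np.isfinite(f).all()
        assert f[1] == pytest.approx(-big + KBT * np.log(2), rel=1e-9)

    def test_jensen_bound_against_mean_work(self, small_apo_ensemble):
        jar = pf.jarzynski_profile(small_apo_ensemble, 300.0).values
        mean = pf.mean_work_profile(small_apo_ensemble).values
        assert np.all(jar <= mean + 1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        w = np.concatenate([np.zeros((6, 1)), rng.normal(0, 2, (6, 5))], axis=1)
        f0 = pf.jarzynski_profile(ensemble_from_works(w), 300.0).values
        shifted = w + np.concatenate([[0.0], np.full(5, 3.7)])
        f1 = pf.jarzynski_profile(ensemble_from_works(shifted), 300.0).values
        np.testing.assert_allclose(f1[1:], f0[1:] + 3.7, rtol=1e-10)


class TestFrameWeights:
    def test_single_slice_reduces_to_umbrella_unbiasing(self):
        # one time slice, zero works: w_i ∝ exp(+βV(q_i, λ0))
        k = 3.9e4
        rng = np.random.default_rng(3)
        q = rng.normal(0.0, 0.01, size=(40, 1))
        ens = ensemble_from_works(np.zeros((40, 1)), positions=q,
                                  lam=np.zeros(1))
        w = pf.frame_weights(ens, spring_constant=k, temperature=300.0)
        v = 0.5 * k * q[:, 0] ** 2
        expected = np.exp(BETA * v - logsumexp(BETA * v))
        np.testing.assert_allclose(w.weights[:, 0], expected, rtol=1e-10)

    def test_single_slice_two_frame_hand_values(self):
        # bias energies {0, kT ln 2} -> weights {1/3, 2/3}
        k = 2.0
        q1 = np.sqrt(2 * KBT * np.log(2) / k)
        ens = ensemble_from_works(np.zeros((2, 1)),
                                  positions=[[0.0], [q1]], lam=np.zeros(1))
        w = pf.frame_weights(ens, spring_constant=k, temperature=300.0)
        np.testing.assert_allclose(w.weights[:, 0], [1 / 3, 2 / 3], rtol=1e-12)

    def test_weights_normalized_and_nonnegative(self, small_apo_ensemble):
        w = pf.frame_weights(small_apo_ensemble)
        assert w.weights.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(w.weights >= 0)

    def test_shift_invariance_of_weights(self, small_apo_ensemble):
        # adding one constant to every work value (all replicas, all slices)
        # rescales numerator and denominator identically
        from pullfe.reweight import _jarzynski_values, _log_bias, _log_weights_from

        ens = small_apo_ensemble
        beta = 1.0 / kt(300.0)
        nbb = _log_bias(ens.position_matrix(), ens.lam,
                        ens.protocol.spring_constant, beta)
        out = {}
        for shift in (0.0, 5.0):
            w = ens.work_matrix() + shift
            f = _jarzynski_values(w, beta)
            out[shift] = _log_weights_from(w, nbb, beta * f, beta * f, beta)
        np.testing.assert_allclose(out[5.0], out[0.0], rtol=1e-8)


class TestProjectFreeEnergy:
    def _weights(self, w_list):
        lw = np.log(np.asarray(w_list, dtype=float))[None, :]
        return pf.FrameWeights(log_weights=lw - logsumexp(lw),
                               slice_free_energy=np.zeros(len(w_list)),
                               temperature=300.0)

    def test_equal_bins_flat_profile(self):
        w = self._weights([0.25, 0.25, 0.25, 0.25])
        prof = pf.project_free_energy(w, [[0.1, 0.1, 0.9, 0.9]], [0.0, 0.5, 1.0])
        assert prof.values[0] == pytest.approx(prof.values[1])

    def test_two_thirds_one_third_hand_value(self):
        w = self._weights([2 / 3, 1 / 3])
        prof = pf.project_free_energy(w, [[0.1, 0.9]], [0.0, 0.5, 1.0])
        assert prof.values[1] - prof.values[0] == pytest.approx(
            KBT * np.log(2), rel=1e-10)
        assert prof.values.min() == 0.0  # minimum-anchored

    def test_empty_bins_are_nan(self):
        w = self._weights([0.5, 0.5])
        prof = pf.project_free_energy(w, [[0.1, 0.2]], [0.0, 0.5, 1.0])
        assert np.isnan(prof.values[1])

    def test_discrete_binning_and_single_support_flag(self):
        w = self._weights([0.5, 0.5])
        prof = pf.project_free_energy(w, [[1, 1]], "discrete")
        assert prof.single_support
        np.testing.assert_array_equal(prof.grid, [1])

    def test_slow_pulled_profile_matches_quadrature(self, small_apo_ensemble,
                                                    apo_landscape):
        w = pf.frame_weights(small_apo_ensemble)
        pos = small_apo_ensemble.position_matrix()
        edges = np.linspace(0.0, 0.35, 15)
        prof = pf.project_free_energy(w, pos, edges)
        exact = []
        for a, b in zip(edges[:-1], edges[1:]):
            z, _ = integrate.quad(
                lambda x: np.exp(-BETA * apo_landscape.energy(x)), a, b, limit=200)
            exact.append(-KBT * np.log(z))
        exact = np.asarray(exact) - np.min(exact)
        # 8x pulling speed, 48 replicas: agreement within ~1 kJ/mol bin-wise
        assert np.nanmax(np.abs(prof.values - exact)) < 1.0


class TestStateDeltaF:
    def _weights_and_nhb(self, bound_share):
        lw = np.log([bound_share, 1.0 - bound_share])[None, :]
        w = pf.FrameWeights(log_weights=lw, slice_free_energy=np.zeros(2),
                            temperature=300.0)
        nhb = np.array([[2, 0]])
        return w, nhb

    def test_equal_weight_gives_zero(self):
        w, nhb = self._weights_and_nhb(0.5)
        assert pf.state_delta_f(w, nhb).value == pytest.approx(0.0, abs=1e-12)

    def test_two_thirds_bound_hand_value(self):
        w, nhb = self._weights_and_nhb(2 / 3)
        res = pf.state_delta_f(w, nhb)
        assert res.value == pytest.approx(KBT * np.log(2), rel=1e-10)
        assert res.value == pytest.approx(1.728, abs=2e-3)

    def test_formation_is_exact_negative(self):
        w, nhb = self._weights_and_nhb(0.7)
        b = pf.state_delta_f(w, nhb, direction="breaking")
        f = pf.state_delta_f(w, nhb, direction="formation")
        assert f.value == -b.value

    def test_empty_state_raises_with_name(self):
        w = pf.FrameWeights(log_weights=np.log([[0.5, 0.5]]),
                            slice_free_energy=np.zeros(2), temperature=300.0)
        with pytest.raises(DegeneratePartitionError, match="unbound"):
            pf.state_delta_f(w, np.array([[2, 1]]))
        with pytest.raises(DegeneratePartitionError, match="bound"):
            pf.state_delta_f(w, np.array([[0, 0]]))

    def test_recovery_on_calibrated_landscape(self, small_apo_ensemble):
        # 8x pulling, 48 replicas: estimate should land near the -2.5 truth
        w = pf.frame_weights(small_apo_ensemble)
        res = pf.state_delta_f(w, small_apo_ensemble.nhb_matrix())
        assert res.value == pytest.approx(-2.5, abs=1.5)


class TestDeltaDeltaF:
    def _result(self, value, se=None, direction="breaking"):
        return pf.DeltaFResult(value=value, direction=direction,
                               temperature=300.0, n_replicas=512, se=se)

    def test_reported_two_system_difference(self):
        # apo -2.5, holo +1.9 -> ΔΔF = -4.4 (ligand stabilizes the pair)
        out = pf.delta_delta_f(self._result(-2.5), self._result(1.9))
        assert out.value == pytest.approx(-4.4)

    def test_identical_inputs_give_zero(self):
        out = pf.delta_delta_f(self._result(1.0, 0.5), self._result(1.0, 0.5))
        assert out.value == 0.0

    def test_errors_combine_in_quadrature(self):
        out = pf.delta_delta_f(self._result(-2.5, 1.4), self._result(1.9, 1.7))
        assert out.se == pytest.approx(np.hypot(1.4, 1.7), rel=1e-12)
        assert out.se == pytest.approx(2.2, abs=0.01)

    def test_direction_mismatch_raises(self):
        with pytest.raises(ConventionError):
            pf.delta_delta_f(self._result(1.0),
                             self._result(1.0, direction="formation"))


class TestWeightConcentration:
    def _weights(self, traj_weights):
        tw = np.asarray(traj_weights, dtype=float)[:, None]
        return pf.FrameWeights(log_weights=np.log(tw / tw.sum()),
                               slice_free_energy=np.zeros(1), temperature=300.0)

    def test_equal_trajectories(self):
        d = pf.weight_concentration(self._weights([1.0] * 8))
        assert d["ess"] == pytest.approx(8.0)
        assert d["max_traj_fraction"] == pytest.approx(1 / 8)

    def test_single_dominant_trajectory_warns(self):
        with pytest.warns(pf.OutlierDominationWarning):
            d = pf.weight_concentration(self._weights([1e-12, 1e-12, 1.0]))
        assert d["ess"] == pytest.approx(1.0, rel=1e-6)
        assert d["max_traj_fraction"] == pytest.approx(1.0, rel=1e-6)

    def test_two_thirds_one_third_hand_value(self):
        with pytest.warns(pf.OutlierDominationWarning):  # 2/3 > 1/2
            d = pf.weight_concentration(self._weights([2 / 3, 1 / 3]))
        assert d["ess"] == pytest.approx(1.8, rel=1e-12)

    def test_low_work_outlier_is_flagged(self, small_apo_ensemble):
        # one replica with work lowered by 10 kT dominates the exponential
        # average: the pathology of rare low-work realizations
        drop = 10 * KBT
        trajs = list(small_apo_ensemble.trajectories)
        t0 = trajs[0]
        trajs[0] = pf.WorkTrajectory(
            time=t0.time, position=t0.position, lam=t0.lam,
            work=t0.work - np.where(t0.time > 0, drop, 0.0), nhb=t0.nhb)
        ens = pf.WorkEnsemble(trajectories=tuple(trajs),
                              protocol=small_apo_ensemble.protocol)
        with pytest.warns(pf.OutlierDominationWarning):
            w = pf.frame_weights(ens)
            d = pf.weight_concentration(w)
        assert d["max_traj_fraction"] > 0.5
        assert d["ess"] < 5
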