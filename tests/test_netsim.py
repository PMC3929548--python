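"""Simulator unit tests: dynamics, events, sampling, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from ifgc import netsim
from ifgc.netsim import (DriveSpec, NetworkSpec, NeuronParams, ParameterError,
                         common_input_fraction, generate_random_network,
                         sample_poisson_trains, simulate, two_neuron_network)


class TestNetworkSpec:
    def test_rejects_autapses_and_bad_entries(self):
        A = np.eye(2, dtype=int)
        with pytest.raises(ParameterError, match="autapse"):
            NetworkSpec(n_exc=2, adjacency=A)
        with pytest.raises(ParameterError, match="0 or 1"):
            NetworkSpec(n_exc=2, adjacency=np.array([[0, 2], [0, 0]]))
        with pytest.raises(ParameterError):
            NetworkSpec(n_exc=1, n_inh=-1)

    def test_coupling_matrix_by_class(self):
        A = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        net = NetworkSpec(n_exc=2, n_inh=1, adjacency=A, S_ee=1.0, S_ie=2.0,
                          S_ei=3.0, S_ii=4.0)
        C = net.coupling_matrix()
        assert C[0, 1] == 1.0          # E -> E
        assert C[0, 2] == 2.0          # E -> I
        assert C[2, 0] == 3.0          # I -> E
        assert np.all(np.diag(C) == 0)

    def test_two_neuron_helper_is_unidirectional(self):
        net = two_neuron_network()
        assert net.adjacency[0, 1] == 1
        assert net.adjacency.sum() == 1


class TestRandomNetwork:
    def test_zero_density_gives_empty_graph(self):
        net = generate_random_network(2, density=0.0, seed=3)
        assert net.adjacency.sum() == 0

    def test_edge_count_within_binomial_99_interval(self):
        net = generate_random_network(100, density=0.05, seed=11)
        n_pairs = 100 * 99
        lo, hi = stats.binom.ppf([0.005, 0.995], n_pairs, 0.05)
        assert lo <= net.adjacency.sum() <= hi
        assert np.all(np.diag(net.adjacency) == 0)

    def test_reproducible_and_validated(self):
        a = generate_random_network(10, density=0.3, seed=5).adjacency
        b = generate_random_network(10, density=0.3, seed=5).adjacency
        assert np.array_equal(a, b)
        with pytest.raises(ParameterError):
            generate_random_network(10, density=1.5)


class TestPoissonTrains:
    def test_zero_rates_empty(self):
        ev, _ = sample_poisson_trains(DriveSpec(rate=0.0), 3, 1000.0, seed=0)
        assert all(len(e) == 0 for e in ev)

    def test_counts_near_expectation(self):
        # rate * duration = 1000; count should be within 3.3*sqrt(1000)
        ev, _ = sample_poisson_trains(DriveSpec(rate=0.1), 4, 10_000.0, seed=2)
        for e in ev:
            assert abs(len(e) - 1000) < 3.3 * np.sqrt(1000)

    def test_common_train_copied_identically(self):
        dr = DriveSpec(rate=0.05, common_rate=0.02, common_strength=0.5,
                       strength=0.1)
        ev, st = sample_poisson_trains(dr, 3, 5000.0, seed=7)
        commons = [e[s == 0.5] for e, s in zip(ev, st)]
        assert len(commons[0]) > 0
        for c in commons[1:]:
            np.testing.assert_array_equal(commons[0], c)

    def test_substreams_stable_under_added_neuron(self):
        ev3, _ = sample_poisson_trains(DriveSpec(rate=0.1), 3, 2000.0, seed=9)
        ev4, _ = sample_poisson_trains(DriveSpec(rate=0.1), 4, 2000.0, seed=9)
        for i in range(3):
            np.testing.assert_array_equal(ev3[i], ev4[i])


class TestCommonInputFraction:
    @pytest.mark.parametrize("lam,lam_c,expected",
                             [(10, 0, 0.0), (0, 5, 1.0), (3, 1, 0.25)])
    def test_values(self, lam, lam_c, expected):
        d = DriveSpec(rate=lam, common_rate=lam_c)
        assert common_input_fraction(d) == pytest.approx(expected)

    def test_undefined_for_zero_rates(self):
        with pytest.raises(ParameterError):
            common_input_fraction(DriveSpec(rate=0.0, common_rate=0.0))


class TestSimulate:
    def test_equilibrium_without_input(self, params):
        net = NetworkSpec(n_exc=1)
        rec = simulate(net, params, DriveSpec(rate=0.0, seed=0), duration=500)
        np.testing.assert_allclose(rec.voltages, params.E_L, atol=1e-12)
        assert len(rec.spikes[0]) == 0

    def test_single_epsp_matches_fine_step_integration(self, params):
        # one subthreshold feedforward spike; reference at dt/100
        net = NetworkSpec(n_exc=1)
        drive = DriveSpec(rate=0.0, seed=0)
        events = ([np.array([20.0])], [np.array([0.05])])
        recs = [simulate(net, params, drive, duration=200, dt=dt, fs=1.0,
                         events=events)
                for dt in (0.01, 0.0001)]
        err = np.abs(recs[0].voltages - recs[1].voltages).max()
        assert err < 1e-6

    def test_dt_convergence_second_order(self, params):
        # subthreshold drive with events snapped to a grid common to all dt
        # values, so binning and spike-reset effects cannot mask the
        # integrator's order
        net = two_neuron_network()
        drive = DriveSpec(rate=0.04, strength=0.02, seed=4)
        ev, js = sample_poisson_trains(drive, 2, 2000.0)
        # snap to a 0.1-ms grid shared by all dt values, nudged well inside
        # the bin so float fuzz cannot flip the binning between dt choices
        ev = [np.round(e, 1) + 1e-3 for e in ev]
        errs = []
        ref = simulate(net, params, drive, duration=2000, dt=0.00125,
                       events=(ev, js))
        assert all(len(s) == 0 for s in ref.spikes)  # stays subthreshold
        for dt in (0.02, 0.01):
            rec = simulate(net, params, drive, duration=2000, dt=dt,
                           events=(ev, js))
            errs.append(np.abs(rec.voltages - ref.voltages).max())
        # halving dt should cut the error ~4x for a second-order scheme
        assert errs[1] < errs[0] / 3.0

    def test_refractory_invariant(self, two_neuron_record, params):
        for st in two_neuron_record.spikes:
            if len(st) > 1:
                assert np.diff(st).min() >= params.tau_ref - 1e-9

    def test_voltages_finite_and_sample_count(self, two_neuron_record):
        rec = two_neuron_record
        assert np.isfinite(rec.voltages).all()
        assert rec.voltages.shape[0] == int(rec.duration * rec.fs)

    def test_firing_regularizes_with_drive_rate(self, two_neuron_net, params):
        cvs = []
        for lam in (netsim.REGIME_RATES["fluctuation"],
                    netsim.REGIME_RATES["mean_driven"]):
            rec = simulate(two_neuron_net, params,
                           DriveSpec(rate=lam, strength=0.07, seed=1),
                           duration=60_000)
            cvs.append(netsim.isi_cv(rec.spikes[0]))
        assert cvs[1] < cvs[0]  # mean-driven firing is markedly more regular

    def test_drive_only_limit_factorizes(self, params):
        # with all couplings zero, neuron 0's trajectory ignores the others
        drive = DriveSpec(rate=0.1, strength=0.07, seed=13)
        rec1 = simulate(NetworkSpec(n_exc=1, S_ee=0.0), params, drive,
                        duration=60_000)
        rec3 = simulate(NetworkSpec(n_exc=3, S_ee=0.0), params, drive,
                        duration=60_000)
        np.testing.assert_allclose(rec1.voltages[:, 0], rec3.voltages[:, 0],
                                   atol=1e-12)
        np.testing.assert_array_equal(rec1.spikes[0], rec3.spikes[0])

    def test_eif_reduces_to_if_without_spike_current(self, params):
        drive = DriveSpec(rate=0.1, strength=0.07, seed=4)
        events = sample_poisson_trains(drive, 2, 5000.0)
        eif = simulate(two_neuron_network(model_kind="EIF"),
                       NeuronParams(delta_T=1e-12), drive, duration=5000,
                       events=events)
        iaf = simulate(two_neuron_network(model_kind="IF"), params, drive,
                       duration=5000, events=events)
        assert np.abs(eif.voltages - iaf.voltages).max() <= 1e-6

    def test_eif_spikes_and_stays_below_cutoff(self, params):
        net = two_neuron_network(model_kind="EIF")
        rec = simulate(net, params, DriveSpec(rate=0.1, strength=0.07, seed=2),
                       duration=30_000)
        assert len(rec.spikes[0]) > 0
        assert rec.voltages.max() <= params.V_cut

    def test_validation_errors(self, params, two_neuron_net):
        with pytest.raises(ParameterError, match="dt"):
            simulate(two_neuron_net, params, DriveSpec(), duration=100, dt=1.0)
        with pytest.raises(ParameterError, match="window"):
            simulate(two_neuron_net, params, DriveSpec(), duration=0.5, fs=1.0)

    def test_bit_identical_reruns(self, two_neuron_net, params):
        dr = DriveSpec(rate=0.1, strength=0.07, seed=21)
        a = simulate(two_neuron_net, params, dr, duration=2000)
        b = simulate(two_neuron_net, params, dr, duration=2000)
        np.testing.assert_array_equal(a.voltages, b.voltages)
        for s, t in zip(a.spikes, b.spikes):
            np.testing.assert_array_equal(s, t)
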