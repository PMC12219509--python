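"""Contact events, autocorrelation, residence times, solvation free energy."""

import math

import numpy as np
import pytest

from memfold import DomainError, InputError, SIMULATION_CONTEXT
from memfold import solvation as solv
from memfold import synthetic as syn


def _trace(q, dt=1.0, mol=0):
    return solv.ContactTrace(molecule_id=mol, q=np.asarray(q), frame_interval=dt)


def _brute_force_events(q, gap_frames):
    """Independent run-length scanner used as the event-detection oracle."""
    events, start, last = [], None, None
    for i, v in enumerate(q):
        if v > 0:
            if start is None:
                start, last = i, i
            elif i - last - 1 <= gap_frames:
                last = i
            else:
                events.append((start, last))
                start, last = i, i
    if start is not None:
        events.append((start, last))
    return events


class TestContactEvents:
    def test_two_events_without_merging(self):
        events = solv.detect_contact_events(_trace([1, 1, 0, 0, 1]), 0.0)
        assert [(e.start_frame, e.end_frame) for e in events] == [(0, 1), (4, 4)]

    def test_gap_merging(self):
        events = solv.detect_contact_events(_trace([1, 1, 0, 0, 1]), 2.0)
        assert len(events) == 1
        assert events[0].merged_gaps == 1
        assert (events[0].start_frame, events[0].end_frame) == (0, 4)

    def test_all_zero_trace_yields_empty_list(self):
        assert solv.detect_contact_events(_trace([0, 0, 0]), 1.0) == []

    def test_matches_run_length_oracle_on_random_traces(self, rng):
        for _ in range(30):
            q = (rng.random(200) < 0.3).astype(int)
            gap = int(rng.integers(0, 4))
            got = solv.detect_contact_events(_trace(q), float(gap))
            want = _brute_force_events(q, gap)
            assert [(e.start_frame, e.end_frame) for e in got] == want

    def test_events_disjoint_and_ordered(self, rng):
        q = (rng.random(500) < 0.4).astype(int)
        events = solv.detect_contact_events(_trace(q), 1.0)
        ends = [-1]
        for ev in events:
            assert ev.start_frame > ends[-1]
            ends.append(ev.end_frame)


class TestAutocorr:
    def test_constant_contact_gives_unity(self):
        acr = solv.contact_autocorr([_trace([5] * 50)], max_lag=20.0)
        np.testing.assert_allclose(acr.c, 1.0)
        assert acr.n_events == 1

    def test_single_frame_event_drops_to_zero(self):
        acr = solv.contact_autocorr([_trace([0, 7, 0, 0, 0, 0])], max_lag=3.0)
        assert acr.c[0] == 1.0
        np.testing.assert_allclose(acr.c[1:], 0.0)

    def test_c_zero_is_one_and_bounded(self, rng):
        q = rng.integers(0, 5, 300)
        acr = solv.contact_autocorr([_trace(q)], max_lag=50.0)
        assert acr.c[0] == pytest.approx(1.0)

    def test_exponential_dwells_give_exponential_decay(self):
        # direct-simulation oracle: survival of exponential dwells
        traces, meta = syn.gen_contact_traces(
            syn.SyntheticSpec(seed=4), k_on=0.01, k_off=0.1,
            n_molecules=200, duration=1500.0, frame_interval=0.5)
        acr = solv.contact_autocorr(traces, max_lag=30.0)
        expect = np.exp(-0.1 * acr.tau)
        assert np.max(np.abs(acr.c - expect)) < 0.03

    def test_event_weighting_biases_low(self):
        # the equal-event-weight variant under-weights long events
        traces, _ = syn.gen_contact_traces(
            syn.SyntheticSpec(seed=4), k_on=0.01, k_off=0.1,
            n_molecules=80, duration=1500.0, frame_interval=0.5)
        pooled = solv.contact_autocorr(traces, max_lag=30.0)
        per_event = solv.contact_autocorr(traces, max_lag=30.0,
                                          weighting="event")
        assert per_event.c[10] < pooled.c[10]

    def test_no_events_rejected(self):
        with pytest.raises(InputError):
            solv.contact_autocorr([_trace([0, 0, 0, 0])], max_lag=2.0)

    def test_max_lag_must_fit_in_trace(self):
        with pytest.raises(InputError):
            solv.contact_autocorr([_trace([1] * 10)], max_lag=20.0)


class TestTripleExp:
    def test_exact_recovery(self):
        tau = np.linspace(0.0, 500.0, 251)
        c = 0.5 * np.exp(-tau) + 0.3 * np.exp(-tau / 10) + 0.2 * np.exp(-tau / 100)
        fit = solv.fit_triple_exp(solv.AutocorrResult(tau=tau, c=c, n_events=1))
        np.testing.assert_allclose(fit.amplitudes, [0.5, 0.3, 0.2], rtol=1e-4)
        np.testing.assert_allclose(fit.time_constants, [1.0, 10.0, 100.0],
                                   rtol=1e-4)
        assert fit.amplitudes.sum() == pytest.approx(1.0)
        assert np.all(np.diff(fit.time_constants) > 0)

    def test_mono_exponential_collapse(self):
        tau = np.linspace(0.0, 100.0, 101)
        c = np.exp(-tau / 20.0)
        fit = solv.fit_triple_exp(solv.AutocorrResult(tau=tau, c=c, n_events=1))
        # whatever the amplitude split, the fitted curve reproduces the data
        np.testing.assert_allclose(fit(tau), c, atol=1e-6)

    def test_noisy_tau_r_within_ten_percent(self, rng):
        tau = np.linspace(0.0, 500.0, 251)
        clean = 0.5 * np.exp(-tau) + 0.3 * np.exp(-tau / 10) + 0.2 * np.exp(-tau / 100)
        truth = solv.residence_time(
            solv.fit_triple_exp(solv.AutocorrResult(tau, clean, 1))).tau_r
        taus = []
        for _ in range(20):
            noisy = clean + rng.normal(0, 0.01, tau.size)
            fit = solv.fit_triple_exp(solv.AutocorrResult(tau, noisy, 1))
            taus.append(solv.residence_time(fit).tau_r)
        assert abs(np.mean(taus) - truth) / truth < 0.10


class TestResidenceTime:
    def test_single_exponential_gives_its_time_constant(self):
        fit = solv.TripleExpFit(amplitudes=np.array([1.0, 0.0, 0.0]),
                                time_constants=np.array([7.0, 8.0, 9.0]),
                                residual_norm=0.0)
        assert solv.residence_time(fit).tau_r == pytest.approx(7.0, rel=1e-9)

    def test_triple_exponential_matches_bisection_oracle(self):
        a = np.array([0.5, 0.3, 0.2])
        ts = np.array([1.0, 10.0, 100.0])
        fit = solv.TripleExpFit(amplitudes=a, time_constants=ts,
                                residual_norm=0.0)
        # manual bisection oracle
        lo, hi = 0.0, 1000.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if float(a @ np.exp(-mid / ts)) > 1.0 / math.e:
                lo = mid
            else:
                hi = mid
        assert solv.residence_time(fit).tau_r == pytest.approx(
            0.5 * (lo + hi), abs=1e-6)

    def test_floored_curve_is_censored(self):
        tau = np.linspace(0.0, 50.0, 26)
        c = 0.5 + 0.5 * np.exp(-tau / 3.0)
        res = solv.residence_time(solv.AutocorrResult(tau, c, 1))
        assert res.censored
        assert res.tau_r == pytest.approx(50.0)

    def test_raw_curve_interpolation(self):
        tau = np.linspace(0.0, 100.0, 101)
        res = solv.residence_time(
            solv.AutocorrResult(tau, np.exp(-tau / 25.0), 1))
        assert res.tau_r == pytest.approx(25.0, abs=0.2)
        assert res.method == "interp"


class TestSolvationDg:
    def test_equal_residence_times_give_zero(self, sim_ctx):
        assert solv.solvation_dg(40.0, 40.0, sim_ctx).dg_solv == 0.0

    def test_lipid_like_ratio(self, sim_ctx):
        # tau ratio 90/40 = 2.25 at 310 K: ~ -0.50 kcal/mol
        res = solv.solvation_dg(90.0, 40.0, sim_ctx)
        assert res.dg_solv == pytest.approx(-sim_ctx.rt * math.log(2.25),
                                            rel=1e-12)
        assert res.dg_solv == pytest.approx(-0.50, abs=0.01)

    def test_antisymmetric_under_swap(self, sim_ctx, rng):
        for _ in range(10):
            a, b = rng.uniform(5.0, 200.0, 2)
            assert solv.solvation_dg(a, b, sim_ctx).dg_solv == pytest.approx(
                -solv.solvation_dg(b, a, sim_ctx).dg_solv, rel=1e-12)

    def test_ensemble_and_mean_tau_forms_identical(self, sim_ctx, rng):
        # the Boltzmann average over per-site free energies collapses to
        # the mean residence time exactly
        for _ in range(50):
            taus = rng.lognormal(mean=3.0, sigma=1.5, size=40)
            bulk = rng.uniform(5.0, 100.0)
            e16 = solv.solvation_dg_ensemble(taus, bulk, sim_ctx)
            e17 = solv.solvation_dg_mean_tau(taus, bulk, sim_ctx)
            assert e16 == pytest.approx(e17, rel=1e-12)

    def test_nonpositive_tau_rejected(self, sim_ctx):
        with pytest.raises(DomainError):
            solv.solvation_dg(0.0, 40.0, sim_ctx)


class TestKineticClosure:
    def test_tau_r_converges_to_inverse_off_rate(self):
        traces, meta = syn.gen_contact_traces(
            syn.SyntheticSpec(seed=1), k_on=0.01, k_off=1.0 / 40.0,
            n_molecules=60, duration=2000.0, frame_interval=0.5)
        assert meta["n_events"] >= 500
        acr = solv.contact_autocorr(traces, max_lag=200.0)
        tau_r = solv.residence_time(solv.fit_triple_exp(acr)).tau_r
        assert abs(tau_r - 40.0) / 40.0 < 0.10

    def test_headgroup_and_tail_counts_sum_to_whole(self, rng):
        # partition invariant: per-frame whole-molecule counts split
        # between headgroup and tail without loss
        whole = rng.integers(0, 30, 400)
        head = np.array([rng.integers(0, w + 1) for w in whole])
        tail = whole - head
        np.testing.assert_array_equal(head + tail, whole)


class TestCoordinateDiagnostics:
    @staticmethod
    def _rigid_copy(coords, rng):
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=rng).as_matrix()
        return coords @ rot.T + rng.uniform(-5, 5, 3)

    def test_static_track_gives_zero_rmsd(self):
        frame = np.random.default_rng(0).normal(size=(6, 3))
        track = solv.CoordinateTrack(np.repeat(frame[None], 5, axis=0), 1.0)
        np.testing.assert_allclose(solv.rmsd_lag([track], [1.0, 2.0]), 0.0,
                                   atol=1e-12)

    def test_rigid_body_motion_is_invisible(self, rng):
        frame = rng.normal(size=(8, 3))
        frames = np.stack([self._rigid_copy(frame, rng) for _ in range(6)])
        track = solv.CoordinateTrack(frames, 1.0)
        np.testing.assert_allclose(solv.rmsd_lag([track], [1.0, 3.0]), 0.0,
                                   atol=1e-10)

    def test_alternating_conformations_match_direct_computation(self, rng):
        from scipy.spatial.transform import Rotation
        conf_a = rng.normal(size=(10, 3))
        conf_b = conf_a + rng.normal(scale=0.5, size=(10, 3))
        frames = np.stack([conf_a, conf_b] * 4)
        track = solv.CoordinateTrack(frames, 1.0)
        # independent oracle: scipy's align_vectors on centered clouds
        ac = conf_a - conf_a.mean(axis=0)
        bc_ = conf_b - conf_b.mean(axis=0)
        _, rssd = Rotation.align_vectors(bc_, ac)
        d = rssd / math.sqrt(10)
        got = solv.rmsd_lag([track], [1.0, 2.0])
        assert got[0] == pytest.approx(d, rel=1e-8)
        assert got[1] == pytest.approx(0.0, abs=1e-10)

    def test_static_track_gives_zero_rmsf(self):
        frame = np.random.default_rng(0).normal(size=(6, 3))
        track = solv.CoordinateTrack(np.repeat(frame[None], 5, axis=0), 1.0)
        np.testing.assert_allclose(solv.rmsf(track), 0.0, atol=1e-12)

    def test_oscillating_atom_rmsf_is_displacement(self):
        # many atoms so the frame superposition absorbs a negligible
        # fraction of the single-atom oscillation
        rng = np.random.default_rng(1)
        base = rng.normal(size=(150, 3)) * 10.0
        frames = np.repeat(base[None], 8, axis=0).copy()
        d = 0.05  # small so the superposition barely shifts the frame
        frames[::2, 0, 0] += d
        frames[1::2, 0, 0] -= d
        vals = solv.rmsf(solv.CoordinateTrack(frames, 1.0))
        assert vals[0] == pytest.approx(d, rel=0.05)

    def test_gaussian_jitter_rmsf(self, rng):
        base = rng.normal(size=(40, 3)) * 20.0
        sigma = 0.1
        frames = base[None] + rng.normal(scale=sigma, size=(400, 40, 3))
        vals = solv.rmsf(solv.CoordinateTrack(frames, 1.0))
        assert np.mean(vals) == pytest.approx(sigma * math.sqrt(3), rel=0.05)

    def test_single_frame_rejected(self):
        with pytest.raises(InputError):
            solv.CoordinateTrack(np.zeros((1, 5, 3)), 1.0)
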