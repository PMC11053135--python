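"""Synthetic-data generator: template contracts, recruitment law, session
determinism and ground-truth consistency."""

import dataclasses

import numpy as np
import pytest

import eesmap as em
from eesmap.errors import ParameterError, ProtocolError


class TestWaveformTemplate:
    def test_slow_template_sample_count_and_p2p(self):
        t = em.waveform_template("slow", 225.0, 10.0, 20000.0)
        assert t.size == 4500
        assert t.max() - t.min() == pytest.approx(10.0, rel=1e-9)

    def test_zero_amplitude_is_all_zero(self):
        assert not em.waveform_template("fast", 20.0, 0.0, 20000.0).any()

    def test_fast_template_is_multiphasic(self):
        t = em.waveform_template("fast", 20.0, 5.0, 20000.0)
        body = t[np.abs(t) > 1e-6 * np.abs(t).max()]
        sign_changes = int((np.diff(np.sign(body)) != 0).sum())
        assert sign_changes >= 2
        assert t.size == 400  # <= 30 ms by default

    @pytest.mark.parametrize("kind", ["fast", "slow"])
    def test_emg_templates_integrate_to_zero(self, kind):
        dur = 20.0 if kind == "fast" else 225.0
        t = em.waveform_template(kind, dur, 1.0, 20000.0)
        assert abs(t.sum()) / np.abs(t).sum() < 0.01

    def test_pressure_template_is_unipolar(self):
        t = em.waveform_template("pressure", 225.0, 3.0, 2000.0)
        assert t.min() >= 0 and t.max() == pytest.approx(3.0, rel=1e-9)

    @pytest.mark.parametrize("dur,fs", [(-1.0, 1000.0), (10.0, 0.0)])
    def test_invalid_parameters_rejected(self, dur, fs):
        with pytest.raises(ParameterError):
            em.waveform_template("fast", dur, 1.0, fs)


class TestRecruitmentGain:
    @pytest.mark.parametrize("current,expected", [(10, 0.0), (40, 10.0), (200, 40.0)])
    def test_piecewise_law(self, current, expected):
        assert em.recruitment_gain(current, 20.0, 0.5, 100.0) == expected

    def test_saturation_below_threshold_rejected(self):
        with pytest.raises(ParameterError):
            em.recruitment_gain(50.0, 100.0, 0.5, 20.0)


class TestGenerateSession:
    def test_same_seed_bitwise_identical(self, compact_setup):
        protocol, sites, channels = compact_setup
        s1, _ = em.generate_session(protocol, sites, channels, seed=7,
                                    sampling_rate=2000.0)
        s2, _ = em.generate_session(protocol, sites, channels, seed=7,
                                    sampling_rate=2000.0)
        for name in s1.channels:
            assert np.array_equal(s1.channels[name], s2.channels[name])
        assert s1.events.equals(s2.events)

    def test_different_seed_differs(self, compact_setup):
        protocol, sites, channels = compact_setup
        s1, _ = em.generate_session(protocol, sites, channels, seed=7,
                                    sampling_rate=2000.0)
        s2, _ = em.generate_session(protocol, sites, channels, seed=8,
                                    sampling_rate=2000.0)
        assert not np.array_equal(s1.channels["Detr"], s2.channels["Detr"])

    def test_adding_a_site_preserves_existing_site_blocks(self, compact_setup):
        """Per-site substreams: an appended site must not perturb earlier ones."""
        protocol, sites, channels = compact_setup
        s1, _ = em.generate_session(protocol, sites[:2], channels, seed=3,
                                    sampling_rate=2000.0)
        s2, _ = em.generate_session(protocol, sites[:3], channels, seed=3,
                                    sampling_rate=2000.0)
        fs = 2000.0
        stop = int(s1.metadata["site_blocks"][1]["stop_s"] * fs)
        for name in s1.channels:
            assert np.array_equal(s1.channels[name][:stop],
                                  s2.channels[name][:stop])

    def test_noisefree_first_peak_at_configured_latency(self, noisefree_session):
        session, truth, _channels = noisefree_session
        fs = session.sampling_rate
        trace = session.channels["Detr"]
        ev = session.events
        sel = ev[(ev.site_id == "T13") & (ev.current_uA == 60.0)]
        for t0 in sel.time_s:
            i0 = int(round(t0 * fs))
            seg = trace[i0 + int(0.005 * fs): i0 + int(0.3 * fs)]  # skip artifact
            # first local maximum of the slow wave
            peak = i0 + int(0.005 * fs) + int(np.argmax(seg))
            lat_ms = (peak - i0) / fs * 1000.0
            assert lat_ms == pytest.approx(38.0, abs=1.5)  # argmax of broad lobe

    def test_zero_gain_channel_is_silent_outside_artifacts(self, compact_setup):
        protocol, sites, _ = compact_setup
        ch = em.ChannelModel("Detr", "slow", 38.0, 225.0, 0.0, 0.0, 600.0, 0.0,
                             latency_jitter_sd_ms=0.0)
        sites = [em.SiteProfile("T13", "rostral", {"Detr": 1.0})]
        session, _ = em.generate_session(protocol, sites, [ch], seed=0,
                                         sampling_rate=2000.0)
        trace = session.channels["Detr"].copy()
        idx = np.round(session.events.time_s.to_numpy() * 2000.0).astype(int)
        trace[idx] = 0.0
        assert not trace.any()

    def test_ground_truth_covers_every_site_channel(self, noisy_session):
        session, truth, channels = noisy_session
        expected = {(s, c.name) for s in session.site_ids for c in channels}
        assert set(truth.entries) == expected
        for (site, _ch), e in truth.entries.items():
            n_site_events = (session.events.site_id == site).sum()
            assert e.pulse_amplitudes.size == n_site_events

    def test_missing_multiplier_rejected(self, compact_setup):
        protocol, _, channels = compact_setup
        bad = [em.SiteProfile("X1", "rostral", {"Detr": 1.0})]
        with pytest.raises(ParameterError):
            em.generate_session(protocol, bad, channels, seed=0)

    def test_negative_gap_is_protocol_error(self, compact_setup):
        protocol, sites, channels = compact_setup
        with pytest.raises(ProtocolError):
            em.generate_session(protocol, sites, channels, seed=0,
                                inter_block_gap_s=-0.5)


@pytest.fixture(scope="module")
def burst_setup(compact_setup):
    protocol, sites, channels = compact_setup
    bp = dataclasses.replace(protocol, frequency_hz=5.0, train_duration_s=6.0)
    channels = [dataclasses.replace(c, tonic_rms=0.02, noise_sd=0.002)
                for c in channels]
    return bp, [sites[0], sites[3]], channels


class TestGenerateBurstSession:
    def test_same_seed_identical(self, burst_setup):
        bp, sites, channels = burst_setup
        s1, _ = em.generate_burst_session(bp, sites, channels, seed=5,
                                          sampling_rate=2000.0)
        s2, _ = em.generate_burst_session(bp, sites, channels, seed=5,
                                          sampling_rate=2000.0)
        assert all(np.array_equal(s1.channels[c], s2.channels[c])
                   for c in s1.channels)

    def test_closed_loop_percent_matches_ground_truth(self, burst_setup):
        bp, sites, channels = burst_setup
        session, truth = em.generate_burst_session(bp, sites, channels, seed=5,
                                                   sampling_rate=2000.0)
        table = em.analyze_burst_session(session)
        for row in table.itertuples():
            expected = truth.expected_percent[(row.site_id, row.channel)]
            assert row.percent == pytest.approx(expected, rel=0.05)

    def test_zero_gain_percent_near_100(self, compact_setup):
        protocol, _, _ = compact_setup
        bp = dataclasses.replace(protocol, frequency_hz=5.0, train_duration_s=6.0)
        ch = em.ChannelModel("EUS", "fast", 10.0, 20.0, 0.0, 0.0, 600.0,
                             0.05, tonic_rms=0.0)
        sites = [em.SiteProfile("L7", "caudal", {"EUS": 1.0})]
        percents = []
        for seed in range(20):
            session, _ = em.generate_burst_session(bp, sites, [ch], seed=seed,
                                                   sampling_rate=2000.0)
            percents.append(em.analyze_burst_session(session).percent.iloc[0])
        assert np.mean(percents) == pytest.approx(100.0, abs=3.0)

    def test_burst_requires_train_duration(self, compact_setup):
        protocol, sites, channels = compact_setup
        with pytest.raises(ProtocolError):
            em.generate_burst_session(protocol, sites, channels, seed=0)


class TestCohort:
    def test_cohort_is_deterministic_and_animals_differ(self, compact_setup):
        protocol, sites, channels = compact_setup
        kw = dict(n_animals=2, seed=9, protocol=protocol, base_sites=sites,
                  channel_models=channels, sampling_rate=2000.0)
        c1 = em.generate_cohort(**kw)
        c2 = em.generate_cohort(**kw)
        assert np.array_equal(c1[0][0].channels["EUS"], c2[0][0].channels["EUS"])
        assert not np.array_equal(c1[0][0].channels["EUS"],
                                  c1[1][0].channels["EUS"])

    def test_variability_perturbs_multipliers_lognormally(self, compact_setup):
        _, sites, _ = compact_setup
        per_animal = em.cohort_site_profiles(sites, 3, seed=1, variability=0.2)
        base = sites[0].multipliers["Detr"]
        drawn = [p[0].multipliers["Detr"] for p in per_animal]
        assert len(set(drawn)) == 3
        assert all(0.3 * base < d < 3 * base for d in drawn)
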