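"""Gait-event detection from vertical GRF and analysis-window arithmetic."""

import numpy as np
import pytest

from gaitpipe.acquisition import EventList
from gaitpipe.events import (AnalysisWindow, WindowError, crop_analog,
                             crop_frames, detect_contacts, manual_window,
                             window_from_contacts, window_from_events)
from gaitpipe.forceplate import GRFSeries

ANALOG_RATE, VIDEO_RATE = 1000.0, 100.0


def _grf_from_fz(fz):
    n = len(fz)
    F = np.zeros((n, 3))
    F[:, 2] = fz
    return GRFSeries(F=F, cop=np.zeros((n, 3)), torque=np.zeros((n, 3)),
                     contact=np.abs(F[:, 2]) >= 20, plate_index=1)


class TestDetectContacts:
    def test_single_burst_boundaries_exact(self):
        """800 N double-hump spanning [1.00 s, 1.60 s) at 1 kHz."""
        t = np.arange(3000) / ANALOG_RATE
        fz = np.zeros(3000)
        inside = (t >= 1.0) & (t < 1.6)
        s = (t[inside] - 1.0) / 0.6
        fz[inside] = 800 * (0.6 + 0.4 * np.sin(np.pi * s))
        contacts = detect_contacts(_grf_from_fz(fz), ANALOG_RATE, VIDEO_RATE,
                                   threshold=20.0)
        assert [c.kind for c in contacts] == ["heel-strike", "toe-off"]
        assert abs(contacts[0].time - 1.0) <= 1.0 / ANALOG_RATE
        assert abs(contacts[1].time - 1.6) <= 1.0 / ANALOG_RATE
        assert contacts[0].frame == 100 and contacts[1].frame == 160

    def test_zero_force_yields_no_events(self):
        assert detect_contacts(_grf_from_fz(np.zeros(2000)), ANALOG_RATE,
                               VIDEO_RATE) == []

    def test_two_contacts_with_flight_phase(self):
        fz = np.zeros(3000)
        fz[500:1100] = 700.0
        fz[1300:1900] = 700.0           # 0.2 s flight between contacts
        contacts = detect_contacts(_grf_from_fz(fz), ANALOG_RATE, VIDEO_RATE)
        assert [c.kind for c in contacts] == ["heel-strike", "toe-off"] * 2
        np.testing.assert_allclose([c.time for c in contacts],
                                   [0.5, 1.1, 1.3, 1.9])

    def test_short_spike_debounced(self):
        fz = np.zeros(2000)
        fz[700:720] = 500.0             # 20 ms < min_contact 50 ms
        assert detect_contacts(_grf_from_fz(fz), ANALOG_RATE, VIDEO_RATE) == []

    def test_detection_recovers_generator_truth(self, zero_noise_session):
        """Every true contact boundary within one analog sample at zero noise."""
        from gaitpipe.forceplate import assemble_wrench, compute_cop_and_torque
        params, truth, acqs = zero_noise_session
        for name, trial in truth.trials.items():
            acq = acqs[name]
            for spec, pt in zip(acq.plates, trial.plates):
                w = assemble_wrench(acq.plate_channels(spec), spec)
                g = compute_cop_and_torque(w, spec.origin * 0.001, 20.0, spec.index)
                contacts = detect_contacts(g, params.analog_rate, params.video_rate)
                assert len(contacts) == 2
                assert abs(contacts[0].time - pt.contact[0]) <= 1.0 / params.analog_rate
                assert abs(contacts[1].time - pt.contact[1]) <= 1.0 / params.analog_rate


class TestWindowFromEvents:
    def _events(self):
        return EventList([("Foot Strike", "Right", 1.0), ("Foot Off", "Right", 1.6)])

    def test_time_to_frame_arithmetic(self):
        w = window_from_events(self._events(), VIDEO_RATE, 240)
        assert (w.start, w.stop, w.source) == (100, 160, "events")
        assert w.nframes == 61

    def test_missing_label_lists_available(self):
        with pytest.raises(WindowError, match="Foot Strike"):
            window_from_events(EventList([("General", "", 1.0)]), VIDEO_RATE, 240)

    def test_stop_before_start_rejected(self):
        ev = EventList([("Foot Off", "Right", 0.5), ("Foot Strike", "Right", 1.0)])
        with pytest.raises(WindowError):
            window_from_events(ev, VIDEO_RATE, 240)

    def test_no_events_suggests_other_modes(self):
        with pytest.raises(WindowError, match="grf-threshold or manual"):
            window_from_events(EventList([]), VIDEO_RATE, 240)


class TestApplyWindow:
    def test_full_trial_window_is_identity(self):
        arr = np.arange(240 * 3.0).reshape(240, 3)
        w = AnalysisWindow(1, 240, "manual")
        np.testing.assert_array_equal(crop_frames(arr, w), arr)

    def test_frame_and_sample_counts(self):
        """Frames 100-160 at ratio 10: 61 video frames, 610 analog samples."""
        w = AnalysisWindow(100, 160, "events")
        video = np.zeros((240, 3))
        analog = np.zeros(2400)
        assert crop_frames(video, w).shape[0] == 61
        assert crop_analog(analog, w, 10).shape[0] == 610

    def test_analog_slice_alignment(self):
        w = AnalysisWindow(100, 160, "events")
        analog = np.arange(2400.0)
        out = crop_analog(analog, w, 10)
        assert out[0] == 990.0 and out[-1] == 1599.0

    def test_manual_window_source_tag_and_bounds(self):
        w = manual_window(50, 80, 240)
        assert w.source == "manual"
        with pytest.raises(WindowError):
            manual_window(50, 300, 240)

    def test_repeated_cropping_is_idempotent(self):
        arr = np.random.default_rng(3).normal(size=(240, 3))
        w = AnalysisWindow(100, 160, "manual")
        once = crop_frames(arr, w)
        again = crop_frames(once, AnalysisWindow(1, once.shape[0], "manual"))
        np.testing.assert_array_equal(once, again)

    def test_window_outside_trial_rejected(self):
        with pytest.raises(WindowError):
            crop_frames(np.zeros((50, 3)), AnalysisWindow(10, 60, "manual"))


def test_window_from_contacts_spans_first_strike_to_last_off():
    from gaitpipe.events import ContactEvent
    contacts = [ContactEvent("heel-strike", 1, 0.5, 50),
                ContactEvent("toe-off", 1, 1.1, 110),
                ContactEvent("heel-strike", 2, 1.0, 100),
                ContactEvent("toe-off", 2, 1.6, 160)]
    w = window_from_contacts(contacts, 240)
    assert (w.start, w.stop, w.source) == (50, 160, "grf-threshold")
    with pytest.raises(WindowError):
        window_from_contacts([], 240)
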