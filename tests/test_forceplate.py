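"""Wrench assembly per plate type and the CoP / free-torque inversion."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpipe.forceplate import (PlateConfigError, PlateWrench, assemble_wrench,
                                 compute_cop_and_torque, zero_off_contact)
from gaitpipe.synthetic import channels_from_wrench, make_plate_specs


def _spec(ptype):
    s = make_plate_specs((2,))[0]
    kwargs = {"type": ptype}
    if ptype == 3:
        kwargs["sensor_offsets"] = (0.12, 0.20)
        kwargs["channel_indices"] = list(range(1, 9))
    if ptype == 4:
        kwargs["cal_matrix"] = np.eye(6)
    return dataclasses.replace(s, **kwargs)


class TestType3Combination:
    """Hand-evaluated 8-channel piezoelectric combinations, a=0.12, b=0.20 m."""

    def test_symmetric_vertical_load(self):
        ch = np.array([[0, 0, 0, 0, 100.0, 100.0, 100.0, 100.0]])
        w = assemble_wrench(ch, _spec(3))
        np.testing.assert_allclose(w.F[0], [0, 0, 400.0])
        np.testing.assert_allclose(w.M[0], [0, 0, 0], atol=1e-12)

    def test_asymmetric_vertical_load(self):
        ch = np.array([[0, 0, 0, 0, 200.0, 100.0, 100.0, 100.0]])
        w = assemble_wrench(ch, _spec(3))
        np.testing.assert_allclose(w.F[0], [0, 0, 500.0])
        # Mx = b*(fz1+fz2-fz3-fz4) = 0.20*100; My = a*(-fz1+fz2+fz3-fz4) = 0.12*(-100)
        np.testing.assert_allclose(w.M[0], [20.0, -12.0, 0.0], atol=1e-12)

    def test_shear_channels_feed_fx_fy_mz(self):
        ch = np.array([[10.0, 30.0, 5.0, -5.0, 0, 0, 0, 0]])
        w = assemble_wrench(ch, _spec(3))
        np.testing.assert_allclose(w.F[0], [40.0, 0.0, 0.0])
        # Mz = b*(-fx12+fx34) + a*(fy14-fy23) = 0.20*20 + 0.12*10
        np.testing.assert_allclose(w.M[0], [0.0, 0.0, 5.2], atol=1e-12)


def test_type4_identity_matches_type2_bit_for_bit(rng):
    channels = rng.normal(scale=200.0, size=(100, 6))
    w2 = assemble_wrench(channels, _spec(2))
    w4 = assemble_wrench(channels, _spec(4))
    assert np.array_equal(w2.F, w4.F)
    assert np.array_equal(w2.M, w4.M)


def test_type4_calibration_inverts_generator_channels(rng):
    spec = dataclasses.replace(_spec(4), cal_matrix=np.eye(6) + 0.05 * rng.normal(size=(6, 6)))
    F = rng.normal(scale=300.0, size=(50, 3))
    M = rng.normal(scale=40.0, size=(50, 3))
    w = assemble_wrench(channels_from_wrench(spec, F, M), spec)
    np.testing.assert_allclose(w.F, F, atol=1e-9)
    np.testing.assert_allclose(w.M, M, atol=1e-9)


def test_type1_cop_passthrough_is_recovered(rng):
    """Device-reported CoP feeds moment synthesis; inversion returns it."""
    spec = _spec(1)
    n = 40
    F = np.column_stack([rng.normal(size=n) * 30, rng.normal(size=n) * 30,
                         400 + 100 * rng.random(n)])
    cop = np.column_stack([rng.uniform(-0.2, 0.2, n), rng.uniform(-0.15, 0.15, n),
                           np.zeros(n)])
    tz = rng.normal(size=n)
    w = assemble_wrench(channels_from_wrench(spec, F, None, cop_m=cop, tz=tz), spec)
    g = compute_cop_and_torque(w, spec.origin * 0.001, 20.0)
    assert np.all(g.contact)
    np.testing.assert_allclose(g.cop, cop, atol=1e-9)
    np.testing.assert_allclose(g.tz, tz, atol=1e-9)


def test_channel_count_mismatch_raises():
    with pytest.raises(PlateConfigError, match="expects 8 channels"):
        assemble_wrench(np.zeros((5, 6)), _spec(3))
    with pytest.raises(PlateConfigError, match="expects 6 channels"):
        assemble_wrench(np.zeros((5, 8)), _spec(2))


class TestCopInversion:
    def test_known_wrench_recovered(self):
        """F=(0,0,-500) N at p=(0.10,0.05,0), o=(0,0,-0.04): M=(-25,50,0)."""
        F = np.array([[0.0, 0.0, -500.0]])
        o = np.array([0.0, 0.0, -0.04])
        p = np.array([[0.10, 0.05, 0.0]])
        M = np.cross(p - o, F)
        np.testing.assert_allclose(M[0], [-25.0, 50.0, 0.0])
        g = compute_cop_and_torque(PlateWrench(F=F, M=M), o, 20.0)
        np.testing.assert_allclose(g.cop[0], p[0], atol=1e-12)
        np.testing.assert_allclose(g.tz[0], 0.0, atol=1e-12)

    def test_force_through_origin(self):
        F = np.array([[0.0, 0.0, 800.0]])
        g = compute_cop_and_torque(PlateWrench(F=F, M=np.zeros((1, 3))),
                                   np.zeros(3), 20.0)
        np.testing.assert_allclose(g.cop[0], 0.0, atol=1e-15)
        np.testing.assert_allclose(g.tz[0], 0.0, atol=1e-15)

    def test_zero_force_means_no_contact(self):
        F = np.zeros((30, 3))
        g = compute_cop_and_torque(PlateWrench(F=F, M=np.zeros((30, 3))),
                                   np.zeros(3), 10.0)
        assert not np.any(g.contact)
        np.testing.assert_array_equal(g.cop, 0.0)   # surface-centre placeholder

    def test_off_contact_export_policy_zeroes_force(self):
        F = np.array([[0, 0, 5.0], [0, 0, 500.0]])
        g = compute_cop_and_torque(PlateWrench(F=F, M=np.zeros((2, 3))),
                                   np.zeros(3), 20.0)
        out = zero_off_contact(g)
        assert not out.contact[0] and out.contact[1]
        np.testing.assert_array_equal(out.F[0], 0.0)
        np.testing.assert_array_equal(out.F[1], [0, 0, 500.0])


@settings(max_examples=60, deadline=None)
@given(
    ptype=st.sampled_from([1, 2, 3, 4]),
    px=st.floats(-0.25, 0.25), py=st.floats(-0.18, 0.18),
    fx=st.floats(-200, 200), fy=st.floats(-200, 200),
    fz=st.floats(30, 1200), fz_sign=st.sampled_from([1.0, -1.0]),
    tz=st.floats(-15, 15),
)
def test_inverse_oracle_recovers_cop_and_torque(ptype, px, py, fx, fy, fz,
                                                fz_sign, tz):
    """For any wrench with |Fz| above threshold, building the forward-model
    moments and running the full channel->assembly->inversion path recovers
    the applied point and free torque to 1e-9."""
    spec = _spec(ptype)
    o = spec.origin * 0.001
    p = np.array([[px, py, 0.0]])
    F = np.array([[fx, fy, fz_sign * fz]])
    tz_arr = np.array([tz])
    d = p - o
    M = np.cross(d, F)
    M[:, 2] += tz
    ch = channels_from_wrench(spec, F, M, cop_m=p, tz=tz_arr)
    g = compute_cop_and_torque(assemble_wrench(ch, spec), o, 20.0)
    assert g.contact[0]
    np.testing.assert_allclose(g.cop[0], p[0], rtol=1e-9, atol=1e-9)
    np.testing.assert_allclose(g.tz[0], tz, rtol=1e-9, atol=1e-9)
    assert g.cop[0, 2] == 0.0
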