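import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from shankgait import (
    ImuRecording,
    Quaternion,
    quat_multiply,
    quat_rotate,
    read_imu_csv,
    write_imu_csv,
)


def _unit_quat(components):
    arr = np.asarray(components, dtype=float)
    return Quaternion.from_array(arr / np.linalg.norm(arr))


quat_components = st.lists(
    st.floats(min_value=-1.0, max_value=1.0), min_size=4, max_size=4
).filter(lambda c: np.linalg.norm(c) > 1e-2)

vectors = st.lists(
    st.floats(min_value=-10.0, max_value=10.0), min_size=3, max_size=3
)


class TestQuaternion:
    def test_identity_element(self):
        q = _unit_quat([0.3, -0.5, 0.7, 0.1])
        out = quat_multiply(Quaternion.identity(), q)
        np.testing.assert_allclose(out.as_array(), q.as_array(), atol=1e-15)

    def test_i_squared_is_minus_one(self):
        i = Quaternion.from_array([0.0, 1.0, 0.0, 0.0])
        out = quat_multiply(i, i)
        np.testing.assert_allclose(out.as_array(), [-1.0, 0.0, 0.0, 0.0], atol=1e-15)

    def test_product_norm_multiplicative(self, rng):
        # oracle: 4x4 matrix form of the Hamilton product
        for _ in range(200):
            p = _unit_quat(rng.normal(size=4))
            q = _unit_quat(rng.normal(size=4))
            pq = quat_multiply(p, q)
            assert abs(pq.norm - 1.0) < 1e-12
            w, x, y, z = p.as_array()
            m = np.array(
                [
                    [w, -x, -y, -z],
                    [x, w, -z, y],
                    [y, z, w, -x],
                    [z, -y, x, w],
                ]
            )
            np.testing.assert_allclose(pq.as_array(), m @ q.as_array(), atol=1e-12)

    @given(quat_components, quat_components, quat_components)
    @settings(max_examples=200)
    def test_associativity(self, a, b, c):
        p, q, r = _unit_quat(a), _unit_quat(b), _unit_quat(c)
        lhs = quat_multiply(quat_multiply(p, q), r)
        rhs = quat_multiply(p, quat_multiply(q, r))
        np.testing.assert_allclose(lhs.as_array(), rhs.as_array(), atol=1e-12)

    def test_rotate_identity(self):
        np.testing.assert_allclose(
            quat_rotate(Quaternion.identity(), [1.0, 2.0, 3.0]), [1.0, 2.0, 3.0]
        )

    def test_rotate_known_90deg_about_z(self):
        q = Quaternion.from_axis_angle([0, 0, 1], math.pi / 2)
        np.testing.assert_allclose(quat_rotate(q, [1, 0, 0]), [0, 1, 0], atol=1e-12)

    def test_rotate_matches_rotation_matrix_oracle(self, rng):
        # independent oracle: scipy Rotation (x, y, z, w component order)
        for _ in range(1000):
            q = _unit_quat(rng.normal(size=4))
            u = rng.normal(size=3)
            w, x, y, z = q.as_array()
            expected = Rotation.from_quat([x, y, z, w]).as_matrix() @ u
            np.testing.assert_allclose(quat_rotate(q, u), expected, atol=1e-9)

    def test_rotate_norm_preserving_and_linear(self, rng):
        for _ in range(1000):
            q = _unit_quat(rng.normal(size=4))
            u, v = rng.normal(size=3), rng.normal(size=3)
            ru = quat_rotate(q, u)
            assert abs(np.linalg.norm(ru) - np.linalg.norm(u)) < 1e-9
            lhs = quat_rotate(q, 2.5 * u - 0.7 * v)
            rhs = 2.5 * ru - 0.7 * quat_rotate(q, v)
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_rotate_rejects_non_unit(self):
        q = Quaternion(2.0, np.zeros(3))
        with pytest.raises(ValueError):
            quat_rotate(q, [1.0, 0.0, 0.0])

    def test_canonical_flips_negative_scalar(self):
        q = Quaternion.from_array([-0.5, 0.5, 0.5, 0.5])
        c = q.canonical()
        assert c.w >= 0
        np.testing.assert_allclose(c.as_array(), [0.5, -0.5, -0.5, -0.5])

    @given(quat_components, vectors)
    @settings(max_examples=200)
    def test_rotation_matrix_agrees_with_sandwich(self, comps, u):
        q = _unit_quat(comps)
        np.testing.assert_allclose(
            q.to_rotation_matrix() @ np.asarray(u), quat_rotate(q, u), atol=1e-9
        )


class TestImuCsv:
    def _write(self, path, lines):
        path.write_text("\n".join(lines) + "\n")

    def test_basic_parse_100hz(self, tmp_path):
        p = tmp_path / "rec.csv"
        self._write(
            p,
            [
                "t,ax,ay,az,gx,gy,gz",
                "0.00,9.81,0,0,0,0,10",
                "0.01,9.81,0,0,0,0,10",
                "0.02,9.81,0,0,0,0,10",
            ],
        )
        rec = read_imu_csv(p)
        assert len(rec) == 3
        assert rec.dt == pytest.approx(0.01)

    def test_deg_per_s_conversion(self, tmp_path):
        p = tmp_path / "rec.csv"
        self._write(
            p,
            ["t,ax,ay,az,gx,gy,gz", "0.00,9.81,0,0,0,0,90", "0.01,9.81,0,0,0,0,90"],
        )
        rec = read_imu_csv(p, gyro_units="deg")
        assert rec.w_s[0, 2] == pytest.approx(1.5707963, abs=1e-6)
        rec_rad = read_imu_csv(p, gyro_units="rad")
        assert rec_rad.w_s[0, 2] == pytest.approx(90.0)

    def test_duplicated_timestamp_is_named(self, tmp_path):
        p = tmp_path / "rec.csv"
        self._write(
            p,
            [
                "t,ax,ay,az,gx,gy,gz",
                "0.00,9.81,0,0,0,0,0",
                "0.01,9.81,0,0,0,0,0",
                "0.01,9.81,0,0,0,0,0",
                "0.02,9.81,0,0,0,0,0",
            ],
        )
        with pytest.raises(ValueError, match="row 2"):
            read_imu_csv(p)

    def test_nan_row_rejected(self, tmp_path):
        p = tmp_path / "rec.csv"
        self._write(
            p,
            ["t,ax,ay,az,gx,gy,gz", "0.00,9.81,0,0,0,0,0", "0.01,,0,0,0,0,0"],
        )
        with pytest.raises(ValueError, match="row 1"):
            read_imu_csv(p)

    def test_roundtrip(self, tmp_path, rng):
        n = 50
        rec = ImuRecording(
            t=np.arange(n) * 0.01,
            a_s=rng.normal(size=(n, 3)),
            w_s=rng.normal(size=(n, 3)),
            dt=0.01,
            side="right",
        )
        p = tmp_path / "out.csv"
        write_imu_csv(rec, p, gyro_units="rad")
        back = read_imu_csv(p, gyro_units="rad", side="right")
        np.testing.assert_allclose(back.a_s, rec.a_s, atol=1e-8)
        np.testing.assert_allclose(back.w_s, rec.w_s, atol=1e-8)


class TestImuRecordingInvariants:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ImuRecording(
                t=np.arange(5) * 0.01,
                a_s=np.zeros((4, 3)),
                w_s=np.zeros((5, 3)),
                dt=0.01,
            )

    def test_nonuniform_time_rejected(self):
        t = np.array([0.0, 0.01, 0.025, 0.03])
        with pytest.raises(ValueError, match="t\\[1\\]"):
            ImuRecording(t=t, a_s=np.zeros((4, 3)), w_s=np.zeros((4, 3)), dt=0.01)
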