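import math

import numpy as np
import pytest
import scipy.linalg

from stereodrr.coords import IEC, IEC_TO_HFS_MATRIX, vec3
from stereodrr.errors import DecompositionError, GeometryError
from stereodrr.projective import (DecomposedGeometry, DetectorModel,
                                  RendererMatrix, calibration_matrix,
                                  compose_renderer_matrix,
                                  decompose_renderer_matrix, detector_scaling,
                                  drr_origin, localization, ndc_scaling,
                                  rotation_matrix_homogeneous, rq_decompose,
                                  translation_matrix)
from stereodrr.stereo_geometry import ImagerFrame, imager_frame

from conftest import random_detector, random_room


def simple_frame():
    """Camera on -Z axis looking up: the hand-checkable configuration."""
    return ImagerFrame(imager=1, t=vec3(0, 0, -1000, IEC),
                       d=vec3(0, 0, 1, IEC), c=vec3(0, 0, 500, IEC),
                       p_x=vec3(1, 0, 0, IEC), p_y=vec3(0, 1, 0, IEC))


SIMPLE_DET = DetectorModel(sx=0.390625, sy=0.390625, cx=-256.0, cy=-256.0,
                           width=512, height=512)


class TestElementaryOperators:
    def test_translation(self):
        np.testing.assert_array_equal(translation_matrix(vec3(0, 0, 0, IEC)),
                                      np.eye(4))
        T = translation_matrix(vec3(0, 0, -1000, IEC))
        np.testing.assert_allclose(T[:, 3], [0, 0, 1000, 1])
        np.testing.assert_allclose(T @ [0, 0, -1000, 1], [0, 0, 0, 1])

    def test_rotation_homogeneous(self):
        f = simple_frame()
        np.testing.assert_array_equal(
            rotation_matrix_homogeneous(f.p_x, f.p_y, f.d), np.eye(4))
        # camera looks along +z after rotation, any valid triad
        p_x = vec3(-1, -1, 0, IEC).unit()
        p_y = vec3(0, 0, -1, IEC)
        d = vec3(1, -1, 0, IEC).unit()
        R = rotation_matrix_homogeneous(p_x, p_y, d)
        np.testing.assert_allclose(R[:3, :3],
                                   np.stack([p_x.v, p_y.v, d.v]), atol=1e-15)
        np.testing.assert_allclose(R @ np.append(d.v, 0.0), [0, 0, 1, 0],
                                   atol=1e-12)
        with pytest.raises(GeometryError):
            rotation_matrix_homogeneous(p_x, p_x, d)

    def test_calibration_is_pinhole(self):
        P = calibration_matrix(2.0)
        v = P @ [1, 1, 2, 1]
        np.testing.assert_allclose(v / v[3], [1, 1, 2, 1])
        np.testing.assert_array_equal(P[3], [0, 0, 1, 0])
        with pytest.raises(GeometryError):
            calibration_matrix(0.0)

    def test_detector_scaling_entries(self):
        S = detector_scaling(DetectorModel(sx=0.390625, sy=0.390625,
                                           cx=10, cy=-3))
        assert S[0, 0] == pytest.approx(2.56)
        assert S[0, 3] == 10 and S[1, 3] == -3
        np.testing.assert_array_equal(S[2], [0, 0, 1, 0])
        np.testing.assert_array_equal(S[3], [0, 0, 0, 1])

    def test_unbinned_detector_halves_spacing(self):
        assert DetectorModel.standard(binning=2).sx == pytest.approx(0.390625)
        assert DetectorModel.standard(binning=1).sx == pytest.approx(0.1953125)

    def test_ndc_maps_pixel_range_to_unit_square(self):
        S = ndc_scaling(512, 512, 1500.0)
        center = S @ [256, 256, 1500, 1]
        np.testing.assert_allclose(center[:2], [0, 0], atol=1e-15)
        corner = S @ [0, 0, 1500, 1]
        np.testing.assert_allclose(corner[:2], [-1, -1])


def test_ndc_detector_calibration_closed_form(rng):
    """S_NDC . S_det . P collapses to the printed closed form entrywise."""
    for _ in range(200):
        W, H = rng.integers(64, 1024, size=2)
        sid = rng.uniform(500, 3000)
        sx, sy = rng.uniform(0.05, 2.0, size=2)
        cx, cy = rng.uniform(-500, 500, size=2)
        det = DetectorModel(sx=sx, sy=sy, cx=cx, cy=cy, width=int(W),
                            height=int(H))
        product = ndc_scaling(int(W), int(H), sid) @ detector_scaling(det) \
            @ calibration_matrix(sid)
        expected = np.array([
            [2 * sid / (W * sx), 0, 2 * cx / W - 1, 0],
            [0, 2 * sid / (H * sy), 2 * cy / H - 1, 0],
            [0, 0, 1, 0],
            [0, 0, 1, 0],
        ])
        np.testing.assert_allclose(product, expected, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(product[2], product[3], atol=1e-15)


class TestCompose:
    def test_simple_frame_matrix(self):
        M = compose_renderer_matrix(simple_frame(), SIMPLE_DET)
        expected = np.array([
            [3840.0, 0.0, -256.0, -256000.0],
            [0.0, 3840.0, -256.0, -256000.0],
            [0.0, 0.0, 1.0, 1000.0],
        ])
        np.testing.assert_allclose(M.m, expected, atol=1e-9)

    def test_normalized_form_relates_to_denormalized(self):
        # folding S_NDC into the stored form: rows 1-2 are rescaled and
        # shifted by the homogeneous row, the homogeneous row is unchanged
        f = simple_frame()
        Mn = compose_renderer_matrix(f, SIMPLE_DET, normalized=True)
        Md = compose_renderer_matrix(f, SIMPLE_DET, normalized=False)
        W, H = SIMPLE_DET.width, SIMPLE_DET.height
        S3 = np.array([[2.0 / W, 0.0, -1.0], [0.0, 2.0 / H, -1.0],
                       [0.0, 0.0, 1.0]])
        np.testing.assert_allclose(Mn.m, S3 @ Md.m, atol=1e-9)

    def test_wc_condition_holds(self, rng):
        for _ in range(10):
            room = random_room(rng)
            M = compose_renderer_matrix(imager_frame(room, 1),
                                        random_detector(rng))
            assert M.m[2] @ [0, 0, 0, 1] > 0


class TestLocalization:
    def test_simple_frame(self):
        L = localization(simple_frame())
        np.testing.assert_allclose(L[:, 3], [0, 0, 1000, 1])
        np.testing.assert_allclose(L @ [0, 0, -1000, 1], [0, 0, 0, 1])

    def test_fourth_column_block_product(self):
        f = simple_frame()
        L = localization(f)
        K = np.array([[3840.0, 0, -256.0], [0, 3840.0, -256.0], [0, 0, 1.0]])
        M = compose_renderer_matrix(f, SIMPLE_DET)
        np.testing.assert_allclose(M.m[:, 3], K @ L[:3, 3], atol=1e-9)


class TestRQDecompose:
    def test_upper_triangular_fixed_point(self):
        A = np.array([[2.0, 1.0, 3.0], [0.0, 4.0, -1.0], [0.0, 0.0, 5.0]])
        R, Q = rq_decompose(A)
        np.testing.assert_allclose(R, A, atol=1e-12)
        np.testing.assert_allclose(Q, np.eye(3), atol=1e-12)

    def test_construct_then_decompose(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(50):
            R0 = np.triu(rng.normal(size=(3, 3)))
            np.fill_diagonal(R0, rng.uniform(0.5, 5.0, size=3))
            Q0 = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            R, Q = rq_decompose(R0 @ Q0)
            np.testing.assert_allclose(R, R0, atol=1e-9)
            np.testing.assert_allclose(Q, Q0, atol=1e-9)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(25):
            A = rng.normal(size=(3, 3))
            if abs(np.linalg.det(A)) < 1e-3:
                continue
            R, Q = rq_decompose(A)
            Rs, Qs = scipy.linalg.rq(A)
            # bring scipy's factors to the positive-diagonal convention
            s = np.sign(np.diag(Rs))
            Rs, Qs = Rs * s[np.newaxis, :], Qs * s[:, np.newaxis]
            np.testing.assert_allclose(R, Rs, atol=1e-10)
            np.testing.assert_allclose(Q, Qs, atol=1e-10)

    def test_sign_fix_preserves_product(self, rng):
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            if abs(np.linalg.det(A)) < 1e-3:
                continue
            R, Q = rq_decompose(A)
            assert np.all(np.diag(R) > 0)
            np.testing.assert_allclose(R @ Q, A,
                                       atol=1e-10 * np.linalg.norm(A))
            np.testing.assert_allclose(Q @ Q.T, np.eye(3), atol=1e-10)
            assert abs(abs(np.linalg.det(Q)) - 1.0) < 1e-10

    def test_singular_matrix_rejected(self):
        with pytest.raises(DecompositionError):
            rq_decompose(np.ones((3, 3)))


class TestDecompose:
    def test_simple_matrix_readout(self):
        M = np.array([
            [3840.0, 0.0, -256.0, -256000.0],
            [0.0, 3840.0, -256.0, -256000.0],
            [0.0, 0.0, 1.0, 1000.0],
        ])
        g = decompose_renderer_matrix(M, 0.390625, 0.390625)
        assert g.sid == pytest.approx(1500.0)  # 3840 * 0.390625
        assert g.cx == pytest.approx(-256.0)
        assert g.cy == pytest.approx(-256.0)
        # focal point (0,0,-1000) IEC -> (0, 1000, 0) HFS
        np.testing.assert_allclose(g.focal_point, [0, 1000, 0], atol=1e-9)
        np.testing.assert_allclose(g.direction, IEC_TO_HFS_MATRIX, atol=1e-12)
        assert g.det_q == 1.0

    def test_projective_scale_invariance(self):
        M = compose_renderer_matrix(simple_frame(), SIMPLE_DET)
        g0 = decompose_renderer_matrix(M, SIMPLE_DET.sx, SIMPLE_DET.sy)
        g1 = decompose_renderer_matrix(RendererMatrix(M.m * -2.5),
                                       SIMPLE_DET.sx, SIMPLE_DET.sy)
        assert g1.sid == pytest.approx(g0.sid)
        np.testing.assert_allclose(g1.focal_point, g0.focal_point, atol=1e-9)
        np.testing.assert_allclose(g1.direction, g0.direction, atol=1e-12)
        np.testing.assert_allclose(g1.drr_origin, g0.drr_origin, atol=1e-9)

    def test_pdet_structure_after_normalization(self, rng):
        room = random_room(rng)
        det = random_detector(rng)
        M = compose_renderer_matrix(imager_frame(room, 2), det)
        Pdet, _ = rq_decompose(M.m[:, :3])
        K = Pdet / Pdet[2, 2]
        assert abs(K[1, 0]) < 1e-10
        assert abs(K[2, 0]) < 1e-10 and abs(K[2, 1]) < 1e-10
        assert K[2, 2] == pytest.approx(1.0)

    def test_roundtrip_recovers_frame(self, rng):
        for _ in range(50):
            room = random_room(rng)
            det = random_detector(rng)
            imager = int(rng.integers(1, 3))
            frame = imager_frame(room, imager)
            M = compose_renderer_matrix(frame, det)
            g = decompose_renderer_matrix(M, det.sx, det.sy)
            assert g.sid == pytest.approx(room.sid, rel=1e-8)
            assert g.cx == pytest.approx(det.cx, rel=1e-8, abs=1e-8)
            assert g.cy == pytest.approx(det.cy, rel=1e-8, abs=1e-8)
            np.testing.assert_allclose(g.focal_point,
                                       IEC_TO_HFS_MATRIX @ frame.t.v,
                                       rtol=1e-8, atol=1e-6)
            D_expect = IEC_TO_HFS_MATRIX @ np.column_stack(
                [frame.p_x.v, frame.p_y.v, frame.d.v])
            np.testing.assert_allclose(g.direction, D_expect, atol=1e-8)

    def test_rank_deficient_rejected(self):
        M = np.zeros((3, 4))
        M[0, 0] = M[1, 1] = 1.0
        with pytest.raises(DecompositionError):
            decompose_renderer_matrix(M, 1.0, 1.0)


class TestDrrOrigin:
    def test_corner_offset_example(self):
        sigma = drr_origin(np.array([0.0, 0.0, -1000.0]), np.eye(3),
                           cx=-256.0, cy=-256.0, sx=0.390625, sy=0.390625,
                           sid=1500.0)
        np.testing.assert_allclose(sigma, [100.0, 100.0, 500.0], atol=1e-12)

    def test_zero_shift_gives_panel_center_ray(self):
        D = IEC_TO_HFS_MATRIX
        t = np.array([5.0, -3.0, 2.0])
        sigma = drr_origin(t, D, 0.0, 0.0, 0.4, 0.4, 1500.0)
        np.testing.assert_allclose(sigma, t + 1500.0 * D[:, 2], atol=1e-12)

    def test_beam_component_is_sid(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(20):
            D = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            t = rng.normal(scale=500, size=3)
            sid = rng.uniform(800, 3000)
            sigma = drr_origin(t, D, rng.uniform(-300, 300),
                               rng.uniform(-300, 300), 0.4, 0.4, sid)
            assert (sigma - t) @ D[:, 2] == pytest.approx(sid)


def test_first_principles_geometry_matches_decomposition(rng):
    room = random_room(rng)
    det = DetectorModel.standard()
    for imager in (1, 2):
        frame = imager_frame(room, imager)
        g_fp = DecomposedGeometry.from_imager_frame(frame, det)
        M = compose_renderer_matrix(frame, det)
        g = decompose_renderer_matrix(M, det.sx, det.sy)
        np.testing.assert_allclose(g_fp.drr_origin, g.drr_origin, atol=1e-6)
        np.testing.assert_allclose(g_fp.direction, g.direction, atol=1e-9)
        np.testing.assert_allclose(g_fp.focal_point, g.focal_point, atol=1e-6)
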