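import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fetalplan.errors import DegenerateLandmarkError, MissingLandmarkError
from fetalplan.imaging_core import (
    BoundingBox,
    LabelMap,
    crop_labels_to_box,
    voxel_to_patient,
)
from fetalplan.landmarks import (
    LandmarkSet,
    detect_landmarks,
    landmark_com,
    tubular_keypoints,
)
from fetalplan.localization import OracleBackend, extract_body_mask, thorax_bounding_box

from conftest import make_labels


def line_labels(n=11, affine=None):
    arr = np.zeros((3, 3, n), dtype=np.uint16)
    arr[0, 0, :] = 1
    lm = make_labels(arr, name="S")
    if affine is not None:
        lm = LabelMap(arr, affine, {"S": 1})
    return lm


class TestLandmarkCom:
    def test_single_voxel(self):
        arr = np.zeros((7, 7, 7), dtype=np.uint16)
        arr[3, 3, 3] = 1
        assert np.allclose(landmark_com(make_labels(arr), "S"), (3, 3, 3))

    def test_symmetric_cube(self):
        arr = np.zeros((11, 11, 11), dtype=np.uint16)
        arr[4:7, 4:7, 4:7] = 1
        assert np.allclose(landmark_com(make_labels(arr), "S"), (5, 5, 5))

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        arr = (rng.random((9, 9, 9)) > 0.7).astype(np.uint16)
        lm = make_labels(arr, spacing=1.7)
        com = landmark_com(lm, "S")
        brute = np.mean(
            [voxel_to_patient(v, lm) for v in np.argwhere(arr)], axis=0
        )
        assert np.allclose(com, brute, atol=1e-12)

    def test_absent_label_raises_with_name(self):
        arr = np.zeros((5, 5, 5), dtype=np.uint16)
        with pytest.raises(MissingLandmarkError) as exc:
            landmark_com(make_labels(arr), "S")
        assert exc.value.structure == "S"


class TestTubularKeypoints:
    def test_straight_line(self):
        start, mid, end = tubular_keypoints(line_labels(), "S")
        assert np.allclose(start, (0, 0, 0), atol=1e-9)
        assert np.allclose(mid, (0, 0, 5), atol=1e-9)
        assert np.allclose(end, (0, 0, 10), atol=1e-9)

    def test_rotated_line_keypoints_rotate(self):
        R = Rotation.from_euler("x", 45, degrees=True).as_matrix()
        aff = np.eye(4)
        aff[:3, :3] = R
        start, mid, end = tubular_keypoints(line_labels(affine=aff), "S")
        pts = sorted([start, mid, end], key=lambda p: p[2])
        expect = [R @ np.array([0, 0, z], float) for z in (0, 5, 10)]
        for got, want in zip(pts, expect):
            assert np.linalg.norm(got - want) < 1e-6

    def test_isotropic_blob_rejected(self):
        arr = np.zeros((9, 9, 9), dtype=np.uint16)
        arr[3:6, 3:6, 3:6] = 1
        with pytest.raises(DegenerateLandmarkError):
            tubular_keypoints(make_labels(arr), "S")

    def test_too_few_voxels_rejected(self):
        arr = np.zeros((5, 5, 5), dtype=np.uint16)
        arr[0, 0, 0] = 1
        arr[0, 0, 1] = 1
        with pytest.raises(DegenerateLandmarkError):
            tubular_keypoints(make_labels(arr), "S")

    def test_mid_projection_between_endpoints(self, default_phantom):
        _, _, _, lm, _ = default_phantom
        for name in ("UV", "DAo", "spine"):
            start, mid, end = tubular_keypoints(lm, name)
            axis = (end - start) / np.linalg.norm(end - start)
            p = (mid - start) @ axis
            assert 0.0 <= p <= np.linalg.norm(end - start)


class TestDetectLandmarks:
    def test_oracle_keypoints_within_2mm_of_truth(self, default_phantom):
        _, vol, body, lm, gt = default_phantom
        box = thorax_bounding_box(extract_body_mask(vol, OracleBackend(body)))
        found = detect_landmarks(vol, box, OracleBackend(lm))
        for name in ("UV", "DAo", "spine"):
            for key in ("start", "mid", "end"):
                d = np.linalg.norm(found.keypoints[name][key] - gt.keypoints[name][key])
                assert d < 2.0, (name, key, d)

    def test_cropped_equals_uncropped_patient_frame(self, default_phantom):
        _, vol, body, lm, _ = default_phantom
        backend = OracleBackend(lm)
        box = thorax_bounding_box(extract_body_mask(vol, OracleBackend(body)))
        full = detect_landmarks(vol, BoundingBox.full(vol.shape), backend)
        cropped = detect_landmarks(vol, box, backend)
        for name in full.com:
            assert np.allclose(full.com[name], cropped.com[name], atol=1e-6)

    def test_backend_omitting_dao_yields_partial_set(self, default_phantom):
        _, vol, body, lm, _ = default_phantom

        def no_dao(volume):
            out = OracleBackend(lm)(volume)
            labels = out.labels.copy()
            labels[labels == out.code("DAo")] = 0
            return LabelMap(labels, out.affine, out.label_codes)

        box = thorax_bounding_box(extract_body_mask(vol, OracleBackend(body)))
        found = detect_landmarks(vol, box, no_dao)
        assert not found.present("DAo")
        assert found.present("UV") and found.present("spine")

    def test_json_round_trip(self, default_phantom):
        _, vol, body, lm, _ = default_phantom
        box = thorax_bounding_box(extract_body_mask(vol, OracleBackend(body)))
        found = detect_landmarks(vol, box, OracleBackend(lm))
        back = LandmarkSet.from_json_dict(found.to_json_dict())
        for name in found.com:
            assert np.allclose(back.com[name], found.com[name])


def test_equivariance_under_rigid_pose():
    """Keypoints move with the fetus, within rasterization tolerance."""
    from fetalplan.phantom import PhantomConfig, generate_phantom

    rot, tra = (30.0, -45.0, 70.0), (6.0, -3.0, 5.0)
    _, _, lm0, _ = generate_phantom(PhantomConfig(seed=6))
    _, _, lm1, _ = generate_phantom(
        PhantomConfig(seed=6, pose_rotation_deg=rot, pose_translation_mm=tra)
    )
    R = Rotation.from_euler("xyz", rot, degrees=True).as_matrix()
    t = np.asarray(tra)
    tol = 2 * 1.5
    for name in ("UV", "DAo", "spine"):
        k0 = tubular_keypoints(lm0, name)
        k1 = tubular_keypoints(lm1, name)
        mapped = {tuple(np.round(R @ p + t, 3)) for p in (k0[0], k0[2])}
        for q in (k1[0], k1[2]):
            assert min(
                np.linalg.norm(np.asarray(m) - q) for m in mapped
            ) < tol
        assert np.linalg.norm(R @ k0[1] + t - k1[1]) < tol
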