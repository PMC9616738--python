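"""Triangulation, the robust shape-model fit and the outlier loop."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.stats import chi2

import pose2thal as p2t
from pose2thal.errors import (
    EmptyInputError,
    InvalidCameraError,
    SchemaError,
    UnderdeterminedPoseError,
)
from pose2thal.pose_reconstruction import (
    ReconstructionConfig,
    TriangulatedPose,
    outlier_threshold,
    reject_outliers_and_fill,
)


def make_pose(model, rng, sigma=None, yaw=None, t=None):
    """A pose drawn from the model, optionally with isotropic noise."""
    b = rng.normal(size=model.n_eigenposes) * np.sqrt(model.eigenvalues)
    yaw = rng.uniform(0, 2 * np.pi) if yaw is None else yaw
    t = rng.normal(size=3) * 5.0 if t is None else t
    pose = p2t.synthesize_pose(model, b, p2t.yaw_rotation(yaw), t)
    if sigma:
        pose = pose + rng.normal(scale=sigma, size=pose.shape)
    return pose, b, yaw, t


def as_triangulated(pose, frame=0, valid=None):
    valid = np.ones(len(pose), bool) if valid is None else valid
    return TriangulatedPose(frame, pose, valid, np.zeros(len(pose)),
                            np.full(len(pose), 4))


class TestTriangulate:
    def test_noiseless_round_trip(self, model):
        kin = p2t.generate_kinematics(3.0, seed=0)
        cams = p2t.default_cameras()
        obs, _ = p2t.project_landmarks(kin, cams, 0.0, 0.0, 0.0, seed=1)
        tri = p2t.triangulate(obs, cams, model.landmark_names)
        for k in range(3):
            assert np.abs(tri[k].coords - kin.pose3d_true[k]).max() < 1e-9
            assert tri[k].valid.all()

    def test_single_view_landmark_flagged_missing(self, model):
        kin = p2t.generate_kinematics(2.0, seed=0)
        cams = p2t.default_cameras()
        obs, _ = p2t.project_landmarks(kin, cams, 0.0, 0.0, 0.0, seed=1)
        first = kin.frame[0]
        mask = ~((obs.frame == first) & (obs.landmark == "nose")
                 & (obs.camera != "cam0"))
        tri = p2t.triangulate(obs[mask], cams, model.landmark_names)
        j = model.landmark_names.index("nose")
        assert not tri[0].valid[j]
        assert np.isnan(tri[0].coords[j]).all()

    def test_one_camera_fully_missing_still_succeeds(self, model):
        kin = p2t.generate_kinematics(2.0, seed=0)
        cams = p2t.default_cameras()
        obs, _ = p2t.project_landmarks(kin, cams, 0.0, 0.0, 0.0, seed=1)
        obs = obs[obs.camera != "cam2"]
        tri = p2t.triangulate(obs, cams, model.landmark_names)
        assert tri[0].valid.all()
        assert np.abs(tri[0].coords - kin.pose3d_true[0]).max() < 1e-9

    def test_noisy_triangulation_matches_nonlinear_oracle(self, model):
        """DLT under 2 px noise agrees with a nonlinear reprojection
        least-squares solve within 10% median 3D error."""
        kin = p2t.generate_kinematics(4.0, seed=3)
        cams = p2t.default_cameras()
        obs, _ = p2t.project_landmarks(kin, cams, 2.0, 0.0, 0.0, seed=4)
        tri = p2t.triangulate(obs, cams, model.landmark_names)
        err_dlt, err_nls = [], []
        for k in range(min(20, len(tri))):
            grp = obs[obs.frame == tri[k].frame]
            for j, name in enumerate(model.landmark_names):
                rows = grp[grp.landmark == name]
                views = [(c.projection, float(r.x), float(r.y))
                         for c in cams for r in rows[rows.camera == c.cam_id].itertuples()]

                def resid(x):
                    out = []
                    for proj, u, v in views:
                        uvw = proj @ np.append(x, 1.0)
                        out += [uvw[0] / uvw[2] - u, uvw[1] / uvw[2] - v]
                    return np.asarray(out)

                sol = least_squares(resid, tri[k].coords[j]).x
                truth = kin.pose3d_true[k, j]
                err_dlt.append(np.linalg.norm(tri[k].coords[j] - truth))
                err_nls.append(np.linalg.norm(sol - truth))
        ratio = np.median(err_dlt) / np.median(err_nls)
        assert abs(ratio - 1.0) < 0.10

    def test_schema_and_empty_errors(self, model):
        import pandas as pd
        cams = p2t.default_cameras()
        with pytest.raises(EmptyInputError):
            p2t.triangulate(
                pd.DataFrame(columns=["frame", "camera", "landmark", "x", "y"]),
                cams, model.landmark_names)
        bad = pd.DataFrame({"frame": [0], "camera": ["cam0"],
                            "landmark": ["wing"], "x": [0.0], "y": [0.0]})
        with pytest.raises(SchemaError):
            p2t.triangulate(bad, cams, model.landmark_names)

    def test_degenerate_camera_rejected(self):
        with pytest.raises(InvalidCameraError):
            p2t.CameraModel("bad", np.zeros((3, 4)))


class TestFitPose:
    def test_generative_identity_noise_free(self, exact_model):
        rng = np.random.default_rng(0)
        for i in range(5):
            pose, b, yaw, t = make_pose(exact_model, rng)
            fit = p2t.fit_pose(as_triangulated(pose, i), exact_model)
            assert np.abs(fit.b - b).max() < 1e-6
            assert np.abs(fit.t - t).max() < 1e-6
            assert abs((fit.yaw - yaw + np.pi) % (2 * np.pi) - np.pi) < 1e-6
            # raw residual sum of squares (undo the sigma^-2 scale)
            assert fit.data_term * exact_model.noise_variance < 1e-12

    def test_mean_pose_gives_zero_scores(self, model):
        fit = p2t.fit_pose(as_triangulated(model.mean_pose.copy()), model)
        assert np.abs(fit.b).max() < 1e-8
        assert fit.cost < 1e-10

    def test_underdetermined_rejected(self, model):
        pose = model.mean_pose.copy()
        valid = np.zeros(11, bool)
        valid[:3] = True
        with pytest.raises(UnderdeterminedPoseError):
            p2t.fit_pose(as_triangulated(pose, valid=valid), model)

    def test_rigid_equivariance(self, model):
        """Rotating/translating the world leaves b unchanged and moves
        (yaw, t) accordingly."""
        rng = np.random.default_rng(1)
        pose, _, _, _ = make_pose(model, rng, sigma=np.sqrt(model.noise_variance))
        fit = p2t.fit_pose(as_triangulated(pose), model)
        dyaw, dt = 0.8, np.array([2.0, -1.0, 0.5])
        moved = pose @ p2t.yaw_rotation(dyaw) + dt
        fit2 = p2t.fit_pose(as_triangulated(moved), model)
        assert np.abs(fit2.b - fit.b).max() < 1e-8
        expected_t = fit.t @ p2t.yaw_rotation(dyaw) + dt
        assert np.abs(fit2.t - expected_t).max() < 1e-7
        assert abs((fit2.yaw - fit.yaw - dyaw + np.pi) % (2 * np.pi) - np.pi) < 1e-7


class TestOutlierLoop:
    def test_threshold_is_chi2_quantile(self, model):
        cfg = ReconstructionConfig(dof_mode="nominal")
        assert outlier_threshold(11, model, cfg) == pytest.approx(
            chi2.ppf(0.99, 33))
        assert chi2.ppf(0.99, 33) == pytest.approx(54.776, abs=0.01)
        cfg_eff = ReconstructionConfig()
        # yaw + translation + 3 scores = 7 fitted parameters
        assert outlier_threshold(11, model, cfg_eff) == pytest.approx(
            chi2.ppf(0.99, 26))

    def test_displaced_landmark_removed_first_and_corrected(self, model):
        rng = np.random.default_rng(2)
        sigma = np.sqrt(model.noise_variance)
        hits, corrected_ok = 0, 0
        for i in range(25):
            pose, b, yaw, t = make_pose(model, rng, sigma=sigma)
            clean = p2t.synthesize_pose(model, b, p2t.yaw_rotation(yaw), t)
            j = int(rng.integers(11))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pose[j] += 20 * sigma * direction
            fit = reject_outliers_and_fill(as_triangulated(pose, i), model)
            hits += bool(fit.removed) and fit.removed[0] == j
            corrected_ok += np.linalg.norm(
                fit.corrected_pose[j] - clean[j]) < 3 * sigma
        assert hits >= 23
        assert corrected_ok >= 23

    def test_removal_decreases_data_term(self, model):
        rng = np.random.default_rng(3)
        sigma = np.sqrt(model.noise_variance)
        pose, _, _, _ = make_pose(model, rng, sigma=sigma)
        direction = rng.normal(size=(3, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        for k, j in enumerate((0, 4, 7)):
            pose[j] += 25 * sigma * direction[k]
        tp = as_triangulated(pose)
        fit0 = p2t.fit_pose(tp, model)
        valid = tp.valid.copy()
        prev = fit0.data_term
        fit = reject_outliers_and_fill(tp, model)
        # re-walk the removal sequence, checking monotonicity
        for j in fit.removed:
            valid[j] = False
            f = p2t.fit_pose(tp, model, valid_override=valid)
            assert f.data_term < prev
            prev = f.data_term

    def test_floor_reached_flags_low_confidence(self, model):
        rng = np.random.default_rng(4)
        sigma = np.sqrt(model.noise_variance)
        pose, _, _, _ = make_pose(model, rng, sigma=sigma)
        pose += rng.normal(scale=40 * sigma, size=pose.shape)  # everything bad
        fit = reject_outliers_and_fill(as_triangulated(pose), model)
        assert fit.low_confidence
        assert fit.corrected_pose.shape == (11, 3)


class TestReconstructSeries:
    def test_clean_session_bias_bounded(self, model):
        kin = p2t.generate_kinematics(8.0, seed=5)
        cams = p2t.default_cameras()
        obs, _ = p2t.project_landmarks(kin, cams, 2.0, 0.0, 0.0, seed=6)
        poses, fits, tri = p2t.reconstruct_series(obs, cams, kin.model)
        err_tri = [np.linalg.norm(tp.coords - kin.pose3d_true[k], axis=1)
                   for k, tp in enumerate(tri)]
        err_fit = [np.linalg.norm(poses[k] - kin.pose3d_true[k], axis=1)
                   for k in range(len(fits))]
        assert np.median(err_fit) <= 1.5 * np.median(err_tri)

    def test_all_missing_frame_imputed_from_prior(self, model):
        kin = p2t.generate_kinematics(2.0, seed=7)
        cams = p2t.default_cameras()
        obs, _ = p2t.project_landmarks(kin, cams, 0.5, 0.0, 0.0, seed=8)
        drop = kin.frame[3]
        keep = obs[obs.frame != drop].copy()
        placeholder = obs[obs.frame == drop].iloc[:1].copy()
        placeholder = placeholder.assign(camera="cam0")  # one view: all missing
        import pandas as pd
        obs2 = pd.concat([keep, placeholder], ignore_index=True)
        poses, fits, _ = p2t.reconstruct_series(obs2, cams, kin.model)
        bad = [f for f in fits if f.frame == drop][0]
        assert bad.low_confidence
        assert np.abs(bad.b).max() == 0.0
        assert np.isfinite(poses[[f.frame for f in fits].index(drop)]).all()
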