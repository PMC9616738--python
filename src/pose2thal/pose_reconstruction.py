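"""Robust 3D pose reconstruction from multi-view 2D landmarks.

Pipeline per frame: DLT triangulation of each landmark over the cameras
that saw it, then a robust fit of the statistical shape model by
minimizing

    C(b, R, t) = sigma^-2 * ||X - (Xbar + sum_i b_i P_i) R - T||_F^2
                 + alpha * sum_i b_i^2 / lambda_i

over the valid landmarks (T replicates the translation vector t across
landmarks).  The minimization alternates a closed-form rigid alignment for
(R, t) with a closed-form ridge solution for the shape scores b.  Frames
whose converged cost exceeds a chi-square quantile enter an outlier loop:
the landmark contributing most to the data term is dropped, the fit is
recomputed, and the test repeated; the final pose is re-synthesized from
the model so that missing and rejected landmarks are filled in.

The default rotation parameterization is yaw-only (rotation about the
vertical axis), keeping up/down deformations such as body arch and rearing
in shape space where they are read out as eigenpose scores; a full 3D
rotation is available via ``rotation="full"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import (
    EmptyInputError,
    InvalidArgumentError,
    InvalidCameraError,
    SchemaError,
    UnderdeterminedPoseError,
)
from .shape_model import ShapeModel, rigid_align, yaw_rotation

OBS_COLUMNS = ("frame", "camera", "landmark", "x", "y", "confidence")


@dataclass
class CameraModel:
    """A calibrated pinhole camera: 3x4 projection matrix, world -> pixels."""

    cam_id: str
    projection: np.ndarray

    def __post_init__(self) -> None:
        self.projection = np.asarray(self.projection, dtype=float)
        if self.projection.shape != (3, 4):
            raise InvalidCameraError("projection matrix must be 3x4")
        if np.linalg.matrix_rank(self.projection) < 3:
            raise InvalidCameraError(f"camera {self.cam_id}: rank-deficient projection")

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project ``(N, 3)`` world points to ``(N, 2)`` pixel coordinates."""
        pts = np.asarray(points, dtype=float)
        hom = np.hstack([pts, np.ones((pts.shape[0], 1))])
        uvw = hom @ self.projection.T
        return uvw[:, :2] / uvw[:, 2:3]

    def to_dict(self) -> dict:
        return {"cam_id": self.cam_id, "projection": self.projection.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(cam_id=d["cam_id"], projection=np.asarray(d["projection"]))


@dataclass
class TriangulatedPose:
    """Per-frame triangulation result.

    ``coords`` is ``(Np, 3)`` with NaN rows where fewer than two cameras saw
    the landmark; ``residual`` is the RMS reprojection error in pixels.
    """

    frame: int
    coords: np.ndarray
    valid: np.ndarray
    residual: np.ndarray
    n_views: np.ndarray


@dataclass
class PoseFit:
    """Solution of the robust shape-model fit for one frame."""

    frame: int
    b: np.ndarray
    rot: np.ndarray
    t: np.ndarray
    cost: float
    data_term: float
    inlier_mask: np.ndarray
    corrected_pose: np.ndarray
    n_iter: int
    converged: bool
    removed: list = field(default_factory=list)
    low_confidence: bool = False

    @property
    def yaw(self) -> float:
        """Heading angle implied by the fitted rotation (rad)."""
        return float(np.arctan2(self.rot[0, 1], self.rot[0, 0]))


@dataclass
class ReconstructionConfig:
    """Knobs for the per-frame robust fit.

    ``alpha`` is the ridge weight on the shape scores (default 0.01);
    ``chi2_prob`` the probability level of the chi-square outlier test;
    ``dof_mode`` chooses the degrees of freedom of that test: "effective"
    subtracts the fitted parameter count from 3*Np (calibrated so clean
    frames are flagged at rate 1 - chi2_prob), "nominal" uses 3*Np.
    """

    alpha: float = 0.01
    chi2_prob: float = 0.99
    rotation: str = "yaw"  # "yaw" | "full"
    np_floor: int = 6
    dof_mode: str = "effective"  # "effective" | "nominal"
    tol: float = 1e-10
    max_iter: int = 300


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------


def _dlt_point(obs: list[tuple[np.ndarray, float, float]]) -> np.ndarray:
    """Linear triangulation of one landmark from >= 2 (P, u, v) views."""
    rows = []
    for proj, u, v in obs:
        rows.append(u * proj[2] - proj[0])
        rows.append(v * proj[2] - proj[1])
    a = np.asarray(rows)
    _, _, vt = np.linalg.svd(a)
    x = vt[-1]
    return x[:3] / x[3]


def triangulate(
    observations2d: pd.DataFrame,
    cameras: list[CameraModel],
    landmark_names: tuple[str, ...],
) -> list[TriangulatedPose]:
    """DLT triangulation of every landmark in every frame.

    Landmarks observed by fewer than two cameras are flagged invalid and
    carry NaN coordinates.  Reprojection residuals (RMS over contributing
    views, pixels) are reported per landmark.
    """
    missing_cols = set(OBS_COLUMNS[:5]) - set(observations2d.columns)
    if missing_cols:
        raise SchemaError(f"observations missing columns {sorted(missing_cols)}")
    if len(observations2d) == 0:
        raise EmptyInputError("no observations")
    unknown = set(observations2d["landmark"].unique()) - set(landmark_names)
    if unknown:
        raise SchemaError(f"unknown landmarks {sorted(unknown)}")

    cam_map = {c.cam_id: c.projection for c in cameras}
    lm_index = {name: i for i, name in enumerate(landmark_names)}
    npts = len(landmark_names)
    out: list[TriangulatedPose] = []
    for frame, grp in observations2d.groupby("frame", sort=True):
        coords = np.full((npts, 3), np.nan)
        valid = np.zeros(npts, dtype=bool)
        residual = np.full(npts, np.nan)
        n_views = np.zeros(npts, dtype=int)
        for lm, lgrp in grp.groupby("landmark"):
            j = lm_index[lm]
            views = [
                (cam_map[row.camera], row.x, row.y)
                for row in lgrp.itertuples()
                if row.camera in cam_map
            ]
            n_views[j] = len(views)
            if len(views) < 2:
                continue
            pt = _dlt_point(views)
            errs = []
            for proj, u, v in views:
                uvw = proj @ np.append(pt, 1.0)
                errs.append((uvw[0] / uvw[2] - u) ** 2 + (uvw[1] / uvw[2] - v) ** 2)
            coords[j] = pt
            valid[j] = True
            residual[j] = float(np.sqrt(np.mean(errs)))
        out.append(TriangulatedPose(int(frame), coords, valid, residual, n_views))
    return out


# ---------------------------------------------------------------------------
# shape-model fit (alternating minimization of the regularized cost)
# ---------------------------------------------------------------------------


def _yaw_align(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal yaw rotation and 3D translation mapping source onto target."""
    src_c = source.mean(axis=0)
    tgt_c = target.mean(axis=0)
    s = source - src_c
    d = target - tgt_c
    m00 = float(s[:, 0] @ d[:, 0] + s[:, 1] @ d[:, 1])
    m01 = float(s[:, 0] @ d[:, 1] - s[:, 1] @ d[:, 0])
    theta = float(np.arctan2(m01, m00))
    rot = yaw_rotation(theta)
    t = tgt_c - src_c @ rot
    return rot, t


def evaluate_cost(
    x: np.ndarray,
    valid: np.ndarray,
    model: ShapeModel,
    b: np.ndarray,
    rot: np.ndarray,
    t: np.ndarray,
    alpha: float,
) -> tuple[float, float, np.ndarray]:
    """Cost, data term and per-landmark data contributions at (b, R, t)."""
    shape = model.mean_pose + np.tensordot(b, model.eigenposes, axes=1)
    pred = shape @ rot + t
    per_lm = np.sum((x - pred) ** 2, axis=1) / model.noise_variance
    per_lm = np.where(valid, per_lm, 0.0)
    data = float(per_lm.sum())
    penalty = float(alpha * np.sum(b**2 / model.eigenvalues))
    return data + penalty, data, per_lm


def fit_pose(
    pose: TriangulatedPose,
    model: ShapeModel,
    alpha: float = 0.01,
    rotation: str = "yaw",
    tol: float = 1e-10,
    max_iter: int = 300,
    valid_override: np.ndarray | None = None,
) -> PoseFit:
    """Minimize the regularized reconstruction cost for one frame.

    Alternates (i) closed-form rigid alignment of the current model shape
    onto the data for (R, t) — yaw-only or full 3D — with (ii) the exact
    ridge solution for b given (R, t), until the cost decreases by less
    than ``tol`` or ``max_iter`` is reached.
    """
    if alpha <= 0:
        raise InvalidArgumentError("alpha must be > 0")
    valid = pose.valid if valid_override is None else valid_override
    n_valid = int(valid.sum())
    if n_valid < 4:
        raise UnderdeterminedPoseError(f"frame {pose.frame}: {n_valid} valid landmarks")
    x = pose.coords
    xv = x[valid]
    k = model.n_eigenposes
    lam = model.eigenvalues
    sig2 = model.noise_variance
    pv = model.eigenposes[:, valid, :].reshape(k, -1)  # (K, 3*n_valid)
    gram = pv @ pv.T / sig2 + alpha * np.diag(1.0 / lam)
    align = _yaw_align if rotation == "yaw" else rigid_align

    b = np.zeros(k)
    cost = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        shape = model.mean_pose + np.tensordot(b, model.eigenposes, axes=1)
        rot, t = align(shape[valid], xv)
        # ridge solve for b in the model frame (rotation preserves norms)
        y = ((xv - t) @ rot.T - model.mean_pose[valid]).reshape(-1)
        b = np.linalg.solve(gram, pv @ y / sig2)
        new_cost, data, _ = evaluate_cost(x, valid, model, b, rot, t, alpha)
        if cost - new_cost < tol:
            cost = new_cost
            converged = True
            break
        cost = new_cost
    cost, data, _ = evaluate_cost(x, valid, model, b, rot, t, alpha)
    corrected = (model.mean_pose + np.tensordot(b, model.eigenposes, axes=1)) @ rot + t
    return PoseFit(
        frame=pose.frame,
        b=b,
        rot=rot,
        t=t,
        cost=cost,
        data_term=data,
        inlier_mask=valid.copy(),
        corrected_pose=corrected,
        n_iter=it,
        converged=converged,
    )


def _n_fit_params(model: ShapeModel, rotation: str) -> int:
    return (1 if rotation == "yaw" else 3) + 3 + model.n_eigenposes


def outlier_threshold(
    n_valid: int, model: ShapeModel, config: ReconstructionConfig
) -> float:
    """Chi-square quantile against which the converged cost is tested."""
    dof = 3 * n_valid
    if config.dof_mode == "effective":
        dof = max(dof - _n_fit_params(model, config.rotation), 1)
    elif config.dof_mode != "nominal":
        raise InvalidArgumentError(f"unknown dof_mode {config.dof_mode!r}")
    return float(chi2.ppf(config.chi2_prob, dof))


def reject_outliers_and_fill(
    pose: TriangulatedPose,
    model: ShapeModel,
    config: ReconstructionConfig | None = None,
) -> PoseFit:
    """Iterative chi-square outlier rejection followed by model in-fill.

    While the converged cost exceeds the chi-square quantile at
    ``config.chi2_prob`` (degrees of freedom per ``config.dof_mode``), the
    valid landmark with the largest contribution to the data term is
    removed and the fit recomputed, stopping when the cost passes the test
    or the valid count would fall below ``config.np_floor``.  The corrected
    pose is re-synthesized from the model at the final (b, R, t), so every
    landmark — missing, rejected or retained — gets a coordinate.
    """
    config = config or ReconstructionConfig()
    if not 0.0 < config.chi2_prob < 1.0:
        raise InvalidArgumentError("chi2_prob must be in (0, 1)")
    valid = pose.valid.copy()
    removed: list[int] = []
    fit = fit_pose(
        pose, model, config.alpha, config.rotation, config.tol, config.max_iter,
        valid_override=valid,
    )
    while True:
        n_valid = int(valid.sum())
        if fit.cost <= outlier_threshold(n_valid, model, config):
            low_confidence = False
            break
        if n_valid - 1 < config.np_floor:
            low_confidence = True
            break
        _, _, per_lm = evaluate_cost(
            pose.coords, valid, model, fit.b, fit.rot, fit.t, config.alpha
        )
        worst = int(np.argmax(np.where(valid, per_lm, -np.inf)))
        valid[worst] = False
        removed.append(worst)
        fit = fit_pose(
            pose, model, config.alpha, config.rotation, config.tol, config.max_iter,
            valid_override=valid,
        )
    fit.removed = removed
    fit.low_confidence = low_confidence
    return fit


# ---------------------------------------------------------------------------
# per-session driver
# ---------------------------------------------------------------------------


def reconstruct_series(
    observations2d: pd.DataFrame,
    cameras: list[CameraModel],
    model: ShapeModel,
    config: ReconstructionConfig | None = None,
) -> tuple[np.ndarray, list[PoseFit], list[TriangulatedPose]]:
    """Triangulate, robust-fit and in-fill every frame of a session.

    Returns the corrected ``(F, Np, 3)`` pose series, the per-frame fits
    and the raw triangulations.  Frames with fewer than four valid
    landmarks are imputed from the model prior (b = 0) at the last known
    rotation/translation and flagged low-confidence.
    """
    config = config or ReconstructionConfig()
    tri = triangulate(observations2d, cameras, model.landmark_names)
    fits: list[PoseFit] = []
    last_rot = np.eye(3)
    last_t = np.zeros(3)
    for tp in tri:
        if int(tp.valid.sum()) >= 4:
            fit = reject_outliers_and_fill(tp, model, config)
            last_rot, last_t = fit.rot, fit.t
        else:
            b = np.zeros(model.n_eigenposes)
            corrected = model.mean_pose @ last_rot + last_t
            fit = PoseFit(
                frame=tp.frame,
                b=b,
                rot=last_rot.copy(),
                t=last_t.copy(),
                cost=np.nan,
                data_term=np.nan,
                inlier_mask=np.zeros_like(tp.valid),
                corrected_pose=corrected,
                n_iter=0,
                converged=False,
                low_confidence=True,
            )
        fits.append(fit)
    poses = np.stack([f.corrected_pose for f in fits])
    return poses, fits, tri


def fits_to_frame(fits: list[PoseFit]) -> pd.DataFrame:
    """Tabulate per-frame fit diagnostics (one row per frame)."""
    rows = []
    for f in fits:
        row = {
            "frame": f.frame,
            "yaw": f.yaw,
            "tx": f.t[0],
            "ty": f.t[1],
            "tz": f.t[2],
            "cost": f.cost,
            "np_used": int(f.inlier_mask.sum()),
            "low_confidence": f.low_confidence,
        }
        for i, bi in enumerate(f.b, start=1):
            row[f"b{i}"] = bi
        rows.append(row)
    return pd.DataFrame(rows)
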