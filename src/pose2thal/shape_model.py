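"""Statistical shape model (SSM) of the mouse body.

A pose is an ``(Np, 3)`` array of landmark coordinates.  The SSM is a linear
model of body shape obtained from generalized Procrustes alignment (scale
fixed to 1) followed by probabilistic PCA on the flattened poses:

    X = (Xbar + sum_i b_i P_i) R + T

where ``Xbar`` is the mean pose, ``P_i`` are orthonormal eigenposes with
eigenvalues ``lambda_i`` (variance of the corresponding shape score ``b_i``)
and an isotropic residual noise variance ``sigma2`` accounts for the
discarded modes.  The scores on the first three eigenposes are read out as
the behavioral variables body arch (Bar), body left/right bend (Blr) and
body lunge (Blu).

Flattening convention: landmark-major, i.e. ``pose.reshape(-1)`` gives
``(x0, y0, z0, x1, y1, z1, ...)``; fixed throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .errors import (
    DegenerateInputError,
    InvalidArgumentError,
    InvalidRotationError,
)

#: canonical landmark set (11 landmarks: head stage + body)
LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "ear_left",
    "ear_right",
    "headstage",
    "neck",
    "body_left",
    "body_right",
    "spine_mid",
    "hip_left",
    "hip_right",
    "tail_base",
)
N_LANDMARKS = len(LANDMARK_NAMES)


@dataclass
class PoseSet:
    """A collection of 3D poses sharing one landmark set.

    Parameters
    ----------
    poses
        Array of shape ``(N, Np, 3)``.
    landmark_names
        ``Np`` landmark names.
    valid
        Optional boolean mask ``(N, Np)``; landmarks flagged False carry no
        usable coordinates.
    """

    poses: np.ndarray
    landmark_names: tuple[str, ...] = LANDMARK_NAMES
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.poses = np.asarray(self.poses, dtype=float)
        if self.poses.ndim != 3 or self.poses.shape[2] != 3:
            raise InvalidArgumentError("poses must have shape (N, Np, 3)")
        if self.poses.shape[1] != len(self.landmark_names):
            raise InvalidArgumentError("landmark_names length mismatch")
        if self.valid is None:
            self.valid = np.ones(self.poses.shape[:2], dtype=bool)
        if not np.all(np.isfinite(self.poses[self.valid])):
            raise InvalidArgumentError("valid landmarks must be finite")

    @property
    def n_poses(self) -> int:
        return self.poses.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.poses.shape[1]


@dataclass
class ShapeModel:
    """Trained statistical shape model.

    Attributes
    ----------
    mean_pose
        ``(Np, 3)`` Procrustes mean pose.
    eigenposes
        ``(K, Np, 3)``; flattened rows are orthonormal.
    eigenvalues
        ``(K,)`` shape-score variances, non-increasing.
    noise_variance
        Isotropic residual variance sigma2 (ML estimate: mean of the
        discarded sample eigenvalues).
    total_variance
        Sum of all sample eigenvalues (retained + discarded); used for
        explained-variance fractions.
    """

    mean_pose: np.ndarray
    eigenposes: np.ndarray
    eigenvalues: np.ndarray
    noise_variance: float
    total_variance: float
    landmark_names: tuple[str, ...] = LANDMARK_NAMES

    def __post_init__(self) -> None:
        self.mean_pose = np.asarray(self.mean_pose, dtype=float)
        self.eigenposes = np.asarray(self.eigenposes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.noise_variance < 0:
            raise InvalidArgumentError("noise_variance must be >= 0")
        lam = self.eigenvalues
        if lam.size > 1 and np.any(np.diff(lam) > 1e-12):
            raise InvalidArgumentError("eigenvalues must be non-increasing")
        flat = self.eigenposes.reshape(self.n_eigenposes, -1)
        gram = flat @ flat.T
        if not np.allclose(gram, np.eye(self.n_eigenposes), atol=1e-8):
            raise InvalidArgumentError("eigenposes must be orthonormal")

    @property
    def n_eigenposes(self) -> int:
        return self.eigenposes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.mean_pose.shape[0]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mean_pose": self.mean_pose.tolist(),
            "eigenposes": self.eigenposes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "noise_variance": float(self.noise_variance),
            "total_variance": float(self.total_variance),
            "landmark_names": list(self.landmark_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeModel":
        return cls(
            mean_pose=np.asarray(d["mean_pose"]),
            eigenposes=np.asarray(d["eigenposes"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            noise_variance=float(d["noise_variance"]),
            total_variance=float(d["total_variance"]),
            landmark_names=tuple(d["landmark_names"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# rigid alignment primitives
# ---------------------------------------------------------------------------


def rigid_align(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation ``R`` and translation ``t`` with ``source @ R + t ~ target``.

    Scale is fixed to 1 (no similarity scaling).  Least squares over all
    landmarks; both arrays ``(Np, 3)``.
    """
    src_c = source.mean(axis=0)
    tgt_c = target.mean(axis=0)
    m = (source - src_c).T @ (target - tgt_c)
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    t = tgt_c - src_c @ rot
    return rot, t


def procrustes_align(
    poses: PoseSet, tol: float = 1e-8, max_iter: int = 50
) -> tuple[PoseSet, np.ndarray]:
    """Generalized Procrustes superimposition with scale fixed to 1.

    Each pose is iteratively rotated/translated onto the running mean,
    starting from the first pose as reference, until the mean pose changes
    by less than ``tol`` (RMS) or ``max_iter`` is reached.

    Returns the aligned pose set and the converged mean pose.
    """
    if poses.n_poses < 2:
        raise InvalidArgumentError("need at least 2 poses")
    if not bool(poses.valid.all()):
        raise InvalidArgumentError("generalized Procrustes requires complete poses")
    spread = poses.poses - poses.poses.mean(axis=1, keepdims=True)
    if float(np.abs(spread).max()) < 1e-12:
        raise DegenerateInputError("all poses have zero spread")

    ref = poses.poses[0].copy()
    aligned = poses.poses.copy()
    for _ in range(max_iter):
        for i in range(poses.n_poses):
            rot, t = rigid_align(poses.poses[i], ref)
            aligned[i] = poses.poses[i] @ rot + t
        new_mean = aligned.mean(axis=0)
        change = float(np.sqrt(np.mean((new_mean - ref) ** 2)))
        ref = new_mean
        if change < tol:
            break
    return PoseSet(aligned, poses.landmark_names), ref


def procrustes_sum_of_squares(aligned: np.ndarray, mean: np.ndarray) -> float:
    """Total squared distance of aligned poses from the mean pose."""
    return float(np.sum((aligned - mean[None]) ** 2))


# ---------------------------------------------------------------------------
# PPCA training and synthesis
# ---------------------------------------------------------------------------


def train_ssm(aligned: PoseSet, n_eigenposes: int = 3) -> ShapeModel:
    """Fit the SSM by probabilistic PCA on aligned poses.

    The ``(N, 3*Np)`` flattened poses are decomposed into ``n_eigenposes``
    orthonormal modes with variances ``lambda_i``; the residual noise
    variance is the maximum-likelihood estimate (mean of the discarded
    sample eigenvalues).
    """
    n, npts = aligned.n_poses, aligned.n_landmarks
    dim = 3 * npts
    if n_eigenposes >= dim:
        raise InvalidArgumentError("n_eigenposes must be < 3*Np")
    if n <= n_eigenposes:
        raise InvalidArgumentError("need more poses than eigenposes")
    flat = aligned.poses.reshape(n, dim)
    pca = PCA(n_components=n_eigenposes)
    pca.fit(flat)
    mean_pose = pca.mean_.reshape(npts, 3)
    eigenposes = pca.components_.reshape(n_eigenposes, npts, 3)
    sigma2 = float(pca.noise_variance_)
    # PPCA generative parameterization: the shape-score variance is the
    # sample eigenvalue minus the isotropic noise riding on top of it
    eigenvalues = np.maximum(pca.explained_variance_ - sigma2, 1e-12)
    total = float(pca.explained_variance_.sum() + sigma2 * (dim - n_eigenposes))
    return ShapeModel(
        mean_pose=mean_pose,
        eigenposes=eigenposes,
        eigenvalues=eigenvalues,
        noise_variance=sigma2,
        total_variance=total,
        landmark_names=aligned.landmark_names,
    )


def check_rotation(rot: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Validate a proper rotation matrix (orthogonal, det +1)."""
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3):
        raise InvalidRotationError("R must be 3x3")
    if not np.allclose(rot @ rot.T, np.eye(3), atol=atol):
        raise InvalidRotationError("R is not orthogonal")
    if np.linalg.det(rot) < 0:
        raise InvalidRotationError("R must be proper (det = +1)")
    return rot


def yaw_rotation(yaw: float) -> np.ndarray:
    """Rotation about the vertical (z) axis by ``yaw`` radians.

    Row-vector convention: ``pose @ yaw_rotation(a)`` rotates points
    counter-clockwise by ``a`` when viewed from above.
    """
    c, s = np.cos(yaw), np.sin(yaw)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def synthesize_pose(
    model: ShapeModel, b: np.ndarray, rot: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Generate the pose ``(Xbar + sum_i b_i P_i) R + t`` (landmarks as rows)."""
    b = np.asarray(b, dtype=float)
    if b.shape != (model.n_eigenposes,):
        raise InvalidArgumentError(
            f"b must have length {model.n_eigenposes}, got {b.shape}"
        )
    rot = check_rotation(rot)
    t = np.asarray(t, dtype=float).reshape(3)
    shape = model.mean_pose + np.tensordot(b, model.eigenposes, axes=1)
    return shape @ rot + t


def explained_variance(model: ShapeModel) -> np.ndarray:
    """Fraction of total pose variance captured by each eigenpose.

    Fractions are ``lambda_i / total_variance`` where the denominator
    includes the residual noise, so they sum to at most 1.
    """
    if model.total_variance <= 0:
        raise InvalidArgumentError("model has zero total variance")
    return model.eigenvalues / model.total_variance


def n_components_for_variance(
    eigenvalues: np.ndarray, total_variance: float, threshold: float = 0.95
) -> int:
    """Smallest eigenpose count whose cumulative fraction reaches ``threshold``."""
    frac = np.cumsum(eigenvalues) / total_variance
    idx = np.searchsorted(frac, threshold)
    return int(min(idx + 1, len(eigenvalues)))
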