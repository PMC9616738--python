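"""Synthetic sessions with the statistical structure the analysis assumes.

The generator emulates a freely exploring mouse recorded by four cameras
at 15 Hz in 15-24 s epochs separated by 30-40 s gaps:

* ground-truth kinematics: shape scores follow mean-reverting (OU)
  dynamics gated by rearing and locomotion bouts, heading is a random
  walk, and the body centre moves through a square arena — giving slow
  (0-2 Hz) behavioral dynamics;
* 2D observations: pinhole projections of the true pose corrupted by
  Gaussian pixel noise, large-displacement outliers and missing
  detections, with exact corruption bookkeeping for test oracles;
* spike trains: inhomogeneous Poisson counts whose log rate is linear in
  the up/down posture score (body arch) and overall motion, the "look-up"
  (positive arch coefficient) / "look-down" (negative) phenomenology.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior_state import BehavioralState, build_state
from .errors import InvalidArgumentError, InvalidTuningError
from .pose_reconstruction import CameraModel, PoseFit
from .shape_model import (
    LANDMARK_NAMES,
    ShapeModel,
    synthesize_pose,
    yaw_rotation,
)

# ---------------------------------------------------------------------------
# built-in mouse shape model
# ---------------------------------------------------------------------------

_MEAN_POSE_CM = np.array(
    [
        [6.5, 0.0, 1.5],    # nose
        [5.0, 1.2, 2.2],    # ear_left
        [5.0, -1.2, 2.2],   # ear_right
        [4.8, 0.0, 3.0],    # headstage
        [4.0, 0.0, 2.0],    # neck
        [1.5, 1.5, 1.2],    # body_left
        [1.5, -1.5, 1.2],   # body_right
        [1.5, 0.0, 2.2],    # spine_mid
        [-1.5, 1.2, 1.0],   # hip_left
        [-1.5, -1.2, 1.0],  # hip_right
        [-3.0, 0.0, 1.0],   # tail_base
    ]
)

# raw deformation directions (cm) before orthonormalization
_MODE_ARCH = np.array(
    [
        [-1.0, 0.0, 2.5], [-0.6, 0.0, 1.8], [-0.6, 0.0, 1.8], [-0.6, 0.0, 2.2],
        [-0.4, 0.0, 1.2], [0.0, 0.0, 0.2], [0.0, 0.0, 0.2], [0.0, 0.0, 0.5],
        [0.2, 0.0, -0.2], [0.2, 0.0, -0.2], [0.5, 0.0, -0.5],
    ]
)
_MODE_BEND = np.array(
    [
        [0.0, 2.5, 0.0], [0.0, 1.8, 0.0], [0.0, 1.8, 0.0], [0.0, 1.7, 0.0],
        [0.0, 1.2, 0.0], [0.0, 0.3, 0.0], [0.0, 0.3, 0.0], [0.0, 0.3, 0.0],
        [0.0, -0.8, 0.0], [0.0, -0.8, 0.0], [0.0, -1.5, 0.0],
    ]
)
_MODE_LUNGE = np.array(
    [
        [2.0, 0.0, 0.0], [1.5, 0.0, 0.0], [1.5, 0.0, 0.0], [1.4, 0.0, 0.0],
        [1.2, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.2, 0.0, 0.0],
        [-0.8, 0.0, 0.0], [-0.8, 0.0, 0.0], [-1.5, 0.0, 0.0],
    ]
)


def default_shape_model(
    eigenvalues: tuple[float, ...] = (1.0, 0.5, 0.25),
    noise_variance: float = 0.02,
) -> ShapeModel:
    """Built-in three-eigenpose mouse model (arch, left/right bend, lunge).

    The deformation directions are orthonormalized (QR) so they satisfy
    the shape-model invariants; eigenvalues are the shape-score variances
    in cm^2 and give the first three modes ~75% of total pose variance.
    """
    mean = _MEAN_POSE_CM - _MEAN_POSE_CM.mean(axis=0)
    raw = np.stack(
        [m.reshape(-1) for m in (_MODE_ARCH, _MODE_BEND, _MODE_LUNGE)]
    )
    q, r = np.linalg.qr(raw.T)
    modes = (q * np.sign(np.diag(r))).T  # keep original orientation
    return ShapeModel(
        mean_pose=mean,
        eigenposes=modes.reshape(3, len(LANDMARK_NAMES), 3),
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        noise_variance=noise_variance,
        total_variance=float(
            sum(eigenvalues) + noise_variance * (3 * len(LANDMARK_NAMES) - 3)
        ),
        landmark_names=LANDMARK_NAMES,
    )


def sample_poses(
    model: ShapeModel, n: int, seed: int = 0, noise: bool = True
) -> np.ndarray:
    """Draw ``n`` aligned poses from the model's generative distribution."""
    rng = np.random.default_rng(seed)
    b = rng.normal(size=(n, model.n_eigenposes)) * np.sqrt(model.eigenvalues)
    poses = model.mean_pose[None] + np.tensordot(b, model.eigenposes, axes=1)
    if noise:
        poses = poses + rng.normal(
            scale=np.sqrt(model.noise_variance), size=poses.shape
        )
    return poses


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


@dataclass
class MotifParams:
    """Dynamics of the simulated behavior.

    Shape scores follow an OU process (time constant ``score_tau_s``,
    stationary SD ``score_sd_frac * sqrt(lambda_i)``) whose target is
    raised along the arch mode during rearing bouts.  Locomotion bouts
    move the body centre at ``loco_speed_cms`` along the heading; heading
    is a random walk.  Bout onsets are Poisson with the given rates.
    """

    score_tau_s: float = 0.6
    score_sd_frac: float = 0.8
    posture_common_frac: float = 0.9   # shared slow drift across all postures
    posture_common_tau_s: float = 6.0
    rear_rate_hz: float = 0.05
    rear_duration_s: float = 2.0
    rear_arch_boost: float = 2.0   # units of sqrt(lambda_1)
    rear_height_cm: float = 2.0
    rear_lunge_drop: float = 0.8   # units of sqrt(lambda_3), body compression
    loco_rate_hz: float = 0.1
    loco_duration_s: float = 3.0
    loco_speed_cms: float = 8.0
    motion_gain: float = 2.0       # bout-gated amplitude envelope on all noise
    envelope_tau_s: float = 0.5
    activity_log_sd: float = 1.0   # SD of the slow log-normal activity level
    activity_tau_s: float = 1.5
    speed_cap: float = 2.4         # cap on the envelope's dynamics speed-up
    yaw_sd: float = 1.0            # rad / sqrt(s)
    xy_jitter_cms: float = 1.0     # extra body-centre jitter SD (cm/sqrt(s))
    z_sd_cm: float = 0.15
    z_tau_s: float = 0.4
    z_base_cm: float = 2.0
    z_arch_gain_cm: float = 0.4    # body-centre rise per unit arch score
    arena_half_cm: float = 15.0
    epoch_duration_range: tuple[float, float] = (15.0, 24.0)
    epoch_gap_range: tuple[float, float] = (30.0, 40.0)

    @classmethod
    def still(cls) -> "MotifParams":
        """Degenerate parameters: no noise, no bouts — a frozen animal."""
        return cls(
            score_sd_frac=0.0, rear_rate_hz=0.0, loco_rate_hz=0.0,
            yaw_sd=0.0, xy_jitter_cms=0.0, z_sd_cm=0.0,
        )


@dataclass
class KinematicsGroundTruth:
    """Ground-truth trajectories; ``pose3d_true`` is the exact synthesis
    of (b_true, yaw_true, t_true) through the shape model."""

    epochs: list[tuple[float, float]]
    frame_rate: float
    frame: np.ndarray
    time_s: np.ndarray
    epoch_index: np.ndarray
    b_true: np.ndarray
    yaw_true: np.ndarray
    t_true: np.ndarray
    pose3d_true: np.ndarray
    model: ShapeModel

    @property
    def n_frames(self) -> int:
        return len(self.frame)


def _draw_epochs(
    duration_s: float, params: MotifParams, rng: np.random.Generator
) -> list[tuple[float, float]]:
    epochs = []
    t = 0.0
    total = 0.0
    while total < duration_s:
        dur = float(rng.uniform(*params.epoch_duration_range))
        epochs.append((t, t + dur))
        total += dur
        t += dur + float(rng.uniform(*params.epoch_gap_range))
    return epochs


def generate_kinematics(
    duration_s: float,
    frame_rate: float = 15.0,
    model: ShapeModel | None = None,
    motif_params: MotifParams | None = None,
    seed: int = 0,
) -> KinematicsGroundTruth:
    """Simulate ground-truth kinematics totalling ``duration_s`` of epochs.

    ``duration_s`` counts recorded (within-epoch) time; the simulation
    runs continuously through the 30-40 s inter-epoch gaps but only
    within-epoch frames are returned.  Shape scores are clipped to
    ``+/- 3 sqrt(lambda_i)``.
    """
    if duration_s <= 0 or frame_rate <= 0:
        raise InvalidArgumentError("duration_s and frame_rate must be > 0")
    model = model or default_shape_model()
    if model.n_eigenposes < 3:
        raise InvalidArgumentError("model needs >= 3 eigenposes")
    p = motif_params or MotifParams()
    rng = np.random.default_rng(seed)
    epochs = _draw_epochs(duration_s, p, rng)
    span = epochs[-1][1]
    dt = 1.0 / frame_rate
    n_total = int(np.ceil(span * frame_rate)) + 1
    times = np.arange(n_total) * dt

    k = model.n_eigenposes
    sqrt_lam = np.sqrt(model.eigenvalues)
    sd = p.score_sd_frac * sqrt_lam
    b = np.zeros((n_total, k))
    yaw = np.zeros(n_total)
    t_xyz = np.zeros((n_total, 3))
    t_xyz[0, 2] = p.z_base_cm

    # Poisson bout onsets, fixed durations
    def bout_mask(rate, dur):
        mask = np.zeros(n_total, dtype=bool)
        if rate <= 0:
            return mask
        t0 = float(rng.exponential(1.0 / rate))
        while t0 < span:
            i0 = int(t0 * frame_rate)
            mask[i0: i0 + max(int(dur * frame_rate), 1)] = True
            t0 += dur + float(rng.exponential(1.0 / rate))
        return mask

    rearing = bout_mask(p.rear_rate_hz, p.rear_duration_s)
    walking = bout_mask(p.loco_rate_hz, p.loco_duration_s)

    theta = dt / p.score_tau_s
    sig_b = sd * np.sqrt(2.0 * theta)
    z_theta = dt / p.z_tau_s
    sig_z = p.z_sd_cm * np.sqrt(2.0 * z_theta)
    # shared amplitude envelope: a slow log-normal activity level plus a
    # bout gate, multiplying every increment — movement magnitudes co-vary
    # the way bout-structured behavior does
    active = (rearing | walking).astype(float)
    gate = np.ones(n_total)
    for i in range(1, n_total):
        gate[i] = gate[i - 1] + (
            1.0 + p.motion_gain * active[i] - gate[i - 1]
        ) * dt / p.envelope_tau_s
    g = np.zeros(n_total)
    if p.activity_log_sd > 0 and p.score_sd_frac > 0:
        a_theta = dt / p.activity_tau_s
        a_sig = p.activity_log_sd * np.sqrt(2.0 * a_theta)
        g[0] = rng.normal(scale=p.activity_log_sd)
        for i in range(1, n_total):
            g[i] = g[i - 1] - a_theta * g[i - 1] + a_sig * rng.normal()
    env = gate * np.exp(g - 0.5 * p.activity_log_sd**2)
    # the envelope speeds posture dynamics up (mean reversion and noise
    # scaled together, keeping the stationary range fixed) rather than
    # widening the posture range: an active animal moves faster, not bigger
    speed = np.minimum(env, p.speed_cap) ** 2
    # slow common drift of the whole body configuration, shared by all
    # shape scores: couples the postures to each other without touching
    # the movement variables (its derivative is negligible)
    common = np.zeros(n_total)
    if p.posture_common_frac > 0 and p.score_sd_frac > 0:
        c_theta = dt / p.posture_common_tau_s
        c_sig = np.sqrt(2.0 * c_theta)
        for i in range(1, n_total):
            common[i] = common[i - 1] - c_theta * common[i - 1] + c_sig * rng.normal()
    for i in range(1, n_total):
        target_b = p.posture_common_frac * common[i] * sd
        if rearing[i]:
            target_b[0] += p.rear_arch_boost * sqrt_lam[0]
            if k >= 3:
                target_b[2] -= p.rear_lunge_drop * sqrt_lam[2]
        b[i] = (
            b[i - 1]
            + speed[i] * theta * (target_b - b[i - 1])
            + np.sqrt(speed[i]) * sig_b * rng.normal(size=k)
        )
        yaw[i] = yaw[i - 1] + env[i] * p.yaw_sd * np.sqrt(dt) * rng.normal()
        step = np.zeros(2)
        if walking[i]:
            step = (p.loco_speed_cms * dt) * np.array(
                [np.cos(yaw[i]), np.sin(yaw[i])]
            )
        step = step + env[i] * p.xy_jitter_cms * np.sqrt(dt) * rng.normal(size=2)
        t_xyz[i, :2] = np.clip(
            t_xyz[i - 1, :2] + step, -p.arena_half_cm, p.arena_half_cm
        )
        z_target = (
            p.z_base_cm
            + (p.rear_height_cm if rearing[i] else 0.0)
            + p.z_arch_gain_cm * b[i, 0]
        )
        zs = min(speed[i], 0.95 / z_theta)  # keep the update stable
        t_xyz[i, 2] = (
            t_xyz[i - 1, 2]
            + zs * z_theta * (z_target - t_xyz[i - 1, 2])
            + np.sqrt(zs) * sig_z * rng.normal()
        )
    b = np.clip(b, -3.0 * sqrt_lam, 3.0 * sqrt_lam)

    ep_idx = np.full(n_total, -1, dtype=int)
    for i, (s, e) in enumerate(epochs):
        ep_idx[(times >= s) & (times < e)] = i
    keep = ep_idx >= 0
    frames = np.nonzero(keep)[0]
    pose3d = np.stack(
        [
            synthesize_pose(model, b[i], yaw_rotation(yaw[i]), t_xyz[i])
            for i in frames
        ]
    )
    return KinematicsGroundTruth(
        epochs=epochs,
        frame_rate=frame_rate,
        frame=frames,
        time_s=times[keep],
        epoch_index=ep_idx[keep],
        b_true=b[keep],
        yaw_true=yaw[keep],
        t_true=t_xyz[keep],
        pose3d_true=pose3d,
        model=model,
    )


# ---------------------------------------------------------------------------
# cameras and 2D observations
# ---------------------------------------------------------------------------


def default_cameras(
    n_cameras: int = 4,
    distance_cm: float = 60.0,
    elevation_deg: float = 30.0,
    focal_px: float = 1500.0,
    center_px: tuple[float, float] = (640.0, 512.0),
) -> list[CameraModel]:
    """Four pinhole cameras at azimuths 0/90/180/270 deg, 30 deg elevation,
    all looking at the arena centre."""
    target = np.array([0.0, 0.0, 2.0])
    cams = []
    el = np.radians(elevation_deg)
    for i in range(n_cameras):
        az = 2 * np.pi * i / n_cameras
        pos = target + distance_cm * np.array(
            [np.cos(az) * np.cos(el), np.sin(az) * np.cos(el), np.sin(el)]
        )
        fwd = target - pos
        fwd /= np.linalg.norm(fwd)
        right = np.cross(fwd, np.array([0.0, 0.0, 1.0]))
        right /= np.linalg.norm(right)
        down = np.cross(fwd, right)
        rot = np.stack([right, down, fwd])  # world -> camera rows
        kmat = np.array(
            [
                [focal_px, 0.0, center_px[0]],
                [0.0, focal_px, center_px[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        proj = kmat @ np.hstack([rot, -(rot @ pos)[:, None]])
        cams.append(CameraModel(cam_id=f"cam{i}", projection=proj))
    return cams


def project_landmarks(
    kinematics: KinematicsGroundTruth,
    cameras: list[CameraModel],
    noise_sd_px: float = 2.0,
    outlier_rate: float = 0.01,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project the true poses to every camera and corrupt the detections.

    Each visible landmark gets isotropic Gaussian pixel noise; a fraction
    ``outlier_rate`` is displaced by 20-40x the noise SD in a random
    direction, and a fraction ``missing_rate`` is dropped.  Returns the
    observation table (frame, camera, landmark, x, y, confidence) and the
    corruption log (frame, camera, landmark, kind).
    """
    if len(cameras) < 2:
        raise InvalidArgumentError("need >= 2 cameras")
    for rate in (outlier_rate, missing_rate):
        if not 0.0 <= rate < 1.0:
            raise InvalidArgumentError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    names = kinematics.model.landmark_names
    n_f, n_lm = kinematics.n_frames, len(names)
    frames_rep = np.repeat(kinematics.frame, n_lm)
    lm_rep = np.tile(np.arange(n_lm), n_f)
    obs_parts = []
    log_parts = []
    unit_noise = max(noise_sd_px, 1.0)
    for cam in cameras:
        px = cam.project(kinematics.pose3d_true.reshape(-1, 3))
        if noise_sd_px > 0:
            px = px + rng.normal(scale=noise_sd_px, size=px.shape)
        n_rows = px.shape[0]
        is_out = rng.random(n_rows) < outlier_rate
        is_miss = rng.random(n_rows) < missing_rate
        is_out &= ~is_miss  # missing wins
        mag = rng.uniform(20.0, 40.0, size=int(is_out.sum())) * unit_noise
        ang = rng.uniform(0.0, 2 * np.pi, size=int(is_out.sum()))
        px[is_out, 0] += mag * np.cos(ang)
        px[is_out, 1] += mag * np.sin(ang)
        keep = ~is_miss
        obs_parts.append(
            pd.DataFrame(
                {
                    "frame": frames_rep[keep],
                    "camera": cam.cam_id,
                    "landmark": np.asarray(names)[lm_rep[keep]],
                    "x": px[keep, 0],
                    "y": px[keep, 1],
                    "confidence": np.where(is_out[keep], 0.95, 0.95),
                }
            )
        )
        for kind, mask in (("outlier", is_out), ("missing", is_miss)):
            if mask.any():
                log_parts.append(
                    pd.DataFrame(
                        {
                            "frame": frames_rep[mask],
                            "camera": cam.cam_id,
                            "landmark": np.asarray(names)[lm_rep[mask]],
                            "kind": kind,
                        }
                    )
                )
    observations = pd.concat(obs_parts, ignore_index=True)
    observations = observations.sort_values(
        ["frame", "camera", "landmark"], kind="stable"
    ).reset_index(drop=True)
    log = (
        pd.concat(log_parts, ignore_index=True)
        if log_parts
        else pd.DataFrame(columns=["frame", "camera", "landmark", "kind"])
    )
    return observations, log


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


@dataclass
class TuningSpec:
    """Log-linear tuning of one unit: rate = exp(b0 + b_ud*UD + b_om*OM).

    ``beta_ud`` weights the z-scored up/down posture score (body arch by
    default; positive = look-up unit, negative = look-down), ``beta_om``
    the z-scored overall motion; ``lag_s`` delays the behavioral drive.
    ``baseline_log_rate`` is log firing rate in Hz.
    """

    unit: str
    baseline_log_rate: float = float(np.log(5.0))
    beta_ud: float = 0.5
    beta_om: float = 0.5
    lag_s: float = 0.0


def default_tuning_population(
    n_units: int,
    beta_ud: float = 0.5,
    beta_om: float = 0.5,
    baseline_hz: float = 5.0,
    lag_s: float = 0.0,
) -> list[TuningSpec]:
    """Half look-up (+beta_ud), half look-down (-beta_ud) units, all
    positively motion-modulated."""
    return [
        TuningSpec(
            unit=f"u{i:03d}",
            baseline_log_rate=float(np.log(baseline_hz)),
            beta_ud=beta_ud if i % 2 == 0 else -beta_ud,
            beta_om=beta_om,
            lag_s=lag_s,
        )
        for i in range(n_units)
    ]


def ground_truth_behavior(kinematics: KinematicsGroundTruth) -> BehavioralState:
    """Behavioral state computed from the noiseless ground-truth poses."""
    model = kinematics.model
    fits = [
        PoseFit(
            frame=int(kinematics.frame[i]),
            b=kinematics.b_true[i],
            rot=yaw_rotation(kinematics.yaw_true[i]),
            t=kinematics.t_true[i],
            cost=0.0,
            data_term=0.0,
            inlier_mask=np.ones(model.n_landmarks, dtype=bool),
            corrected_pose=kinematics.pose3d_true[i],
            n_iter=0,
            converged=True,
        )
        for i in range(kinematics.n_frames)
    ]
    return build_state(
        fits,
        kinematics.pose3d_true,
        model.landmark_names,
        kinematics.epochs,
        kinematics.frame_rate,
        frame=kinematics.frame,
        time_s=kinematics.time_s,
    )


def generate_spikes(
    behavior: BehavioralState,
    tuning: TuningSpec,
    epochs: list[tuple[float, float]],
    bin_s: float = 1.0 / 15.0,
    seed: int = 0,
    ud_variable: str = "Bar",
    om_variable: str = "OM",
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Inhomogeneous Poisson spike train driven by posture and motion.

    The per-bin rate is ``exp(b0 + beta_ud * UD + beta_om * OM)`` with UD
    and OM the z-scored behavior averaged into bins (optionally delayed by
    ``lag_s``); counts are Poisson and spike times uniform within bins.
    Returns (spike times, per-epoch count vectors).
    """
    from .neural_coupling import bin_spikes

    if bin_s <= 0:
        raise InvalidArgumentError("bin_s must be > 0")
    rng = np.random.default_rng(seed)
    empty = bin_spikes(
        np.array([]), epochs, bin_s, behavior=behavior,
        covariate_names=(ud_variable, om_variable),
    )
    lag_bins = int(round(tuning.lag_s / bin_s))
    spike_times = []
    counts_out = []
    for ep_i, (start, _) in enumerate(epochs):
        ud = np.nan_to_num(empty.covariates[ud_variable][ep_i], nan=0.0)
        om = np.nan_to_num(empty.covariates[om_variable][ep_i], nan=0.0)
        if lag_bins > 0:
            ud = np.concatenate([np.full(lag_bins, ud[0] if len(ud) else 0.0),
                                 ud[:-lag_bins]]) if len(ud) > lag_bins else ud
            om = np.concatenate([np.full(lag_bins, om[0] if len(om) else 0.0),
                                 om[:-lag_bins]]) if len(om) > lag_bins else om
        log_rate = (
            tuning.baseline_log_rate + tuning.beta_ud * ud + tuning.beta_om * om
        )
        if np.any(log_rate > 20.0):
            raise InvalidTuningError(f"unit {tuning.unit}: log-rate overflow")
        lam = np.exp(log_rate) * bin_s
        c = rng.poisson(lam)
        counts_out.append(c.astype(int))
        for k, n_sp in enumerate(c):
            if n_sp:
                t0 = start + k * bin_s
                spike_times.append(t0 + rng.uniform(0.0, bin_s, size=n_sp))
    times = (
        np.sort(np.concatenate(spike_times)) if spike_times else np.array([])
    )
    return times, counts_out


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSession:
    """A complete simulated recording, reproducible from its seed."""

    kinematics: KinematicsGroundTruth
    behavior: BehavioralState
    observations2d: pd.DataFrame
    corruption: pd.DataFrame
    cameras: list[CameraModel]
    spikes: dict[str, np.ndarray]
    counts: dict[str, list[np.ndarray]]
    tuning: list[TuningSpec]
    seed: int

    @property
    def epochs(self) -> list[tuple[float, float]]:
        return self.kinematics.epochs


def make_session(
    duration_s: float = 600.0,
    n_units: int = 20,
    seed: int = 0,
    frame_rate: float = 15.0,
    model: ShapeModel | None = None,
    motif_params: MotifParams | None = None,
    cameras: list[CameraModel] | None = None,
    noise_sd_px: float = 2.0,
    outlier_rate: float = 0.01,
    missing_rate: float = 0.02,
    tuning: list[TuningSpec] | None = None,
    spike_bin_s: float = 1.0 / 15.0,
) -> SyntheticSession:
    """Generate kinematics, corrupted 2D observations and tuned spikes."""
    rng = np.random.default_rng(seed)
    kin = generate_kinematics(
        duration_s, frame_rate, model, motif_params, seed=int(rng.integers(2**31))
    )
    cams = cameras or default_cameras()
    obs, log = project_landmarks(
        kin, cams, noise_sd_px, outlier_rate, missing_rate,
        seed=int(rng.integers(2**31)),
    )
    behavior = ground_truth_behavior(kin)
    tuning = tuning or default_tuning_population(n_units)
    spikes = {}
    counts = {}
    for spec in tuning:
        st, c = generate_spikes(
            behavior, spec, kin.epochs, bin_s=spike_bin_s,
            seed=int(rng.integers(2**31)),
        )
        spikes[spec.unit] = st
        counts[spec.unit] = c
    return SyntheticSession(
        kinematics=kin,
        behavior=behavior,
        observations2d=obs,
        corruption=log,
        cameras=cams,
        spikes=spikes,
        counts=counts,
        tuning=tuning,
        seed=seed,
    )
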