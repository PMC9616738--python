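"""Behavioral state variables derived from corrected 3D poses.

Fourteen variables summarize posture and movement at the video frame rate:

======  =====================================================================
Hel     head elevation: angle (deg) of the neck->nose vector above horizontal
Hlr     head left/right: signed horizontal angle (deg) between the body
        midline (tail_base->neck) and the neck->nose vector; positive = left
Bar     body arch           (score on eigenpose 1)
Blr     body left/right bend (score on eigenpose 2)
Blu     body lunge           (score on eigenpose 3)
Re      rearing: z-coordinate of the body translation t
dHel..dRe  temporal derivatives of the six postures (per second)
Lc      locomotion: x-y displacement of the body centre between consecutive
        frames (arena units per frame step)
OM      overall motion: summed 3D displacement of all landmarks between
        consecutive frames
======  =====================================================================

Differences between consecutive frames are assigned to the later frame, so
the first frame of every recording epoch is masked for all movement
variables.  All variables are z-scored per session before any coupling
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InvalidArgumentError, SchemaError
from .pose_reconstruction import PoseFit

POSTURE_VARS = ("Hel", "Hlr", "Bar", "Blr", "Blu", "Re")
MOVEMENT_VARS = ("dHel", "dHlr", "dBar", "dBlr", "dBlu", "dRe", "Lc", "OM")
STATE_VARS = POSTURE_VARS + MOVEMENT_VARS


@dataclass
class BehavioralState:
    """Per-frame behavioral state time series.

    ``values`` holds the 14 variables (columns ``STATE_VARS``); ``mask`` is
    True where a value is defined.  ``raw`` keeps the pre-z-score copy.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    frame: np.ndarray
    time_s: np.ndarray
    epoch: np.ndarray
    frame_rate: float
    zscored: bool = False
    raw: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(STATE_VARS) - set(self.values.columns)
        if missing:
            raise SchemaError(f"state missing variables {sorted(missing)}")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def variable(self, name: str, masked: bool = True) -> np.ndarray:
        v = self.values[name].to_numpy(dtype=float)
        if masked:
            v = np.where(self.mask[name].to_numpy(), v, np.nan)
        return v


def assign_epochs(time_s: np.ndarray, epochs: list[tuple[float, float]]) -> np.ndarray:
    """Index of the epoch containing each time, -1 outside all epochs."""
    out = np.full(len(time_s), -1, dtype=int)
    for i, (start, end) in enumerate(epochs):
        out[(time_s >= start) & (time_s < end)] = i
    return out


def compute_postures(
    fits: list[PoseFit],
    poses: np.ndarray,
    landmark_names: tuple[str, ...],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Six posture variables from corrected poses and their fits.

    Returns (values, mask) frames of columns ``POSTURE_VARS``.  Frames with
    coincident nose/neck (or neck/tail-base) landmarks are masked for the
    head angles.
    """
    if len(fits) != poses.shape[0]:
        raise InvalidArgumentError("fits and poses must align")
    idx = {name: i for i, name in enumerate(landmark_names)}
    for req in ("nose", "neck", "tail_base"):
        if req not in idx:
            raise SchemaError(f"landmark set must include {req!r}")
    nose = poses[:, idx["nose"], :]
    neck = poses[:, idx["neck"], :]
    tail = poses[:, idx["tail_base"], :]

    v = nose - neck  # head vector
    m = neck - tail  # body midline
    v_norm = np.linalg.norm(v, axis=1)
    m_xy = np.linalg.norm(m[:, :2], axis=1)
    ok = (v_norm > 1e-9) & (m_xy > 1e-9)

    with np.errstate(invalid="ignore", divide="ignore"):
        hel = np.degrees(np.arctan2(v[:, 2], np.linalg.norm(v[:, :2], axis=1)))
        # positive Hlr = head turned to the animal's left (counter-clockwise
        # from above relative to the midline)
        cross = m[:, 0] * v[:, 1] - m[:, 1] * v[:, 0]
        dot = m[:, 0] * v[:, 0] + m[:, 1] * v[:, 1]
        hlr = np.degrees(np.arctan2(cross, dot))

    b = np.stack([f.b for f in fits])
    if b.shape[1] < 3:
        raise InvalidArgumentError("shape model must expose >= 3 eigenpose scores")
    t = np.stack([f.t for f in fits])
    values = pd.DataFrame(
        {
            "Hel": hel,
            "Hlr": hlr,
            "Bar": b[:, 0],
            "Blr": b[:, 1],
            "Blu": b[:, 2],
            "Re": t[:, 2],
        }
    )
    mask = pd.DataFrame(
        {name: (ok if name in ("Hel", "Hlr") else np.ones(len(values), bool))
         for name in POSTURE_VARS}
    )
    return values, mask


def compute_movements(
    postures: pd.DataFrame,
    posture_mask: pd.DataFrame,
    fits: list[PoseFit],
    poses: np.ndarray,
    epoch: np.ndarray,
    frame_rate: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eight movement variables from consecutive-frame differences.

    Posture derivatives are scaled by the frame rate (units per second);
    locomotion and overall motion are raw per-step displacements.  All are
    masked on the first frame of each epoch (and wherever the source
    posture is masked on either frame).
    """
    n = len(postures)
    same_epoch = np.zeros(n, dtype=bool)
    same_epoch[1:] = (epoch[1:] == epoch[:-1]) & (epoch[1:] >= 0)

    values = {}
    masks = {}
    for name in POSTURE_VARS:
        x = postures[name].to_numpy(dtype=float)
        d = np.full(n, np.nan)
        d[1:] = (x[1:] - x[:-1]) * frame_rate
        m = posture_mask[name].to_numpy()
        dm = same_epoch.copy()
        dm[1:] &= m[1:] & m[:-1]
        dm[0] = False
        values["d" + name] = d
        masks["d" + name] = dm

    t = np.stack([f.t for f in fits])
    lc = np.full(n, np.nan)
    lc[1:] = np.linalg.norm(t[1:, :2] - t[:-1, :2], axis=1)
    om = np.full(n, np.nan)
    om[1:] = np.linalg.norm(poses[1:] - poses[:-1], axis=2).sum(axis=1)
    for name, series in (("Lc", lc), ("OM", om)):
        values[name] = series
        masks[name] = same_epoch.copy()

    return pd.DataFrame(values), pd.DataFrame(masks)


def build_state(
    fits: list[PoseFit],
    poses: np.ndarray,
    landmark_names: tuple[str, ...],
    epochs: list[tuple[float, float]],
    frame_rate: float,
    frame: np.ndarray | None = None,
    time_s: np.ndarray | None = None,
    zscore: bool = True,
) -> BehavioralState:
    """Assemble the full 14-variable state from fits and corrected poses."""
    n = poses.shape[0]
    if frame is None:
        frame = np.array([f.frame for f in fits], dtype=int)
    if time_s is None:
        time_s = frame / frame_rate
    epoch = assign_epochs(time_s, epochs)
    post_v, post_m = compute_postures(fits, poses, landmark_names)
    mov_v, mov_m = compute_movements(post_v, post_m, fits, poses, epoch, frame_rate)
    values = pd.concat([post_v, mov_v], axis=1)[list(STATE_VARS)]
    mask = pd.concat([post_m, mov_m], axis=1)[list(STATE_VARS)]
    in_epoch = epoch >= 0
    mask = mask.mul(pd.Series(in_epoch), axis=0)
    state = BehavioralState(
        values=values,
        mask=mask,
        frame=frame,
        time_s=np.asarray(time_s, dtype=float),
        epoch=epoch,
        frame_rate=frame_rate,
        zscored=False,
        raw=values.copy(),
    )
    return zscore_state(state) if zscore else state


def zscore_state(state: BehavioralState) -> BehavioralState:
    """Z-score each variable over its unmasked frames (session-wide).

    Zero-variance variables are zero-filled and flagged.  Idempotent up to
    numerical precision.
    """
    values = state.values.copy()
    flags = dict(state.flags)
    for name in STATE_VARS:
        m = state.mask[name].to_numpy()
        if int(m.sum()) < 2:
            raise InvalidArgumentError(f"{name}: fewer than 2 unmasked frames")
        x = values[name].to_numpy(dtype=float)
        mu = float(np.mean(x[m]))
        sd = float(np.std(x[m]))
        if sd < 1e-12:
            values[name] = np.where(m, 0.0, np.nan)
            flags[f"{name}_zero_variance"] = True
        else:
            values[name] = np.where(m, (x - mu) / sd, np.nan)
    return BehavioralState(
        values=values,
        mask=state.mask.copy(),
        frame=state.frame,
        time_s=state.time_s,
        epoch=state.epoch,
        frame_rate=state.frame_rate,
        zscored=True,
        raw=state.raw if state.raw is not None else state.values.copy(),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# variable grouping: pairwise MI matrix + hierarchical clustering
# ---------------------------------------------------------------------------


def variable_mi_matrix(
    state: BehavioralState, n_quantiles: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Pairwise bias-corrected mutual information between the 14 variables.

    Each variable is quantile-discretized into ``n_quantiles`` equal-
    occupancy bins; off-diagonal entries are corrected MI in bits, the
    diagonal carries the (corrected) discrete entropies.
    """
    from .neural_coupling import mutual_information, quantile_discretize

    if n_quantiles < 2:
        raise InvalidArgumentError("n_quantiles must be >= 2")
    names = list(STATE_VARS)
    labels = {}
    masks = {}
    for name in names:
        m = state.mask[name].to_numpy()
        masks[name] = m
        x = state.values[name].to_numpy(dtype=float)
        lab = np.full(len(x), -1, dtype=int)
        lab[m] = quantile_discretize(x[m], n_quantiles)
        labels[name] = lab
    mat = np.zeros((len(names), len(names)))
    rng = np.random.default_rng(seed)
    for i, a in enumerate(names):
        for j in range(i, len(names)):
            bname = names[j]
            both = masks[a] & masks[bname]
            est = mutual_information(
                labels[a][both], labels[bname][both],
                seed=int(rng.integers(2**31)),
            )
            mat[i, j] = mat[j, i] = est.corrected
    return pd.DataFrame(mat, index=names, columns=names)


def cluster_variables(
    mi_matrix: pd.DataFrame, n_fine: int = 5
) -> dict:
    """Agglomerative (WPGMA) clustering of the MI matrix.

    MI is converted to a dissimilarity ``d_ij = 1 - MI_ij / max_offdiag``
    (negative corrected MI clipped to 0 first).  Returns the linkage tree
    plus flat partitions at 2 clusters (the posture/movement split) and at
    ``n_fine`` clusters.
    """
    mat = mi_matrix.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise SchemaError("MI matrix must be symmetric")
    names = list(mi_matrix.columns)
    off = ~np.eye(len(names), dtype=bool)
    mi = np.clip(mat, 0.0, None)
    peak = mi[off].max()
    if peak <= 0:
        raise InvalidArgumentError("MI matrix has no positive off-diagonal entries")
    dist = 1.0 - mi / peak
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="weighted")
    return {
        "linkage": link,
        "variables": names,
        "labels_2": hierarchy.fcluster(link, t=2, criterion="maxclust"),
        "labels_fine": hierarchy.fcluster(link, t=n_fine, criterion="maxclust"),
    }
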