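"""End-to-end orchestration: simulate -> train-ssm -> reconstruct ->
behavior -> couple -> classify, with uniform file I/O and seeding.

All artifacts are plain text: landmark observations, spike times and
epochs as CSV, camera calibration and the shape model as JSON.  Every
stochastic stage takes its seed from :class:`PipelineConfig`, so a full
run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as synth
from .behavior_state import (
    STATE_VARS,
    build_state,
    cluster_variables,
    variable_mi_matrix,
)
from .errors import SchemaError
from .neural_coupling import (
    CC_BIN_S,
    MI_BIN_S,
    bin_spikes,
    crosscorr_significance,
    fit_predictive_model,
    mutual_information,
    pairwise_mi,
    quantile_discretize,
    shift_control,
    top_code_counts,
)
from .pose_reconstruction import (
    CameraModel,
    ReconstructionConfig,
    fits_to_frame,
    reconstruct_series,
)
from .shape_model import (
    LANDMARK_NAMES,
    PoseSet,
    ShapeModel,
    procrustes_align,
    train_ssm,
)
from .unit_typing import (
    bivariate_rate_histogram,
    build_adjacency,
    label_communities,
    newman_communities,
    partition_to_frame,
)

log = logging.getLogger("pose2thal")


@dataclass
class PipelineConfig:
    """All pipeline knobs, defaulting to the analysis constants.

    Frame rate 15 Hz; 0.67 s bins for MI/prediction and 0.0667 s bins for
    cross-correlograms; alpha = 0.01; 1000 permutations for the CC null;
    100 shifts for the coherence null; 5 quantile bins.
    """

    out_dir: str = "."
    seed: int = 0
    condition: str = "dark"
    frame_rate: float = 15.0
    duration_s: float = 600.0
    n_units: int = 20
    mi_bin_s: float = MI_BIN_S
    cc_bin_s: float = CC_BIN_S
    alpha: float = 0.01
    chi2_prob: float = 0.99
    n_quantiles: int = 5
    n_perm: int = 1000
    n_shifts: int = 100
    cc_variables: tuple[str, ...] = ("Bar", "OM")
    n_eigenposes: int = 3
    noise_sd_px: float = 2.0
    outlier_rate: float = 0.01
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("frame_rate", "duration_s", "mi_bin_s", "cc_bin_s"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_session(session: synth.SyntheticSession, out_dir: str | Path) -> dict:
    """Write a synthetic session's input files (CSV + JSON) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.observations2d.to_csv(out / "landmarks.csv", index=False)
    (out / "calibration.json").write_text(
        json.dumps([c.to_dict() for c in session.cameras])
    )
    spike_rows = [
        {"unit": u, "time_s": t}
        for u, times in session.spikes.items()
        for t in times
    ]
    pd.DataFrame(spike_rows, columns=["unit", "time_s"]).to_csv(
        out / "spikes.csv", index=False
    )
    pd.DataFrame(session.epochs, columns=["start_s", "end_s"]).to_csv(
        out / "epochs.csv", index=False
    )
    session.corruption.to_csv(out / "corruption_log.csv", index=False)
    truth = pd.DataFrame(
        {
            "frame": session.kinematics.frame,
            "time_s": session.kinematics.time_s,
            "yaw": session.kinematics.yaw_true,
            "tx": session.kinematics.t_true[:, 0],
            "ty": session.kinematics.t_true[:, 1],
            "tz": session.kinematics.t_true[:, 2],
        }
    )
    for i in range(session.kinematics.b_true.shape[1]):
        truth[f"b{i + 1}"] = session.kinematics.b_true[:, i]
    truth.to_csv(out / "ground_truth.csv", index=False)
    return {name: str(out / name) for name in (
        "landmarks.csv", "calibration.json", "spikes.csv", "epochs.csv")}


def read_cameras(path: str | Path) -> list[CameraModel]:
    return [CameraModel.from_dict(d) for d in json.loads(Path(path).read_text())]


def read_epochs(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    if not {"start_s", "end_s"} <= set(df.columns):
        raise SchemaError("epochs file needs start_s,end_s columns")
    return [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]


def read_spikes(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    if not {"unit", "time_s"} <= set(df.columns):
        raise SchemaError("spikes file needs unit,time_s columns")
    return {
        str(u): np.sort(g["time_s"].to_numpy(dtype=float))
        for u, g in df.groupby("unit")
    }


def validate_inputs(paths: dict[str, str | Path]) -> dict[str, dict]:
    """Schema checks for every input file; report-only (never raises).

    Checks column sets, the 11-landmark set, epoch sanity (positive,
    non-overlapping) and camera matrix ranks.
    """
    report: dict[str, dict] = {}

    def check(name, fn):
        try:
            msg = fn()
            report[name] = {"ok": True, "detail": msg or "pass"}
        except Exception as exc:  # report-only by contract
            report[name] = {"ok": False, "detail": str(exc)}

    if "landmarks" in paths:
        def _landmarks():
            df = pd.read_csv(paths["landmarks"])
            need = {"frame", "camera", "landmark", "x", "y"}
            if not need <= set(df.columns):
                raise SchemaError(f"missing columns {sorted(need - set(df.columns))}")
            seen = set(df["landmark"].unique())
            if seen != set(LANDMARK_NAMES):
                raise SchemaError("landmark set mismatch")
            return f"{len(df)} rows"
        check("landmarks", _landmarks)
    if "calibration" in paths:
        check("calibration", lambda: f"{len(read_cameras(paths['calibration']))} cameras")
    if "epochs" in paths:
        def _epochs():
            eps = read_epochs(paths["epochs"])
            arr = np.array(eps)
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise SchemaError("epoch with non-positive duration")
            order = np.argsort(arr[:, 0])
            if np.any(arr[order][1:, 0] < arr[order][:-1, 1]):
                raise SchemaError("overlapping epochs")
            return f"{len(eps)} epochs"
        check("epochs", _epochs)
    if "spikes" in paths:
        check("spikes", lambda: f"{len(read_spikes(paths['spikes']))} units")
    return report


# ---------------------------------------------------------------------------
# per-stage drivers
# ---------------------------------------------------------------------------


def couple_units(
    spikes: dict[str, np.ndarray],
    state,
    epochs: list[tuple[float, float]],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Cross-correlation, MI and encoding results for every unit.

    Per unit: CC significance against each variable in
    ``config.cc_variables`` (0.0667 s bins, epoch-permutation null); MI of
    the top-coded 0.67 s counts with the (Bar, OM) pair plus the
    single-variable shuffle control; boosted-tree encoding from (Bar, OM)
    with its half-swap shift control.
    """
    rows = []
    rng = np.random.default_rng(config.seed)
    for unit, times in spikes.items():
        row: dict = {"unit": unit}
        cc = bin_spikes(
            times, epochs, config.cc_bin_s, behavior=state,
            covariate_names=config.cc_variables, unit=unit,
        )
        for var in config.cc_variables:
            res = crosscorr_significance(
                cc.counts, cc.covariates[var], bin_s=config.cc_bin_s,
                n_perm=config.n_perm, seed=int(rng.integers(2**31)),
            )
            row[f"cc_peak_{var}"] = res.peak_value
            row[f"cc_lag_{var}"] = res.peak_lag_s
            row[f"cc_sig_{var}"] = res.significant
        mi_bins = bin_spikes(
            times, epochs, config.mi_bin_s, behavior=state,
            covariate_names=("Bar", "OM"), unit=unit,
        )
        counts = top_code_counts(mi_bins.concatenated())
        bar = np.nan_to_num(mi_bins.concatenated("Bar"), nan=0.0)
        om = np.nan_to_num(mi_bins.concatenated("OM"), nan=0.0)
        la = quantile_discretize(bar, config.n_quantiles)
        lb = quantile_discretize(om, config.n_quantiles)
        mi2, mi1 = pairwise_mi(
            counts, la, lb, seed=int(rng.integers(2**31)), names=("Bar", "OM")
        )
        row["mi2_bits"] = mi2.corrected
        row["mi1_bits"] = mi1.corrected
        feats = np.column_stack([bar, om])
        enc = fit_predictive_model(
            feats, counts, kind="counts", seed=int(rng.integers(2**31)),
            direction="encode", predictors=("Bar", "OM"),
        )
        enc_shift = fit_predictive_model(
            shift_control(feats), counts, kind="counts",
            seed=int(rng.integers(2**31)), direction="encode",
            predictors=("Bar", "OM"),
        )
        row["encode_acc"] = enc.accuracy
        row["encode_shift_acc"] = enc_shift.accuracy
        rows.append(row)
    return pd.DataFrame(rows)


def classify_units(
    spikes: dict[str, np.ndarray],
    state,
    epochs: list[tuple[float, float]],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, object]:
    """Bivariate histograms -> adjacency -> communities -> semantic labels."""
    hists = []
    for unit, times in spikes.items():
        bins = bin_spikes(
            times, epochs, config.mi_bin_s, behavior=state,
            covariate_names=("Bar", "OM"), unit=unit,
        )
        hists.append(
            bivariate_rate_histogram(
                bins.concatenated(),
                np.nan_to_num(bins.concatenated("Bar"), nan=0.0),
                np.nan_to_num(bins.concatenated("OM"), nan=0.0),
                n_bins=config.n_quantiles,
                bin_s=config.mi_bin_s,
                unit=unit,
            )
        )
    graph, _, median = build_adjacency(hists)
    partition = newman_communities(graph, median_threshold=median)
    partition = label_communities(partition, hists)
    return partition_to_frame(partition, hists), partition


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a synthetic session and write all artifacts.

    Returns a machine-readable summary with per-stage outputs; halts with
    the stage name on failure (partial outputs are retained).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config), "stages": {}}
    stage = "simulate"
    try:
        session = synth.make_session(
            duration_s=config.duration_s,
            n_units=config.n_units,
            seed=config.seed,
            frame_rate=config.frame_rate,
            noise_sd_px=config.noise_sd_px,
            outlier_rate=config.outlier_rate,
            missing_rate=config.missing_rate,
        )
        write_session(session, out)
        summary["stages"][stage] = {"n_frames": session.kinematics.n_frames,
                                    "n_units": len(session.spikes)}

        stage = "train-ssm"
        rng = np.random.default_rng(config.seed + 1)
        poses = synth.sample_poses(session.kinematics.model, 350,
                                   seed=int(rng.integers(2**31)))
        aligned, _ = procrustes_align(PoseSet(poses))
        model = train_ssm(aligned, n_eigenposes=config.n_eigenposes)
        model.save(out / "ssm.json")
        summary["stages"][stage] = {
            "eigenvalues": model.eigenvalues.tolist(),
            "noise_variance": model.noise_variance,
        }

        stage = "reconstruct"
        rec_cfg = ReconstructionConfig(
            alpha=config.alpha, chi2_prob=config.chi2_prob
        )
        poses3d, fits, _ = reconstruct_series(
            session.observations2d, session.cameras, model, rec_cfg
        )
        fits_to_frame(fits).to_csv(out / "fits.csv", index=False)
        summary["stages"][stage] = {"n_frames": len(fits)}

        stage = "behavior"
        state = build_state(
            fits, poses3d, model.landmark_names, session.epochs,
            config.frame_rate,
        )
        state.values.assign(
            frame=state.frame, epoch=state.epoch
        ).to_csv(out / "behavior.csv", index=False)
        mi = variable_mi_matrix(state, config.n_quantiles, seed=config.seed + 2)
        mi.to_csv(out / "mi_matrix.csv")
        tree = cluster_variables(mi)
        (out / "dendrogram.json").write_text(json.dumps({
            "variables": tree["variables"],
            "linkage": np.asarray(tree["linkage"]).tolist(),
            "labels_2": tree["labels_2"].tolist(),
        }))
        summary["stages"][stage] = {"variables": list(STATE_VARS)}

        stage = "couple"
        coupling = couple_units(session.spikes, state, session.epochs, config)
        coupling.to_csv(out / "coupling.csv", index=False)
        summary["stages"][stage] = {
            "n_significant_Bar": int(coupling.get(
                "cc_sig_Bar", pd.Series(dtype=bool)).sum()),
        }

        stage = "classify"
        labels, partition = classify_units(
            session.spikes, state, session.epochs, config
        )
        labels.to_csv(out / "labels.csv", index=False)
        summary["stages"][stage] = {
            "n_communities": partition.n_communities,
            "modularity": partition.modularity,
        }
    except Exception as exc:
        log.error("pipeline halted at stage %s: %s", stage, exc)
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        (out / "summary.json").write_text(json.dumps(summary, default=str))
        raise
    (out / "summary.json").write_text(json.dumps(summary, default=str))
    return summary
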