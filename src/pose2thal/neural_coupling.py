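"""Coupling between binned spiking and behavioral state variables.

The suite mirrors a standard single-unit/behavior workflow:

* spike counts binned within recording epochs (0.67 s bins for information
  and prediction analyses, 0.0667 s bins for cross-correlograms);
* mean-removed cross-correlograms over lags of +/-2 s with a permutation
  null built by shuffling the order of count epochs against the fixed
  behavior (1000 permutations, per-lag [0.0005, 0.9995] band);
* Welch magnitude-squared coherence with a circular-shift null
  (mean +/- 2 SD over 100 shifts);
* Shannon mutual information from quantile-discretized variables, with
  finite-sampling bias removed by quadratic extrapolation of the plug-in
  estimate over fractions {1, 1/2, 1/4} of the data;
* gradient-boosted tree encoding/decoding (learning rate 0.025, 500
  rounds, depth 3, gamma 1, Poisson log-likelihood loss for counts) with a
  half-swap shift control;
* per-unit Pearson similarity of cross-correlograms across two recording
  conditions with a unit-re-pairing shuffle null.

Lag sign convention: positive lag means spiking follows behavior (the
behavioral variable leads).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import pearsonr, rankdata

from .errors import InvalidArgumentError

CC_BIN_S = 1.0 / 15.0  # cross-correlogram bin (~0.0667 s)
MI_BIN_S = 0.67  # spike-count bin for MI and prediction


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


@dataclass
class BinnedCounts:
    """Spike counts of one unit binned within epochs, with aligned covariates.

    ``counts`` and each covariate are lists of per-epoch arrays; trailing
    partial bins are dropped.  Covariates are frame-wise behavioral values
    averaged within each bin (masked frames ignored).
    """

    unit: str
    bin_s: float
    counts: list[np.ndarray]
    covariates: dict[str, list[np.ndarray]] = field(default_factory=dict)
    n_spikes_outside: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.counts)

    @property
    def epoch_lengths(self) -> np.ndarray:
        return np.array([len(c) for c in self.counts], dtype=int)

    def concatenated(self, name: str | None = None) -> np.ndarray:
        if name is None:
            return np.concatenate(self.counts) if self.counts else np.array([])
        return np.concatenate(self.covariates[name])


def bin_spikes(
    spike_times: np.ndarray,
    epochs: list[tuple[float, float]],
    bin_s: float,
    behavior=None,
    covariate_names: tuple[str, ...] | None = None,
    unit: str = "unit",
) -> BinnedCounts:
    """Bin one unit's spike times within each epoch.

    ``behavior`` may be a :class:`~pose2thal.behavior_state.BehavioralState`
    whose variables are averaged into the same bins.  Spikes outside every
    epoch are ignored but counted.
    """
    if bin_s <= 0:
        raise InvalidArgumentError("bin_s must be > 0")
    starts = np.array([e[0] for e in epochs])
    ends = np.array([e[1] for e in epochs])
    order = np.argsort(starts)
    if np.any(starts[order][1:] < ends[order][:-1]):
        raise InvalidArgumentError("epochs must be non-overlapping")
    spike_times = np.asarray(spike_times, dtype=float)

    counts: list[np.ndarray] = []
    covs: dict[str, list[np.ndarray]] = {}
    names: tuple[str, ...] = ()
    if behavior is not None:
        from .behavior_state import STATE_VARS

        names = covariate_names or STATE_VARS
        covs = {n: [] for n in names}
    n_inside = 0
    for start, end in epochs:
        n_bins = int(np.floor((end - start) / bin_s + 1e-9))
        if n_bins == 0:
            counts.append(np.zeros(0, dtype=int))
            for n in names:
                covs[n].append(np.zeros(0))
            continue
        edges = start + np.arange(n_bins + 1) * bin_s
        c, _ = np.histogram(spike_times, bins=edges)
        counts.append(c.astype(int))
        n_inside += int(c.sum())
        if behavior is not None:
            in_ep = (behavior.time_s >= start) & (behavior.time_s < edges[-1])
            t_ep = behavior.time_s[in_ep]
            bin_idx = np.minimum(
                ((t_ep - start) / bin_s).astype(int), n_bins - 1
            )
            for n in names:
                v = behavior.variable(n, masked=True)[in_ep]
                acc = np.zeros(n_bins)
                cnt = np.zeros(n_bins)
                ok = np.isfinite(v)
                np.add.at(acc, bin_idx[ok], v[ok])
                np.add.at(cnt, bin_idx[ok], 1.0)
                with np.errstate(invalid="ignore"):
                    covs[n].append(np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan))
    outside = int(len(spike_times)) - int(
        sum(((spike_times >= s) & (spike_times < e)).sum() for s, e in epochs)
    )
    return BinnedCounts(
        unit=unit, bin_s=bin_s, counts=counts, covariates=covs,
        n_spikes_outside=outside,
    )


# ---------------------------------------------------------------------------
# cross-correlation and its permutation null
# ---------------------------------------------------------------------------


@dataclass
class CrossCorrResult:
    """Cross-correlogram with its epoch-permutation null band."""

    lags_s: np.ndarray
    curve: np.ndarray
    null_low: np.ndarray
    null_high: np.ndarray
    significant: bool
    peak_lag_s: float
    peak_value: float
    n_perm: int


def _epoch_curve(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson-style cross-correlation for one epoch at lags -L..L.

    ``curve[L + l] = sum_t x~_t y~_(t-l) / (n_overlap * sx * sy)``.
    """
    n = len(x)
    xt = x - x.mean()
    yt = y - y.mean()
    sx = xt.std()
    sy = yt.std()
    if sx < 1e-12 or sy < 1e-12:
        return np.zeros(2 * max_lag + 1)
    full = np.correlate(xt, yt, mode="full")
    lags = np.arange(-max_lag, max_lag + 1)
    vals = full[n - 1 + lags]
    n_overlap = n - np.abs(lags)
    return np.clip(vals / (n_overlap * sx * sy), -1.0, 1.0)


def cross_correlation(
    counts: list[np.ndarray],
    variable: list[np.ndarray],
    bin_s: float = CC_BIN_S,
    max_lag_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged mean-removed cross-correlogram in correlation units.

    Per-epoch curves (mean removed, normalized by the product of the
    epoch SDs and the per-lag overlap) are averaged weighted by epoch
    length.  Epochs shorter than ``2 * max_lag_s`` are excluded.
    """
    max_lag = int(round(max_lag_s / bin_s))
    lags_s = np.arange(-max_lag, max_lag + 1) * bin_s
    curves = []
    weights = []
    for x, y in zip(counts, variable):
        y = np.nan_to_num(np.asarray(y, dtype=float), nan=0.0)
        if len(x) < 2 * max_lag:
            continue
        curves.append(_epoch_curve(np.asarray(x, dtype=float), y, max_lag))
        weights.append(len(x))
    if not curves:
        raise InvalidArgumentError("no epoch long enough for the requested lag range")
    w = np.asarray(weights, dtype=float)
    curve = (np.stack(curves) * w[:, None]).sum(axis=0) / w.sum()
    return lags_s, curve


def crosscorr_significance(
    counts: list[np.ndarray],
    variable: list[np.ndarray],
    bin_s: float = CC_BIN_S,
    max_lag_s: float = 2.0,
    n_perm: int = 1000,
    seed: int = 0,
    band_mode: str = "pooled",
) -> CrossCorrResult:
    """Permutation test of the cross-correlogram.

    The null is built by randomly permuting the order of the count epochs
    while the behavioral epochs stay fixed, recomputing the whole lag
    curve each time; the observed curve is significant iff any lag falls
    outside the [0.0005, 0.9995] quantiles of the null.

    ``band_mode="pooled"`` (default) takes those quantiles over the pooled
    null values across permutations and lags, which resolves the nominal
    0.0005 tail with 1000 permutations; ``"per-lag"`` takes them lag by
    lag, whose finest attainable tail is ~1/(n_perm + 1).

    Count/behavior epoch pairs of unequal length are truncated to the
    shorter of the two; pairwise epoch curves are precomputed so each of
    the ``n_perm`` permutations is a cheap weighted average.
    """
    max_lag = int(round(max_lag_s / bin_s))
    lags_s = np.arange(-max_lag, max_lag + 1) * bin_s
    keep = [
        i for i in range(len(counts))
        if len(counts[i]) >= 2 * max_lag and len(variable[i]) >= 2 * max_lag
    ]
    n_ep = len(keep)
    if n_ep < 2:
        raise InvalidArgumentError("need >= 2 usable epochs for the permutation null")
    if n_ep < 10:
        warnings.warn("fewer than 10 epochs: permutation null is coarse")
    xs = [np.asarray(counts[i], dtype=float) for i in keep]
    ys = [np.nan_to_num(np.asarray(variable[i], dtype=float), nan=0.0) for i in keep]

    # pairwise[i, j] = curve of (count epoch i, behavior epoch j)
    pairwise = np.zeros((n_ep, n_ep, 2 * max_lag + 1))
    pair_w = np.zeros((n_ep, n_ep))
    for i in range(n_ep):
        for j in range(n_ep):
            n = min(len(xs[i]), len(ys[j]))
            pairwise[i, j] = _epoch_curve(xs[i][:n], ys[j][:n], max_lag)
            pair_w[i, j] = n

    diag = np.arange(n_ep)
    w_obs = pair_w[diag, diag]
    observed = (pairwise[diag, diag] * w_obs[:, None]).sum(axis=0) / w_obs.sum()

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n_ep) for _ in range(n_perm)])
    null_curves = pairwise[perms, diag[None, :]]  # (n_perm, n_ep, n_lags)
    null_w = pair_w[perms, diag[None, :]]
    null = (null_curves * null_w[:, :, None]).sum(axis=1) / null_w.sum(
        axis=1, keepdims=True
    )
    if band_mode == "pooled":
        lo = np.full(null.shape[1], np.quantile(null, 0.0005))
        hi = np.full(null.shape[1], np.quantile(null, 0.9995))
    elif band_mode == "per-lag":
        lo = np.quantile(null, 0.0005, axis=0)
        hi = np.quantile(null, 0.9995, axis=0)
    else:
        raise InvalidArgumentError(f"unknown band_mode {band_mode!r}")
    outside = (observed < lo) | (observed > hi)
    peak = int(np.argmax(np.abs(observed)))
    return CrossCorrResult(
        lags_s=lags_s,
        curve=observed,
        null_low=lo,
        null_high=hi,
        significant=bool(outside.any()),
        peak_lag_s=float(lags_s[peak]),
        peak_value=float(observed[peak]),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# magnitude-squared coherence
# ---------------------------------------------------------------------------


def magnitude_squared_coherence(
    counts: list[np.ndarray],
    variable: list[np.ndarray],
    fs: float = 15.0,
    n_shifts: int = 100,
    seed: int = 0,
    nperseg: int = 64,
) -> dict:
    """Welch MSC between counts and a behavioral variable, with shift null.

    Per-epoch coherence spectra are averaged weighted by epoch length;
    the null is the mean +/- 2 SD of the epoch-averaged MSC under random
    circular shifts of the variable within each epoch.
    """
    keep = [i for i in range(len(counts)) if len(counts[i]) >= nperseg]
    if not keep:
        raise InvalidArgumentError("no epoch reaches nperseg samples")
    xs = [np.asarray(counts[i], dtype=float) for i in keep]
    ys = [np.nan_to_num(np.asarray(variable[i], dtype=float), nan=0.0) for i in keep]
    w = np.array([len(x) for x in xs], dtype=float)

    def averaged(ys_local):
        specs = []
        for x, y in zip(xs, ys_local):
            f, cxy = signal.coherence(x, y, fs=fs, nperseg=nperseg)
            specs.append(cxy)
        return f, (np.stack(specs) * w[:, None]).sum(axis=0) / w.sum()

    freqs, msc = averaged(ys)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shifts, len(freqs)))
    for s in range(n_shifts):
        shifted = [np.roll(y, int(rng.integers(1, len(y)))) for y in ys]
        _, null[s] = averaged(shifted)
    return {
        "freqs": freqs,
        "msc": msc,
        "null_mean": null.mean(axis=0),
        "null_sd": null.std(axis=0),
        "above_null": msc > null.mean(axis=0) + 2 * null.std(axis=0),
    }


# ---------------------------------------------------------------------------
# mutual information with quadratic-extrapolation bias correction
# ---------------------------------------------------------------------------


@dataclass
class MIEstimate:
    """Plug-in and bias-corrected mutual information (bits)."""

    names: tuple[str, ...]
    plugin: float
    corrected: float
    subsample_n: np.ndarray
    subsample_mi: np.ndarray
    shuffle_control: float | None = None
    low_sample: bool = False


def quantile_discretize(series: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-occupancy integer labels from empirical quantiles.

    Ties are broken by stable rank (order of appearance), so occupancies
    are equal up to +/-1.  If the series has fewer distinct values than
    bins, the distinct values themselves become the labels (reduced bin
    count, with a warning).
    """
    if n_bins < 2:
        raise InvalidArgumentError("n_bins must be >= 2")
    x = np.asarray(series, dtype=float)
    n = len(x)
    distinct = np.unique(x)
    if len(distinct) < n_bins:
        warnings.warn(
            f"series has {len(distinct)} distinct values < {n_bins} bins; reduced"
        )
        return np.searchsorted(distinct, x).astype(int)
    ranks = rankdata(x, method="ordinal") - 1  # stable tie-break
    return (ranks * n_bins // n).astype(int)


def top_code_counts(counts: np.ndarray, quantile: float = 0.99) -> np.ndarray:
    """Clip spike counts at their ``quantile`` to bound the MI state space."""
    counts = np.asarray(counts)
    cap = int(np.ceil(np.quantile(counts, quantile)))
    return np.minimum(counts, cap)


def _plugin_mi_bits(r: np.ndarray, s: np.ndarray) -> float:
    """Plug-in MI (bits) from the joint frequency histogram of two labels."""
    ru, ri = np.unique(r, return_inverse=True)
    su, si = np.unique(s, return_inverse=True)
    joint = np.zeros((len(ru), len(su)))
    np.add.at(joint, (ri, si), 1.0)
    joint /= joint.sum()
    pr = joint.sum(axis=1, keepdims=True)
    ps = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pr @ ps)[nz])))


def mutual_information(
    labels_r: np.ndarray,
    labels_s: np.ndarray,
    n_partitions: int = 10,
    seed: int = 0,
    names: tuple[str, ...] = ("R", "S"),
) -> MIEstimate:
    """Bias-corrected MI between two discrete series.

    The plug-in estimate is computed on the full data and on random
    subsets of 1/2 and 1/4 of the samples (``n_partitions`` random subsets
    per fraction, averaged); a quadratic in inverse sample size is fit
    through the three points and evaluated at infinite data.  Because the
    extrapolation is linear in the entropies, extrapolating MI directly is
    identical to extrapolating H(R) and H(R|S) separately.
    """
    r = np.asarray(labels_r)
    s = np.asarray(labels_s)
    if len(r) != len(s):
        raise InvalidArgumentError("series must be aligned")
    n = len(r)
    rng = np.random.default_rng(seed)
    mi_full = _plugin_mi_bits(r, s)
    ns = [n]
    mis = [mi_full]
    for frac in (0.5, 0.25):
        m = max(int(round(n * frac)), 2)
        vals = [
            _plugin_mi_bits(r[idx], s[idx])
            for idx in (rng.choice(n, size=m, replace=False) for _ in range(n_partitions))
        ]
        ns.append(m)
        mis.append(float(np.mean(vals)))
    inv_n = 1.0 / np.asarray(ns, dtype=float)
    coeffs = np.polyfit(inv_n, np.asarray(mis), 2)
    corrected = float(np.polyval(coeffs, 0.0))
    return MIEstimate(
        names=names,
        plugin=mi_full,
        corrected=corrected,
        subsample_n=np.asarray(ns),
        subsample_mi=np.asarray(mis),
        low_sample=n < 100,
    )


def pairwise_mi(
    counts_labels: np.ndarray,
    var_a: np.ndarray,
    var_b: np.ndarray,
    n_shuffles: int = 1,
    seed: int = 0,
    names: tuple[str, ...] = ("A", "B"),
) -> tuple[MIEstimate, MIEstimate]:
    """MI between counts and a variable pair, plus the single-variable control.

    MI2 uses the joint (a, b) label.  The single-variable control shuffles
    the time order of one variable of the pair (either one), recomputes the
    pair MI, and keeps the larger of the two — both corrected identically.
    """
    a = np.asarray(var_a)
    b = np.asarray(var_b)
    r = np.asarray(counts_labels)
    rng = np.random.default_rng(seed)

    def joint_labels(x, y):
        ny = int(y.max()) + 1
        return x * ny + y

    mi2 = mutual_information(
        r, joint_labels(a, b), seed=int(rng.integers(2**31)), names=names
    )
    controls = []
    for which in range(2):
        vals = []
        for _ in range(n_shuffles):
            perm = rng.permutation(len(a))
            ja = joint_labels(a[perm], b) if which == 0 else joint_labels(a, b[perm])
            est = mutual_information(r, ja, seed=int(rng.integers(2**31)))
            vals.append(est)
        best = max(vals, key=lambda e: e.corrected)
        controls.append(best)
    control = max(controls, key=lambda e: e.corrected)
    mi1 = MIEstimate(
        names=names,
        plugin=control.plugin,
        corrected=control.corrected,
        subsample_n=control.subsample_n,
        subsample_mi=control.subsample_mi,
        shuffle_control=control.corrected,
    )
    return mi2, mi1


# ---------------------------------------------------------------------------
# gradient-boosted encoding / decoding
# ---------------------------------------------------------------------------


@dataclass
class PredictionResult:
    """Held-out prediction accuracy of a boosted-tree model."""

    direction: str
    predictors: tuple[str, ...]
    accuracy: float
    shift_accuracy: float | None = None


#: boosted-tree hyperparameters used throughout (CPU histogram method)
XGB_PARAMS = dict(
    learning_rate=0.025,
    n_estimators=500,
    max_depth=3,
    gamma=1.0,
    subsample=1.0,
    tree_method="hist",
)


def shift_control(features: np.ndarray) -> np.ndarray:
    """Swap the two halves of a feature series (rows), keeping within-half order."""
    x = np.asarray(features)
    if len(x) < 2:
        raise InvalidArgumentError("need >= 2 bins")
    half = len(x) // 2
    return np.concatenate([x[half:], x[:half]], axis=0)


def fit_predictive_model(
    features: np.ndarray,
    target: np.ndarray,
    kind: str = "counts",
    seed: int = 0,
    direction: str = "encode",
    predictors: tuple[str, ...] = (),
    n_estimators: int | None = None,
) -> PredictionResult:
    """Train/evaluate a gradient-boosted tree predictor on a half split.

    Count targets use the Poisson log-likelihood objective, continuous
    targets squared error.  The first half of the bins (temporal order)
    trains the model; accuracy is the Pearson correlation between
    prediction and truth on the second half.
    """
    from xgboost import XGBRegressor

    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] == 1 and len(target) > 1:
        x = x.T
    y = np.asarray(target, dtype=float)
    ok = np.isfinite(x).all(axis=1) & np.isfinite(y)
    x, y = x[ok], y[ok]
    half = len(y) // 2
    params = dict(XGB_PARAMS)
    if n_estimators is not None:
        params["n_estimators"] = n_estimators
    objective = "count:poisson" if kind == "counts" else "reg:squarederror"
    model = XGBRegressor(objective=objective, random_state=seed, **params)
    model.fit(x[:half], y[:half])
    pred = model.predict(x[half:])
    if np.std(pred) < 1e-12 or np.std(y[half:]) < 1e-12:
        acc = 0.0
    else:
        acc = float(pearsonr(pred, y[half:])[0])
    return PredictionResult(
        direction=direction, predictors=predictors, accuracy=acc
    )


# ---------------------------------------------------------------------------
# cross-condition tuning stability
# ---------------------------------------------------------------------------


def compare_tuning(
    curves_cond1: dict[str, np.ndarray],
    curves_cond2: dict[str, np.ndarray],
    n_shuffles: int = 10000,
    seed: int = 0,
) -> dict:
    """Per-unit similarity of tuning curves across two conditions.

    For each unit present in both conditions the Pearson correlation
    between its (concatenated) cross-correlogram curves is computed; the
    null re-pairs units at random across conditions ``n_shuffles`` times
    and records the mean correlation of each re-pairing.
    """
    units = sorted(set(curves_cond1) & set(curves_cond2))
    if len(units) < 5:
        raise InvalidArgumentError("need >= 5 shared units")
    c1 = np.stack([np.asarray(curves_cond1[u], dtype=float) for u in units])
    c2 = np.stack([np.asarray(curves_cond2[u], dtype=float) for u in units])
    z1 = (c1 - c1.mean(axis=1, keepdims=True)) / c1.std(axis=1, keepdims=True)
    z2 = (c2 - c2.mean(axis=1, keepdims=True)) / c2.std(axis=1, keepdims=True)
    pair_corr = z1 @ z2.T / c1.shape[1]  # all cross-condition Pearson pairs
    observed = np.diag(pair_corr)
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_shuffles)
    n = len(units)
    for s in range(n_shuffles):
        null_means[s] = pair_corr[np.arange(n), rng.permutation(n)].mean()
    obs_mean = float(observed.mean())
    return {
        "units": units,
        "rho_cc": pd.Series(observed, index=units),
        "observed_mean": obs_mean,
        "null_means": null_means,
        "p_value": float((null_means >= obs_mean).mean()),
    }
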