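"""Look-up / look-down unit classification via community detection.

Each unit is summarized by a bivariate firing-rate histogram over joint
quantile bins of body arch (Bar) and overall motion (OM), z-scored per
unit.  Units form a graph whose edges connect pairs with Spearman
correlation between histograms above the median of the off-diagonal
correlation distribution; Newman's leading-eigenvector bisection then
partitions the graph by maximizing modularity.  The community with the
higher mean z-rate in the top Bar quantile is labeled "look-up", the
other(s) "look-down".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import EmptyInputError, InvalidArgumentError
from .neural_coupling import quantile_discretize


@dataclass
class RateHistogram2D:
    """Per-unit mean firing rate over a joint quantile grid.

    ``z_grid`` is the rate grid z-scored with the mean/SD of the occupied
    cells; cells with occupancy below the floor are imputed with the
    unit's overall mean rate before z-scoring (``imputed`` marks them).
    """

    unit: str
    axes: tuple[str, str]
    rate_grid: np.ndarray
    occupancy: np.ndarray
    z_grid: np.ndarray
    imputed: np.ndarray
    uninformative: bool = False


@dataclass
class CommunityPartition:
    """Result of modularity community detection over units."""

    labels: dict[str, int]
    n_communities: int
    modularity: float
    median_threshold: float
    semantic: dict[int, str] = field(default_factory=dict)


def bivariate_rate_histogram(
    counts: np.ndarray,
    var1: np.ndarray,
    var2: np.ndarray,
    n_bins: int = 5,
    min_occupancy: int = 5,
    bin_s: float = 1.0,
    unit: str = "unit",
    axes: tuple[str, str] = ("Bar", "OM"),
) -> RateHistogram2D:
    """Mean firing rate per joint quantile cell of two variables.

    Cells with fewer than ``min_occupancy`` samples are imputed with the
    unit's mean rate; units with fewer than half the cells occupied are
    rejected.  The grid is z-scored using the occupied-cell statistics.
    """
    counts = np.asarray(counts, dtype=float)
    l1 = quantile_discretize(np.asarray(var1, dtype=float), n_bins)
    l2 = quantile_discretize(np.asarray(var2, dtype=float), n_bins)
    occ = np.zeros((n_bins, n_bins))
    acc = np.zeros((n_bins, n_bins))
    np.add.at(occ, (l1, l2), 1.0)
    np.add.at(acc, (l1, l2), counts)
    occupied = occ > 0
    if occupied.sum() < occ.size / 2:
        raise InvalidArgumentError(
            f"unit {unit}: fewer than half of histogram cells occupied"
        )
    with np.errstate(invalid="ignore"):
        rate = np.where(occupied, acc / np.maximum(occ, 1), np.nan) / bin_s
    imputed = occ < min_occupancy
    mean_rate = counts.mean() / bin_s
    rate = np.where(imputed, mean_rate, rate)
    good = ~imputed
    mu = float(rate[good].mean()) if good.any() else mean_rate
    sd = float(rate[good].std()) if good.any() else 0.0
    uninformative = sd < 1e-12
    z = np.zeros_like(rate) if uninformative else (rate - mu) / sd
    return RateHistogram2D(
        unit=unit, axes=axes, rate_grid=rate, occupancy=occ,
        z_grid=z, imputed=imputed, uninformative=uninformative,
    )


def build_adjacency(
    histograms: list[RateHistogram2D],
) -> tuple[nx.Graph, pd.DataFrame, float]:
    """Median-thresholded Spearman-correlation graph over units.

    Units are connected when the Spearman correlation between their
    flattened z-grids is strictly above the median of the off-diagonal
    correlation distribution, giving an unweighted graph with ~half of
    all possible edges.
    """
    if len(histograms) < 4:
        raise InvalidArgumentError("need >= 4 units")
    units = [h.unit for h in histograms]
    flat = np.stack([h.z_grid.reshape(-1) for h in histograms])
    corr, _ = spearmanr(flat.T)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    off = corr[~np.eye(len(units), dtype=bool)]
    median = float(np.median(off))
    graph = nx.Graph()
    graph.add_nodes_from(units)
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            if corr[i, j] > median:  # strict: ties at the median stay apart
                graph.add_edge(units[i], units[j])
    return graph, pd.DataFrame(corr, index=units, columns=units), median


def _modularity_value(adj: np.ndarray, labels: np.ndarray) -> float:
    k = adj.sum(axis=1)
    m2 = k.sum()
    if m2 == 0:
        return 0.0
    b = adj - np.outer(k, k) / m2
    same = labels[:, None] == labels[None, :]
    return float((b * same).sum() / m2)


def newman_communities(
    graph: nx.Graph, median_threshold: float = float("nan"), refine: bool = True
) -> CommunityPartition:
    """Leading-eigenvector modularity bisection (recursive).

    The graph's modularity matrix ``B = A - k k^T / 2m`` is bisected along
    the sign of its leading eigenvector (zero components join the positive
    group); each part is re-bisected using the generalized modularity
    matrix of the subgraph until the leading eigenvalue is non-positive or
    the bisection would not increase modularity.  By default each
    bisection is fine-tuned by greedy node swaps (the Kernighan-Lin-style
    stage of the published method); ``refine=False`` disables it.
    """
    nodes = list(graph.nodes)
    if not nodes:
        raise EmptyInputError("empty graph")
    adj = nx.to_numpy_array(graph, nodelist=nodes)
    n = len(nodes)
    deg = adj.sum(axis=1)
    m2 = deg.sum()
    labels = np.zeros(n, dtype=int)
    if m2 == 0:
        part = CommunityPartition(
            labels={u: 0 for u in nodes}, n_communities=1,
            modularity=0.0, median_threshold=median_threshold,
        )
        return part
    b_full = adj - np.outer(deg, deg) / m2
    next_label = [1]

    def delta_q(bg: np.ndarray, s: np.ndarray) -> float:
        return float(s @ bg @ s) / (2.0 * m2)

    def refine_pass(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
        best = s.copy()
        best_q = delta_q(bg, best)
        improved = True
        while improved:
            improved = False
            for i in range(len(s)):
                trial = best.copy()
                trial[i] *= -1
                q = delta_q(bg, trial)
                if q > best_q + 1e-12:
                    best, best_q = trial, q
                    improved = True
        return best

    def bisect(indices: np.ndarray) -> None:
        if len(indices) < 2:
            return
        bg = b_full[np.ix_(indices, indices)]
        bg_hat = bg - np.diag(bg.sum(axis=1))  # generalized modularity matrix
        eigvals, eigvecs = np.linalg.eigh(bg_hat)
        if eigvals[-1] <= 1e-12:
            return
        lead = eigvecs[:, -1]
        s = np.where(lead >= 0, 1, -1)  # zeros join the positive group
        if refine:
            s = refine_pass(bg_hat, s)
        if np.all(s == s[0]) or delta_q(bg_hat, s) <= 1e-12:
            return
        group_b = indices[s < 0]
        labels[group_b] = next_label[0]
        next_label[0] += 1
        bisect(indices[s > 0])
        bisect(group_b)

    bisect(np.arange(n))
    q = _modularity_value(adj, labels)
    uniq = {lab: i for i, lab in enumerate(sorted(set(labels.tolist())))}
    return CommunityPartition(
        labels={u: uniq[lab] for u, lab in zip(nodes, labels)},
        n_communities=len(uniq),
        modularity=q,
        median_threshold=median_threshold,
    )


def label_communities(
    partition: CommunityPartition, histograms: list[RateHistogram2D]
) -> CommunityPartition:
    """Attach look-up / look-down semantics to the communities.

    The community with the higher mean z-rate in the top quantile of the
    first histogram axis (body arch), averaged over the second axis, is
    "look-up"; every other community is "look-down".  A single community
    is labeled "unclassified".
    """
    hist_map = {h.unit: h for h in histograms}
    comms = sorted(set(partition.labels.values()))
    if len(comms) < 2:
        partition.semantic = {c: "unclassified" for c in comms}
        return partition
    score = {}
    size = {}
    for c in comms:
        members = [u for u, lab in partition.labels.items() if lab == c]
        tops = [hist_map[u].z_grid[-1, :].mean() for u in members if u in hist_map]
        score[c] = float(np.mean(tops)) if tops else -np.inf
        size[c] = len(members)
    # ties broken toward the larger community first (flagged by ordering)
    best = max(comms, key=lambda c: (score[c], size[c]))
    partition.semantic = {
        c: ("look-up" if c == best else "look-down") for c in comms
    }
    return partition


def partition_to_frame(
    partition: CommunityPartition, histograms: list[RateHistogram2D]
) -> pd.DataFrame:
    """Tabulate unit, community, semantic label and modularity."""
    rows = [
        {
            "unit": u,
            "community": c,
            "semantic_label": partition.semantic.get(c, ""),
            "modularity": partition.modularity,
        }
        for u, c in sorted(partition.labels.items())
    ]
    return pd.DataFrame(rows)
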