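"""Connectome prediction accuracy and identifiability metrics.

Measured connectomes are highly similar to each other and to the population
mean (unrelated individuals can correlate above 0.9), so raw prediction
correlation is uninformative on its own. The suite therefore combines:

* ``avgcorr`` — mean Pearson correlation of measured and predicted edge
  vectors per subject;
* ``avgcorr_demean`` — the same after subtracting the training-population
  mean connectome from both, removing the trivially shared component
  (predicting the population mean for everyone scores exactly 0);
* ``top1acc`` — fraction of subjects whose own predicted connectome is the
  single most similar to their measured connectome (chance 1/n);
* ``avgrank`` — average rank percentile: the fraction of other subjects'
  predictions that are less similar to a subject's measured connectome than
  their own prediction, averaged over subjects (chance 0.5, perfect 1).

Graph-metric preservation compares weighted network statistics (node
strength, betweenness, characteristic path length, Louvain modularity) of
measured vs predicted connectomes by Spearman rank correlation across
subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .flavors import ConnectomeMatrix, EdgeVectorSet, ValidationError

__all__ = [
    "PathMetricReport", "cross_correlation_matrix",
    "avgcorr", "avgcorr_demean", "top1acc", "avgrank", "path_metrics",
    "graph_metrics", "graph_metric_agreement", "GRAPH_METRIC_NAMES",
]

GRAPH_METRIC_NAMES = ("mean_strength", "mean_betweenness",
                      "char_path_length", "modularity")


@dataclass
class PathMetricReport:
    """All four edge-space metrics for one source -> target path."""

    source: str
    target: str
    avgcorr: float
    avgcorr_demean: float
    top1acc: float
    avgrank: float
    n_subj: int


def _as_array(x) -> np.ndarray:
    if isinstance(x, EdgeVectorSet):
        return x.data
    return np.atleast_2d(np.asarray(x, dtype=float))


def _check_aligned(measured, predicted):
    M, P = _as_array(measured), _as_array(predicted)
    if M.shape != P.shape:
        raise ValidationError(
            f"measured {M.shape} and predicted {P.shape} shapes differ")
    if (isinstance(measured, EdgeVectorSet) and isinstance(predicted, EdgeVectorSet)
            and measured.subject_ids != predicted.subject_ids):
        raise ValidationError("measured and predicted subject orderings differ")
    return M, P


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    """Demean + unit-norm rows; zero-variance rows become zero rows (r = 0)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    const = norms < 1e-14
    if np.any(const):
        warnings.warn(
            f"{int(const.sum())} zero-variance vector(s): correlations set to 0")
    norms[const] = 1.0
    Xn = Xc / norms[:, None]
    Xn[const] = 0.0
    return Xn


def cross_correlation_matrix(measured, predicted) -> np.ndarray:
    """C[s, a] = Pearson corr(measured subject s, predicted subject a)."""
    M, P = _check_aligned(measured, predicted)
    return _normalize_rows(M) @ _normalize_rows(P).T


def avgcorr(measured, predicted) -> float:
    """Mean over subjects of corr(X_s, Xhat_s)."""
    M, P = _check_aligned(measured, predicted)
    Mn, Pn = _normalize_rows(M), _normalize_rows(P)
    return float(np.mean(np.sum(Mn * Pn, axis=1)))


def avgcorr_demean(measured, predicted, mu_train: np.ndarray) -> float:
    """Mean over subjects of corr(X_s - mu_tr, Xhat_s - mu_tr).

    ``mu_train`` must be the mean edge vector of *training* subjects only.
    """
    M, P = _check_aligned(measured, predicted)
    mu = np.asarray(mu_train, dtype=float).ravel()
    if mu.size != M.shape[1]:
        raise ValidationError("mu_train length does not match edge dimension")
    return avgcorr(M - mu, P - mu)


def top1acc(measured, predicted) -> float:
    """Fraction of subjects whose own prediction is their best match.

    Ties at the maximum count against the subject (conservative), so the
    population-mean pseudo-prediction scores 0, not chance.
    """
    C = cross_correlation_matrix(measured, predicted)
    n = C.shape[0]
    if n < 2:
        raise ValidationError("top1acc needs at least 2 subjects")
    hits = 0
    for s in range(n):
        others = np.delete(C[s], s)
        if C[s, s] > others.max():
            hits += 1
    return hits / n


def avgrank(measured, predicted, ties: str = "half") -> float:
    """Average rank percentile of each subject's own prediction.

    Per subject s: the fraction over a != s of predictions less similar to
    X_s than the subject's own (corr(X_s, Xhat_a) < corr(X_s, Xhat_s)),
    averaged over subjects. Exact similarity ties count 1/2 by default
    (midrank), so the constant population-mean pseudo-prediction scores
    exactly chance (0.5); pass ``ties="strict"`` for the strict inequality.
    """
    if ties not in ("half", "strict"):
        raise ValidationError("ties must be 'half' or 'strict'")
    C = cross_correlation_matrix(measured, predicted)
    n = C.shape[0]
    if n < 2:
        raise ValidationError("avgrank needs at least 2 subjects")
    total = 0.0
    for s in range(n):
        others = np.delete(C[s], s)
        below = np.sum(others < C[s, s])
        if ties == "half":
            below = below + 0.5 * np.sum(others == C[s, s])
        total += below / (n - 1)
    return total / n


def path_metrics(measured, predicted, mu_train: np.ndarray,
                 source: str = "", target: str = "") -> PathMetricReport:
    M, _ = _check_aligned(measured, predicted)
    return PathMetricReport(
        source=source, target=target,
        avgcorr=avgcorr(measured, predicted),
        avgcorr_demean=avgcorr_demean(measured, predicted, mu_train),
        top1acc=top1acc(measured, predicted),
        avgrank=avgrank(measured, predicted),
        n_subj=M.shape[0],
    )


# ---------------------------------------------------------------------------
# graph-metric preservation


def graph_metrics(m: ConnectomeMatrix | np.ndarray, seed: int = 0,
                  negative_weights: str = "zero") -> dict[str, float]:
    """Weighted graph statistics of one connectome.

    Node strength is the signed sum of incident edge weights. For
    betweenness, characteristic path length and Louvain modularity, negative
    weights are dropped (``negative_weights="zero"``) and distances are
    1/weight on the remaining positive edges. Path length over a
    disconnected graph averages reachable pairs only, with a warning.
    """
    W = m.values.copy() if isinstance(m, ConnectomeMatrix) else np.asarray(m, dtype=float).copy()
    n = W.shape[0]
    np.fill_diagonal(W, 0.0)
    strength = float(W.sum(axis=0).mean())

    Wp = W.copy()
    if negative_weights == "zero":
        Wp[Wp < 0] = 0.0
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu = np.triu_indices(n, k=1)
    for i, j, w in zip(*iu, Wp[iu]):
        if w > 0:
            G.add_edge(int(i), int(j), weight=float(w), distance=1.0 / float(w))

    if G.number_of_edges() == 0:
        warnings.warn("empty graph: path-based metrics undefined (nan)")
        return {"mean_strength": strength, "mean_betweenness": np.nan,
                "char_path_length": np.nan, "modularity": np.nan}

    bc = nx.betweenness_centrality(G, weight="distance", normalized=True)
    mean_bc = float(np.mean(list(bc.values())))

    if nx.is_connected(G):
        cpl = nx.average_shortest_path_length(G, weight="distance")
    else:
        warnings.warn("disconnected graph: path length over reachable pairs only")
        total, count = 0.0, 0
        for comp in nx.connected_components(G):
            sub = G.subgraph(comp)
            k = sub.number_of_nodes()
            if k > 1:
                total += nx.average_shortest_path_length(sub, weight="distance") \
                    * (k * (k - 1) / 2)
                count += k * (k - 1) // 2
        cpl = total / count if count else np.nan

    comms = nx.community.louvain_communities(G, weight="weight", seed=seed)
    Q = nx.community.modularity(G, comms, weight="weight")

    return {"mean_strength": strength, "mean_betweenness": mean_bc,
            "char_path_length": float(cpl), "modularity": float(Q)}


def graph_metric_agreement(measured: list, predicted: list,
                           seed: int = 0) -> dict[str, float]:
    """Spearman rank correlation of each graph metric across subjects."""
    if len(measured) != len(predicted):
        raise ValidationError("measured/predicted subject counts differ")
    if len(measured) < 3:
        raise ValidationError("need at least 3 subjects")
    gm = [graph_metrics(m, seed=seed) for m in measured]
    gp = [graph_metrics(p, seed=seed) for p in predicted]
    out: dict[str, float] = {}
    for name in GRAPH_METRIC_NAMES:
        a = np.array([d[name] for d in gm])
        b = np.array([d[name] for d in gp])
        if np.ptp(a) < 1e-14 or np.ptp(b) < 1e-14:
            warnings.warn(f"{name}: constant across subjects; agreement undefined")
            out[name] = np.nan
            continue
        out[name] = float(stats.spearmanr(a, b).statistic)
    return out
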