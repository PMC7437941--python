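"""Posterior correlation summaries, edge testing, and network evaluation.

An edge between genes g and g' is declared when the equal-tailed credible
interval of their log-mean correlation rho_gg' excludes zero.  The
approximate p-value a* of a pair is the size of the smallest equal-tailed
interval containing zero,

    a* = 2 min(#{rho < 0}, #{rho > 0}) / M,

which is dual to the CI rule (up to the discreteness of M samples) and is
used to rank pairs when computing AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

__all__ = [
    "CorrelationPosterior", "GeneNetwork", "summarize_correlations",
    "approx_pvalue", "test_edges", "evaluate_network",
    "export_network", "read_network",
]


@dataclass
class CorrelationPosterior:
    """Per-pair posterior mean, CI bounds, and approximate p-values."""

    rho_hat: np.ndarray  # (G, G)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    approx_p: np.ndarray
    level: float
    gene_ids: list

    @property
    def n_genes(self) -> int:
        return self.rho_hat.shape[0]


@dataclass
class GeneNetwork:
    """Undirected significant-edge list with posterior summaries."""

    edges: pd.DataFrame  # columns gene_a, gene_b, rho_hat, approx_p, sign
    level: float
    gene_ids: list

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return {frozenset((a, b)) for a, b in
                zip(self.edges.gene_a, self.edges.gene_b)}


def approx_pvalue(samples) -> float:
    """Smallest equal-tailed CI containing zero, expressed as a tail mass."""
    samples = np.asarray(samples, dtype=float)
    M = samples.size
    if M < 1:
        raise ValueError("need at least one posterior sample")
    n_neg = int(np.sum(samples < 0))
    n_pos = int(np.sum(samples > 0))
    return min(1.0, 2.0 * min(n_neg, n_pos) / M)


def summarize_correlations(traces, level: float = 0.95,
                           gene_ids=None) -> CorrelationPosterior:
    """Pool retained correlation draws across chains and summarize per pair."""
    if not isinstance(traces, (list, tuple)):
        traces = [traces]
    rho = np.concatenate([t.rho_samples for t in traces], axis=0)
    M = rho.shape[0]
    if M == 0:
        raise ValueError("no retained correlation samples")
    if gene_ids is None:
        gene_ids = [f"gene_{g + 1}" for g in range(rho.shape[1])]
    tail = (1.0 - level) / 2.0
    rho_hat = rho.mean(axis=0)
    ci_lo = np.quantile(rho, tail, axis=0)
    ci_hi = np.quantile(rho, 1.0 - tail, axis=0)
    n_neg = np.sum(rho < 0, axis=0)
    n_pos = np.sum(rho > 0, axis=0)
    approx_p = np.minimum(1.0, 2.0 * np.minimum(n_neg, n_pos) / M)
    return CorrelationPosterior(rho_hat=rho_hat, ci_lo=ci_lo, ci_hi=ci_hi,
                                approx_p=approx_p, level=level,
                                gene_ids=list(gene_ids))


def test_edges(cp: CorrelationPosterior, level: float | None = None) -> GeneNetwork:
    """Edges are pairs whose CI at the given level excludes zero.

    The CI bounds stored in ``cp`` are used as-is; to test at a different
    level, re-summarize the posterior at that level first.
    """
    level = cp.level if level is None else level
    if abs(level - cp.level) > 1e-12:
        raise ValueError(
            "re-summarize the posterior at the requested level first"
        )
    G = cp.n_genes
    iu = np.triu_indices(G, k=1)
    excl = (cp.ci_lo[iu] > 0) | (cp.ci_hi[iu] < 0)
    idx = np.flatnonzero(excl)
    ga = [cp.gene_ids[iu[0][j]] for j in idx]
    gb = [cp.gene_ids[iu[1][j]] for j in idx]
    edges = pd.DataFrame({
        "gene_a": ga,
        "gene_b": gb,
        "rho_hat": cp.rho_hat[iu][idx],
        "approx_p": cp.approx_p[iu][idx],
        "sign": np.sign(cp.rho_hat[iu][idx]).astype(int),
    })
    return GeneNetwork(edges=edges, level=level, gene_ids=list(cp.gene_ids))


def _auc_scores(cp: CorrelationPosterior):
    """Ranking scores for all unordered pairs: by 1/a*, ties by |rho_hat|,
    remaining ties share an average rank (dense rank composition)."""
    G = cp.n_genes
    iu = np.triu_indices(G, k=1)
    primary = rankdata(-cp.approx_p[iu], method="dense")
    secondary = rankdata(np.abs(cp.rho_hat[iu]), method="dense")
    return iu, primary * (secondary.max() + 1.0) + secondary


def evaluate_network(estimated: GeneNetwork, truth, cp: CorrelationPosterior | None = None):
    """TPR, FDR, AUC and edge count against a reference edge set.

    ``truth`` is an iterable of gene-id pairs.  AUC requires the full
    posterior ranking (``cp``); when omitted, AUC is NaN.
    """
    truth_set = {frozenset(t) for t in truth}
    if not truth_set:
        raise ValueError("the reference edge set is empty; TPR is undefined")
    est = estimated.edge_set()
    tp = len(est & truth_set)
    fp = len(est - truth_set)
    tpr = tp / len(truth_set)
    fdr = fp / max(1, len(est))
    auc = np.nan
    if cp is not None:
        iu, scores = _auc_scores(cp)
        labels = np.array([
            frozenset((cp.gene_ids[a], cp.gene_ids[b])) in truth_set
            for a, b in zip(*iu)
        ])
        auc = float(roc_auc_score(labels, scores))
    return {"tpr": tpr, "fdr": fdr, "auc": auc, "n_edges": len(est)}


def export_network(net: GeneNetwork, path, fmt: str = "csv") -> None:
    """Write the edge list as CSV or GraphML."""
    if fmt == "csv":
        net.edges.to_csv(path, index=False)
    elif fmt == "graphml":
        g = nx.Graph(level=net.level)
        g.add_nodes_from(net.gene_ids)
        for row in net.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, rho_hat=float(row.rho_hat),
                       approx_p=float(row.approx_p), sign=int(row.sign))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "csv", level: float = 0.95) -> GeneNetwork:
    """Round-trip reader for :func:`export_network` output."""
    if fmt == "csv":
        edges = pd.read_csv(path)
        if edges.empty:
            edges = pd.DataFrame(columns=["gene_a", "gene_b", "rho_hat",
                                          "approx_p", "sign"])
        genes = sorted(set(edges.gene_a) | set(edges.gene_b))
        return GeneNetwork(edges=edges, level=level, gene_ids=genes)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        rows = [
            {"gene_a": a, "gene_b": b, "rho_hat": d["rho_hat"],
             "approx_p": d["approx_p"], "sign": int(d["sign"])}
            for a, b, d in g.edges(data=True)
        ]
        edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho_hat",
                                            "approx_p", "sign"])
        return GeneNetwork(edges=edges, level=float(g.graph.get("level", level)),
                           gene_ids=list(g.nodes))
    raise ValueError(f"unknown network format {fmt!r}")
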