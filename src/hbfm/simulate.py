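"""Synthetic count data with known co-expression structure.

Two generators are provided:

* :func:`simulate_counts` draws counts from the factor model itself:
  baseline means beta_g ~ Gamma(3, 0.5) (shape/rate, mean 6), factor
  scores lambda_if ~ Lognormal(0, phi_f), counts Poisson.  Loadings are
  fixed block designs: genes are sorted into groups and all genes in a
  group share one loading row, so the true network (pairs with nonzero
  log-mean correlation) is known exactly.

* :func:`simulate_norta` draws counts whose marginals are zero-inflated
  negative binomial, coupled through a Gaussian copula (the NORTA
  construction: correlated standard normals pushed through each gene's
  ZINB quantile function).  This produces correlated data whose
  generative process is *not* the factor model.

Two canonical designs ship with the package: ``sim10`` (10 factors,
10 groups of 5 genes, 350 true edges) and ``sim15`` (15 factors,
425 true edges).  Both use the factor-scale multiset
{0.20, 0.35, 0.50, 0.65, 0.80} (each value twice, resp. three times),
communities of correlated groups wired to reach the stated edge counts,
and a mix of positive and negative associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_core import ExpressionCounts, ModelState, pairwise_correlation

__all__ = [
    "SimulationDesign", "ZinbParams", "build_block_loadings", "true_network",
    "simulate_counts", "simulate_norta", "get_design", "synthetic_zinb_params",
]


@dataclass
class SimulationDesign:
    """Block-loading template for model-based simulation."""

    n_groups: int
    genes_per_group: int
    group_loadings: np.ndarray  # (n_groups, F_sim) in {-1, 0, 1}
    phi_values: np.ndarray  # (F_sim,)
    N: int = 500
    beta_shape: float = 3.0
    beta_rate: float = 0.5
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        self.group_loadings = np.asarray(self.group_loadings)
        self.phi_values = np.asarray(self.phi_values, dtype=float)
        if not np.isin(self.group_loadings, (-1, 0, 1)).all():
            raise ValueError("group loadings must lie in {-1, 0, 1}")
        if self.group_loadings.shape != (self.n_groups, self.phi_values.size):
            raise ValueError("group_loadings must be n_groups x F_sim")
        if np.any(self.phi_values <= 0):
            raise ValueError("phi values must be positive")
        if np.any(np.abs(self.group_loadings).sum(axis=1) == 0):
            raise ValueError("every group needs at least one active factor")

    @property
    def n_genes(self) -> int:
        return self.n_groups * self.genes_per_group

    @property
    def F_sim(self) -> int:
        return self.phi_values.size


@dataclass
class ZinbParams:
    """Zero-inflated negative binomial marginal for one gene."""

    pi0: float  # extra zero mass
    size: float  # NB dispersion (larger = closer to Poisson)
    mu: float  # NB mean

    def __post_init__(self):
        if not (0 <= self.pi0 <= 1) or self.size <= 0 or self.mu <= 0:
            raise ValueError(f"invalid ZINB parameters: {self}")

    @property
    def nb_p(self) -> float:
        return self.size / (self.size + self.mu)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function of the ZINB mixture."""
        u = np.asarray(u, dtype=float)
        out = np.zeros(u.shape)
        above = u > self.pi0
        if self.pi0 < 1 and above.any():
            adj = (u[above] - self.pi0) / (1.0 - self.pi0)
            out[above] = stats.nbinom.ppf(adj, self.size, self.nb_p)
        return out.astype(np.int64)


def build_block_loadings(design: SimulationDesign):
    """Expand group loadings to gene level; returns (alpha, n_true_edges)."""
    alpha = np.repeat(design.group_loadings, design.genes_per_group, axis=0)
    edges = true_network(alpha, design.phi_values)
    return alpha.astype(np.int8), len(edges)


def true_network(alpha, phi, tol: float = 1e-12):
    """All unordered gene-index pairs with nonzero log-mean correlation."""
    rho = pairwise_correlation(alpha, phi)
    iu = np.triu_indices(rho.shape[0], k=1)
    hit = np.abs(rho[iu]) > tol
    return [(int(a), int(b)) for a, b in
            zip(iu[0][hit], iu[1][hit])]


def simulate_counts(design: SimulationDesign):
    """Draw counts from the factor model under a block design.

    Returns ``(counts, truth, state)`` where ``truth`` is the set of true
    edges as frozensets of gene ids and ``state`` the generating
    parameters.
    """
    rng = np.random.default_rng(design.seed)
    alpha, _ = build_block_loadings(design)
    G, F, N = design.n_genes, design.F_sim, design.N
    beta = rng.gamma(design.beta_shape, 1.0 / design.beta_rate, G)
    phi = design.phi_values
    lam = np.exp(rng.normal(0.0, np.sqrt(phi)[None, :], size=(N, F)))
    af = alpha.astype(float)
    log_mu = (np.log(beta)[:, None] + af @ np.log(lam).T
              - (0.5 * (np.abs(af) @ phi))[:, None])
    y = rng.poisson(np.exp(log_mu))
    counts = ExpressionCounts(values=y)
    theta = np.abs(alpha).mean(axis=0)
    state = ModelState(beta=beta, alpha=alpha, lam=lam, phi=phi.copy(),
                       theta=theta)
    truth = {frozenset((counts.gene_ids[a], counts.gene_ids[b]))
             for a, b in true_network(alpha, phi)}
    return counts, truth, state


def simulate_norta(zinb: list, latent_corr, N: int, seed: int = 0,
                   gene_ids=None) -> ExpressionCounts:
    """Correlated ZINB counts through a Gaussian copula.

    ``latent_corr`` must be a correlation matrix; if it is not positive
    semi-definite it is repaired by clipping negative eigenvalues (with a
    warning) and renormalizing the diagonal.
    """
    rng = np.random.default_rng(seed)
    C = np.array(latent_corr, dtype=float)
    G = len(zinb)
    if C.shape != (G, G):
        raise ValueError("latent correlation must be G x G")
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() < -1e-10:
        warnings.warn("latent correlation not PSD; clipping eigenvalues")
        w = np.clip(w, 0.0, None)
        C = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        w, V = np.linalg.eigh(C)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    Z = root @ rng.standard_normal((G, N))
    U = stats.norm.cdf(Z)
    y = np.empty((G, N), dtype=np.int64)
    for g, params in enumerate(zinb):
        y[g] = params.ppf(U[g])
    return ExpressionCounts(values=y, gene_ids=gene_ids)


def synthetic_zinb_params(G: int, rng: np.random.Generator) -> list:
    """Synthetic per-gene ZINB parameters with scRNA-seq-like ranges.

    A stand-in marginal set (not estimated from any real dataset): NB
    means lognormal around a few counts, moderate dispersion, and a broad
    spread of zero-inflation probabilities.
    """
    mu = np.exp(rng.normal(1.0, 1.0, G))
    size = rng.uniform(0.5, 3.0, G)
    pi0 = rng.uniform(0.0, 0.6, G)
    return [ZinbParams(pi0=float(p), size=float(s), mu=float(m))
            for p, s, m in zip(pi0, size, mu)]


def _sim10_design(N: int, seed: int) -> SimulationDesign:
    """Ten groups, ten factors, 350 true edges.

    Three communities of correlated groups (sizes 4 + 3 + 2, sharing one
    factor each with mixed signs) plus one isolated group give 10
    correlated group pairs (6 + 3 + 1).  Private factors with large
    scales dilute the shared-factor signal, so between-group
    correlations span weak (~0.3) through strong (1.0) — a heterogeneous
    difficulty profile rather than a uniformly strong one.
    """
    phi = np.array([0.20, 0.20, 0.35, 0.35, 0.50, 0.50, 0.65, 0.65, 0.80, 0.80])
    L = np.zeros((10, 10), dtype=np.int8)
    # community of four groups sharing factor 2 (phi = 0.35); the large
    # private scales make these the weak edges (|rho| ~ 0.30-0.35)
    for g, s in zip((0, 1, 2, 3), (1, 1, -1, -1)):
        L[g, 2] = s
    for g, f in zip((0, 1, 2, 3), (8, 9, 7, 6)):
        L[g, f] = 1
    # community of three groups sharing factor 5 (phi = 0.50); moderate
    # edges (|rho| ~ 0.54-0.77)
    for g, s in zip((4, 5, 6), (1, -1, 1)):
        L[g, 5] = s
    L[4, 3] = 1
    L[5, 4] = 1
    # community of two groups sharing factor 1 only: one strong pair
    L[7, 1], L[8, 1] = 1, -1
    # isolated group
    L[9, 0] = 1
    return SimulationDesign(n_groups=10, genes_per_group=5, group_loadings=L,
                            phi_values=phi, N=N, seed=seed, name="sim10")


def _sim15_design(N: int, seed: int) -> SimulationDesign:
    """Ten groups, fifteen factors, 425 true edges.

    Communities of sizes 4 + 4 + 2 give 13 correlated group pairs
    (6 + 6 + 1), again with between-group correlations ranging from weak
    to strong.
    """
    phi = np.repeat([0.20, 0.35, 0.50, 0.65, 0.80], 3)
    L = np.zeros((10, 15), dtype=np.int8)
    # community of four groups on factor 3 (phi = 0.35): weak edges
    for g, s in zip((0, 1, 2, 3), (1, 1, -1, -1)):
        L[g, 3] = s
    for g, f in zip((0, 1, 2, 3), (12, 13, 9, 10)):
        L[g, f] = 1
    L[2, 4] = 1  # second private
    # community of four groups on factor 6 (phi = 0.50): moderate edges
    for g, s in zip((4, 5, 6, 7), (1, -1, 1, -1)):
        L[g, 6] = s
    for g, f in zip((4, 5, 6), (7, 8, 11)):
        L[g, f] = 1
    L[5, 2] = 1  # second private
    L[6, 5] = 1  # second private
    # community of two groups on factor 0 (phi = 0.20): weak pair
    L[8, 0], L[9, 0] = 1, -1
    L[8, 14] = 1
    L[9, 1] = 1
    return SimulationDesign(n_groups=10, genes_per_group=5, group_loadings=L,
                            phi_values=phi, N=N, seed=seed, name="sim15")


def get_design(name: str, N: int = 500, seed: int = 0) -> SimulationDesign:
    """Canonical shipped designs: ``sim10`` (350 edges) or ``sim15`` (425)."""
    if name == "sim10":
        return _sim10_design(N, seed)
    if name == "sim15":
        return _sim15_design(N, seed)
    raise ValueError(f"unknown design {name!r}; available: sim10, sim15")
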