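"""Generative model for sparse Poisson–lognormal latent-factor counts.

Counts Y_gi for gene g in cell i are conditionally Poisson with mean

    mu_gi = beta_g * prod_f exp{-phi_f/2 |alpha_gf|} * lambda_if^{alpha_gf},

where beta_g > 0 is the baseline (marginal mean) expression of gene g,
alpha_gf in {-1, 0, 1} is a discrete loading saying whether and how latent
factor f drives gene g, lambda_if > 0 is a cell-specific factor score with
log lambda_if ~ Normal(0, phi_f), and phi_f is the *variance* of the factor
on the log scale.  The exp{-phi_f/2 |alpha_gf|} adjustment makes
E(Y_gi) = beta_g marginally over the factor scores for any loading pattern.

Shared factors induce correlation between log-means of gene pairs; that
correlation depends only on (alpha, phi) and is the statistic from which
the co-expression network is built (see :func:`pairwise_correlation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ExpressionCounts",
    "ModelState",
    "PriorSpec",
    "compute_log_mean",
    "compute_mean",
    "loglik_conditional",
    "marginal_moments",
    "pairwise_correlation",
]


@dataclass
class ExpressionCounts:
    """A genes x cells matrix of non-negative integer counts with labels."""

    values: np.ndarray
    gene_ids: list[str] = field(default=None)
    cell_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        G, N = self.values.shape
        if G < 2 or N < 1:
            raise ValueError(f"need at least 2 genes and 1 cell, got {G}x{N}")
        if np.any(self.values < 0) or np.any(self.values != np.floor(self.values)):
            raise ValueError("counts must be non-negative integers")
        self.values = self.values.astype(np.int64)
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{g + 1}" for g in range(G)]
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i + 1}" for i in range(N)]
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.cell_ids = [str(x) for x in self.cell_ids]
        if len(self.gene_ids) != G or len(self.cell_ids) != N:
            raise ValueError("label lengths do not match the count matrix")
        if len(set(self.gene_ids)) != G or len(set(self.cell_ids)) != N:
            raise ValueError("gene and cell labels must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class PriorSpec:
    """Hyperparameters of the hierarchical priors.

    Defaults are the diffuse, conditionally conjugate choices used
    throughout: beta_g ~ Gamma(0.001, 0.001) (shape/rate),
    phi_f ~ Lognormal(h1, h2) with h1 ~ Normal(0, 100) (variance 100) and
    h2 ~ InverseGamma(1, 1) (shape/scale), |alpha_gf| ~ Bernoulli(theta_f)
    split evenly between +1 and -1, theta_f ~ Beta(1, 1).
    """

    beta_shape: float = 0.001
    beta_rate: float = 0.001
    h1_mean: float = 0.0
    h1_var: float = 100.0
    h2_shape: float = 1.0
    h2_scale: float = 1.0
    theta_a: float = 1.0
    theta_b: float = 1.0


@dataclass
class ModelState:
    """One joint configuration of all model parameters.

    beta : (G,) positive baseline means; alpha : (G, F) loadings in
    {-1, 0, 1}; lam : (N, F) positive factor scores; phi : (F,) positive
    log-scale variances; theta : (F,) activation probabilities in [0, 1];
    h1, h2 : hyperparameters of the lognormal prior on phi.
    """

    beta: np.ndarray
    alpha: np.ndarray
    lam: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    h1: float = 0.0
    h2: float = 1.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha)
        self.lam = np.asarray(self.lam, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.beta <= 0):
            raise ValueError("beta must be strictly positive")
        if not np.isin(self.alpha, (-1, 0, 1)).all():
            raise ValueError("alpha entries must lie in {-1, 0, 1}")
        self.alpha = self.alpha.astype(np.int8)
        if np.any(self.lam <= 0):
            raise ValueError("lambda must be strictly positive")
        if np.any(self.phi <= 0):
            raise ValueError("phi must be strictly positive")
        if np.any((self.theta < 0) | (self.theta > 1)):
            raise ValueError("theta must lie in [0, 1]")
        G, F = self.alpha.shape
        if self.beta.shape != (G,) or self.phi.shape != (F,) or self.theta.shape != (F,):
            raise ValueError("inconsistent parameter shapes")
        if self.lam.shape[1] != F:
            raise ValueError("lam must have one column per factor")
        if self.h2 <= 0:
            raise ValueError("h2 must be positive")

    @property
    def n_genes(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_cells(self) -> int:
        return self.lam.shape[0]

    @property
    def n_factors(self) -> int:
        return self.alpha.shape[1]

    def copy(self) -> "ModelState":
        return ModelState(
            beta=self.beta.copy(), alpha=self.alpha.copy(), lam=self.lam.copy(),
            phi=self.phi.copy(), theta=self.theta.copy(), h1=self.h1, h2=self.h2,
        )


def compute_log_mean(state: ModelState) -> np.ndarray:
    """log mu_gi as a (G, N) matrix, assembled entirely in log space.

    log mu_gi = log beta_g + sum_f alpha_gf log lambda_if
                - 1/2 sum_f phi_f |alpha_gf|.
    """
    alpha = state.alpha.astype(float)
    log_w = alpha @ np.log(state.lam).T  # (G, N)
    adj = 0.5 * (np.abs(alpha) @ state.phi)  # (G,)
    return np.log(state.beta)[:, None] + log_w - adj[:, None]


def compute_mean(state: ModelState) -> np.ndarray:
    """Conditional Poisson mean matrix mu (G, N); all entries finite > 0."""
    with np.errstate(over="ignore"):
        mu = np.exp(compute_log_mean(state))
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        g, i = np.argwhere(~np.isfinite(mu) | (mu <= 0))[0]
        f = int(np.argmax(np.abs(state.alpha[g]) * state.phi))
        raise FloatingPointError(
            f"non-finite mean at gene {g}, cell {i} (dominant factor {f}): "
            "factor score magnitude out of double range"
        )
    return mu


def loglik_conditional(Y: ExpressionCounts, state: ModelState) -> float:
    """Poisson log-likelihood sum_gi [y log mu - mu - log y!] given the factors."""
    y = Y.values
    if y.shape != (state.n_genes, state.n_cells):
        raise ValueError(
            f"counts are {y.shape} but state implies "
            f"({state.n_genes}, {state.n_cells})"
        )
    log_mu = compute_log_mean(state)
    val = float(np.sum(y * log_mu) - np.sum(np.exp(log_mu)) - np.sum(gammaln(y + 1.0)))
    if not np.isfinite(val):
        raise FloatingPointError("non-finite conditional log-likelihood")
    return val


def marginal_moments(beta_g, alpha_row, phi):
    """Marginal mean and variance of Y_gi with the factor scores integrated out.

    The mean is beta_g for every loading pattern (by construction of the
    exp{-phi/2} adjustment); the variance is

        Var(Y_gi) = beta_g + beta_g^2 (exp{sum_f phi_f |alpha_gf|} - 1),

    i.e. Poisson variance inflated by the lognormal second moment of the
    product of active factors — always >= the mean.
    """
    beta_g = float(beta_g)
    alpha_row = np.asarray(alpha_row)
    phi = np.asarray(phi, dtype=float)
    if beta_g <= 0 or np.any(phi <= 0) or not np.isin(alpha_row, (-1, 0, 1)).all():
        raise ValueError("invalid marginal-moment inputs")
    s = float(np.sum(phi * np.abs(alpha_row)))
    mean = beta_g
    var = beta_g + beta_g**2 * np.expm1(s)
    return mean, var


def pairwise_correlation(alpha, phi) -> np.ndarray:
    """Correlation of log mu between all gene pairs, from loadings alone.

    rho_gg' = sum_f phi_f a_gf a_g'f /
              sqrt( (sum_f phi_f a_gf^2)(sum_f phi_f a_g'f^2) ),

    with any 0/0 (a gene with no active factor) defined as exactly 0 —
    including that gene's diagonal entry, so such genes can never form
    edges.
    """
    alpha = np.asarray(alpha, dtype=float)
    phi = np.asarray(phi, dtype=float)
    cov = (alpha * phi) @ alpha.T
    var = (alpha * alpha) @ phi
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, np.where(var > 0, 1.0, 0.0))
    return rho
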