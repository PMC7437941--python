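"""Multi-chain fitting, chain ranking, DIC, and posterior predictive checks.

The number of factors F is chosen by fitting a grid of candidate values,
running several independently seeded chains per F (each warm-started by
stochastic EM), keeping the best chains by average retained conditional
log-likelihood, and selecting the F with the lowest DIC.  DIC uses half
the posterior variance of the deviance as the effective number of
parameters:

    DIC = mean(D) + var(D) / 2,    D = -2 log p(Y | beta, alpha, phi, lam).

Both the ranking score and the deviance condition on the sampled factor
scores; the marginal likelihood with the scores integrated out has no
closed form, so "average marginal likelihood" is implemented as the mean
retained conditional log-likelihood per chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import ChainTrace, SamplerConfig, run_chain
from .model_core import ExpressionCounts, ModelState, PriorSpec
from .stochastic_em import EMSchedule, initialize_chain

__all__ = [
    "FitResult", "fit_hbfm", "rank_chains", "dic", "select_F",
    "posterior_predictive",
]


@dataclass
class FitResult:
    """Fit of one factor count: retained (top-ranked) chains and their DIC."""

    F: int
    traces: list
    dic: float
    per_chain_avg_loglik: list = field(default_factory=list)
    all_chain_avg_loglik: list = field(default_factory=list)

    def pooled_rho(self) -> np.ndarray:
        """All retained correlation draws pooled across chains, (M, G, G)."""
        return np.concatenate([t.rho_samples for t in self.traces], axis=0)


def rank_chains(traces: list, keep: int) -> list:
    """Keep the ``keep`` chains with the highest mean retained log-likelihood.

    Ties are broken by original chain index, so the result is
    deterministic; chains that failed or retained nothing score -inf.
    """
    def score(t: ChainTrace) -> float:
        if t.n_retained == 0:
            return -np.inf
        s = t.avg_loglik
        return s if np.isfinite(s) else -np.inf

    if len(traces) < keep:
        warnings.warn(f"only {len(traces)} chains available, keeping all")
        keep = len(traces)
    order = sorted(range(len(traces)), key=lambda j: (-score(traces[j]), j))
    return [traces[j] for j in order[:keep]]


def dic(traces: list) -> float:
    """DIC from deviance draws pooled over the given chains."""
    D = np.concatenate([t.deviance for t in traces])
    if D.size < 2:
        raise ValueError("DIC needs at least two deviance samples")
    return float(np.mean(D) + 0.5 * np.var(D, ddof=1))


def fit_hbfm(Y: ExpressionCounts, F: int,
             n_chains: int = 8, n_keep: int = 5,
             schedule: EMSchedule | None = None,
             sampler_cfg: SamplerConfig | None = None,
             prior: PriorSpec | None = None,
             seed: int = 0) -> FitResult:
    """Fit one factor count: warm-start and run ``n_chains`` chains, rank
    them, and compute the DIC of the retained set.

    Chain seeds are spawned from ``seed`` so results do not depend on
    execution order.
    """
    schedule = schedule or EMSchedule()
    sampler_cfg = sampler_cfg or SamplerConfig()
    chain_seeds = np.random.SeedSequence(seed).generate_state(2 * n_chains) % (2**31)
    traces = []
    for c in range(n_chains):
        sched_c = EMSchedule(schedule.warmup_iters, schedule.em_iters,
                             schedule.average_window, seed=int(chain_seeds[2 * c]))
        cfg_c = SamplerConfig(
            n_iter=sampler_cfg.n_iter, n_retain=sampler_cfg.n_retain,
            phi_proposal_sd=sampler_cfg.phi_proposal_sd,
            gig_shrink_b=sampler_cfg.gig_shrink_b,
            seed=int(chain_seeds[2 * c + 1]),
            adapt_phi=sampler_cfg.adapt_phi,
            recompute_every=sampler_cfg.recompute_every,
        )
        init = initialize_chain(Y, F, sched_c, prior, cfg_c)
        traces.append(run_chain(Y, init, cfg_c, prior))
    kept = rank_chains(traces, n_keep)
    return FitResult(
        F=F, traces=kept, dic=dic(kept),
        per_chain_avg_loglik=[t.avg_loglik for t in kept],
        all_chain_avg_loglik=[t.avg_loglik if t.n_retained else -np.inf
                              for t in traces],
    )


def select_F(Y: ExpressionCounts, F_grid: list,
             fit_fn=None, boundary_increment: int = 3,
             **fit_kwargs):
    """Fit every F in the grid and return the lowest-DIC fit.

    If the grid maximum wins, one extra fit at ``max + boundary_increment``
    is run and compared, so a winner at the boundary is re-examined once.

    Returns ``(best_fit, table)`` where ``table`` is a per-F DataFrame of
    DIC and mean per-chain log-likelihoods.
    """
    if not F_grid:
        raise ValueError("F grid must be non-empty")
    fit_fn = fit_fn or fit_hbfm
    fits = {}
    for F in sorted(set(int(F) for F in F_grid)):
        fits[F] = fit_fn(Y, F, **fit_kwargs)
    best_F = min(fits, key=lambda F: fits[F].dic)
    if best_F == max(fits) and boundary_increment > 0:
        F_ext = best_F + boundary_increment
        fits[F_ext] = fit_fn(Y, F_ext, **fit_kwargs)
        best_F = min(fits, key=lambda F: fits[F].dic)
    table = pd.DataFrame(
        {
            "F": list(fits),
            "dic": [fits[F].dic for F in fits],
            "mean_loglik": [float(np.mean(fits[F].per_chain_avg_loglik))
                            for F in fits],
        }
    ).sort_values("F").reset_index(drop=True)
    return fits[best_F], table


def posterior_predictive(Y: ExpressionCounts, trace: ChainTrace,
                         n_datasets: int, rng: np.random.Generator):
    """Regenerate datasets from retained draws with fresh factor scores.

    For each replicate a retained iteration's (beta, alpha, phi) is chosen
    at random, the factor scores are redrawn from their Lognormal(0, phi_f)
    prior, and counts are drawn Poisson from the implied means.

    Returns ``(datasets, summaries)``; ``summaries`` is a DataFrame with
    one row per (replicate, gene): mean, variance and proportion of zeros.
    """
    G, N = Y.values.shape
    datasets = []
    rows = []
    picks = rng.integers(0, trace.n_retained, size=n_datasets)
    for d, m in enumerate(picks):
        beta = trace.beta_samples[m]
        alpha = trace.alpha_samples[m].astype(float)
        phi = trace.phi_samples[m]
        lam_log = rng.normal(0.0, np.sqrt(phi)[None, :], size=(N, phi.size))
        log_mu = (np.log(beta)[:, None] + alpha @ lam_log.T
                  - (0.5 * (np.abs(alpha) @ phi))[:, None])
        y = rng.poisson(np.exp(log_mu))
        datasets.append(ExpressionCounts(values=y, gene_ids=Y.gene_ids,
                                         cell_ids=Y.cell_ids))
        rows.append(pd.DataFrame({
            "dataset": d,
            "gene": Y.gene_ids,
            "mean": y.mean(axis=1),
            "variance": y.var(axis=1, ddof=1),
            "zero_prop": (y == 0).mean(axis=1),
        }))
    return datasets, pd.concat(rows, ignore_index=True)
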