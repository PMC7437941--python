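"""Stochastic-EM warm start for the Gibbs sampler.

The one-at-a-time loading updates make the posterior highly multimodal
(factors cannot split or merge in a single move), so chains are seeded
from a stochastic EM pass: the usual sweep is run, but beta is set to its
conditional posterior mode, each alpha_gf to the argmax of its three
conditional probabilities, and phi_f to the maximizer of its conditional
density, while theta, h1, h2 and the factor scores are still sampled.
After a short full-MCMC warm-up and a longer EM phase, the continuous
parameters are averaged over a trailing window and each loading is set to
its most frequent value in that window (ties broken at random).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcmc import GibbsSweeper, SamplerConfig, _block_rngs
from .model_core import ExpressionCounts, ModelState, PriorSpec

__all__ = ["EMSchedule", "em_step", "initialize_chain", "random_start"]


@dataclass
class EMSchedule:
    """Iteration plan for the warm start.

    A random start, ``warmup_iters`` full MCMC sweeps, then ``em_iters``
    stochastic-EM sweeps; the last ``average_window`` of them are
    averaged into the returned starting state (defaults 100 / 2,000 /
    200).

    Setting ``n_starts > 1`` runs that many independent pilots (random
    start, warm-up, ``pilot_iters`` EM sweeps each) and continues only
    the one with the best conditional log-likelihood.  This guards
    against the EM freezing into a poor loading configuration and is
    useful when a single good point estimate is wanted — but it
    homogenizes chains, and the credible-interval edge testing relies on
    *diverse* independently-started chains, so the default is a single
    start per chain.
    """

    warmup_iters: int = 100
    em_iters: int = 2000
    average_window: int = 200
    seed: int = 0
    n_starts: int = 1
    pilot_iters: int = 150

    def __post_init__(self):
        if self.average_window > self.em_iters:
            raise ValueError("average_window cannot exceed em_iters")
        if self.n_starts < 1:
            raise ValueError("need at least one start")
        # the averaging window must fit after the pilot phase
        self.pilot_iters = max(0, min(self.pilot_iters,
                                      self.em_iters - self.average_window))


def random_start(Y: ExpressionCounts, F: int, rng: np.random.Generator) -> ModelState:
    """Dispersed random initialization.

    beta starts at jittered per-gene means, loadings are iid with
    P(+1) = P(-1) = 0.1, and phi and the factor scores are drawn from
    their priors at h1 = 0, h2 = 1.
    """
    G, N = Y.values.shape
    gene_means = np.maximum(Y.values.mean(axis=1), 0.1)
    beta = gene_means * np.exp(rng.normal(0.0, 0.2, G))
    alpha = rng.choice(np.array([-1, 0, 1], dtype=np.int8), size=(G, F),
                       p=[0.1, 0.8, 0.1])
    phi = np.exp(rng.normal(0.0, 1.0, F))
    lam = np.exp(np.clip(rng.normal(0.0, np.sqrt(phi), size=(N, F)), -30.0, 30.0))
    theta = rng.beta(1.0, 1.0, F)
    return ModelState(beta=beta, alpha=alpha, lam=lam, phi=phi, theta=theta,
                      h1=0.0, h2=1.0)


def em_step(Y: ExpressionCounts, state: ModelState, rng: np.random.Generator,
            prior: PriorSpec | None = None) -> ModelState:
    """One stochastic-EM sweep; returns the updated state."""
    sw = GibbsSweeper(Y, state, prior=prior)
    for k in sw.rngs:
        sw.rngs[k] = rng
    sw.full_sweep(em=True)
    return sw.state


def initialize_chain(Y: ExpressionCounts, F: int,
                     schedule: EMSchedule | None = None,
                     prior: PriorSpec | None = None,
                     sampler_cfg: SamplerConfig | None = None) -> ModelState:
    """Produce a starting ModelState for one MCMC chain."""
    schedule = schedule or EMSchedule()
    cfg = sampler_cfg or SamplerConfig()

    best_sw, best_ll, best_rngs = None, -np.inf, None
    for child in np.random.SeedSequence(schedule.seed).spawn(schedule.n_starts):
        rngs = _block_rngs(int(child.generate_state(1)[0] % 2**31))
        start = random_start(Y, F, rngs["misc"])
        sw = GibbsSweeper(Y, start, cfg, prior, rngs=rngs)
        for it in range(schedule.warmup_iters):
            sw.full_sweep()
            if (it + 1) % cfg.recompute_every == 0:
                sw.recompute_W()
        for it in range(schedule.pilot_iters):
            sw.full_sweep(em=True)
            if (it + 1) % cfg.recompute_every == 0:
                sw.recompute_W()
        sw.recompute_W()
        ll = sw.loglik()
        if ll > best_ll:
            best_sw, best_ll, best_rngs = sw, ll, rngs
    sw, rngs = best_sw, best_rngs

    G, N = Y.values.shape
    W = schedule.average_window
    sums = {
        "beta": np.zeros(G), "phi": np.zeros(F), "theta": np.zeros(F),
        "lam": np.zeros((N, F)), "h1": 0.0, "h2": 0.0,
    }
    alpha_counts = np.zeros((3, G, F), dtype=np.int32)  # index: value + 1
    remaining = schedule.em_iters - schedule.pilot_iters
    for it in range(remaining):
        sw.full_sweep(em=True)
        if (it + 1) % cfg.recompute_every == 0:
            sw.recompute_W()
        if it >= remaining - W:
            s = sw.state
            sums["beta"] += s.beta
            sums["phi"] += s.phi
            sums["theta"] += s.theta
            sums["lam"] += s.lam
            sums["h1"] += s.h1
            sums["h2"] += s.h2
            idx = (s.alpha.astype(np.int32) + 1,
                   np.arange(G)[:, None], np.arange(F)[None, :])
            alpha_counts[idx] += 1

    # modal loading per entry; ties broken uniformly via random priorities
    best = alpha_counts.max(axis=0)
    priority = rngs["misc"].random((3, G, F))
    masked = np.where(alpha_counts == best, priority, -1.0)
    modal = (np.argmax(masked, axis=0) - 1).astype(np.int8)

    return ModelState(
        beta=sums["beta"] / W,
        alpha=modal,
        lam=sums["lam"] / W,
        phi=sums["phi"] / W,
        theta=np.clip(sums["theta"] / W, 0.0, 1.0),
        h1=sums["h1"] / W,
        h2=sums["h2"] / W,
    )
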