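"""Metropolis-within-Gibbs sampler for the Poisson–lognormal factor model.

One sweep visits, in fixed order:

1. beta_g   ~ Gamma (conjugate, exact);
2. theta_f  ~ Beta (conjugate, exact);
3. alpha_gf ~ three-way categorical from its full conditional, column by
   column (genes within a column are conditionally independent, so each
   column is drawn jointly);
4. h1       ~ Normal (conjugate, exact);
5. h2       ~ InverseGamma (conjugate, exact);
6. phi_f    by a lognormal random-walk Metropolis step (prior draw when the
   factor is inactive);
7. lambda_if by an independence Metropolis step with a generalized inverse
   Gaussian proposal shrunk by a factor b on its rate parameters (prior
   draw when the factor is inactive; Gamma / inverse-Gamma limits when one
   rate parameter vanishes).

For speed the sampler maintains W = mu / beta (a G x N matrix) across
sweeps by multiplicative rank-one updates whenever a loading, factor
score, or factor scale changes, with a periodic full recomputation to
bound floating-point drift.  All categorical weights are computed on the
log scale and normalized by log-sum-exp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._gig import gig_logpdf, gig_rvs
from .model_core import ExpressionCounts, ModelState, PriorSpec, pairwise_correlation

__all__ = [
    "SamplerConfig",
    "ChainTrace",
    "run_chain",
    "update_beta",
    "update_theta",
    "update_alpha",
    "update_h1",
    "update_h2",
    "update_phi",
    "update_lambda",
]

_BLOCKS = ("beta", "theta", "alpha", "h1", "h2", "phi", "lam", "misc")

# hard upper bound on the log-scale variance phi: keeps exp(phi/2) finite.
# Values this large are beyond any data-supported regime, so the implied
# prior truncation is immaterial.
PHI_MAX = 700.0


@dataclass
class SamplerConfig:
    """Knobs of the Metropolis-within-Gibbs chain.

    n_iter / n_retain : total sweeps and how many trailing sweeps are
        stored for inference (defaults 4,000 / 1,000).
    phi_proposal_sd : initial scale sigma of the lognormal random walk on
        phi; adapted toward 25–45% acceptance during the pre-retention
        window, then frozen.
    gig_shrink_b : multiplicative shrinkage b in (0, 1] applied to the GIG
        proposal rates to thicken its tails (default 0.9).
    recompute_every : sweeps between full recomputations of W.
    """

    n_iter: int = 4000
    n_retain: int = 1000
    phi_proposal_sd: float = 0.3
    gig_shrink_b: float = 0.9
    seed: int = 0
    adapt_phi: bool = True
    recompute_every: int = 100

    def __post_init__(self):
        if not (0 < self.gig_shrink_b <= 1):
            raise ValueError("gig_shrink_b must lie in (0, 1]")
        if self.n_retain > self.n_iter:
            raise ValueError("n_retain cannot exceed n_iter")


@dataclass
class ChainTrace:
    """Retained draws and summaries from one chain."""

    rho_samples: np.ndarray  # (M, G, G)
    loglik: np.ndarray  # (M,)
    deviance: np.ndarray  # (M,)
    beta_samples: np.ndarray  # (M, G)
    phi_samples: np.ndarray  # (M, F)
    alpha_samples: np.ndarray  # (M, G, F) int8
    acceptance: dict
    final_state: ModelState
    seed: int
    config: SamplerConfig
    failed: str | None = None

    @property
    def n_retained(self) -> int:
        return self.loglik.shape[0]

    @property
    def avg_loglik(self) -> float:
        return float(np.mean(self.loglik))

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            rho_samples=self.rho_samples, loglik=self.loglik,
            deviance=self.deviance, beta_samples=self.beta_samples,
            phi_samples=self.phi_samples, alpha_samples=self.alpha_samples,
            seed=self.seed,
            final_beta=self.final_state.beta, final_alpha=self.final_state.alpha,
            final_lam=self.final_state.lam, final_phi=self.final_state.phi,
            final_theta=self.final_state.theta,
            final_h=[self.final_state.h1, self.final_state.h2],
            acc_phi=self.acceptance.get("phi", np.nan),
            acc_lam=self.acceptance.get("lam", np.nan),
        )

    @classmethod
    def load(cls, path) -> "ChainTrace":
        z = np.load(path)
        state = ModelState(
            beta=z["final_beta"], alpha=z["final_alpha"], lam=z["final_lam"],
            phi=z["final_phi"], theta=z["final_theta"],
            h1=float(z["final_h"][0]), h2=float(z["final_h"][1]),
        )
        return cls(
            rho_samples=z["rho_samples"], loglik=z["loglik"],
            deviance=z["deviance"], beta_samples=z["beta_samples"],
            phi_samples=z["phi_samples"], alpha_samples=z["alpha_samples"],
            acceptance={"phi": float(z["acc_phi"]), "lam": float(z["acc_lam"])},
            final_state=state, seed=int(z["seed"]), config=SamplerConfig(),
        )


def _block_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_BLOCKS))
    return {name: np.random.default_rng(s) for name, s in zip(_BLOCKS, children)}


class GibbsSweeper:
    """Mutable workspace executing sweeps in place over a ModelState."""

    def __init__(self, Y: ExpressionCounts, state: ModelState,
                 cfg: SamplerConfig | None = None,
                 prior: PriorSpec | None = None,
                 rngs: dict | None = None):
        self.cfg = cfg or SamplerConfig()
        self.prior = prior or PriorSpec()
        self.state = state.copy()
        if Y.values.shape != (state.n_genes, state.n_cells):
            raise ValueError("count matrix shape does not match the state")
        self.y = Y.values
        self.yf = self.y.astype(float)
        self.ysum = self.y.sum(axis=1).astype(float)
        from scipy.special import gammaln
        self._lgamma_const = float(np.sum(gammaln(self.y + 1.0)))
        self.rngs = rngs or _block_rngs(self.cfg.seed)
        self.phi_sd = float(self.cfg.phi_proposal_sd)
        self.acc = {"phi": [0, 0], "lam": [0, 0]}
        self.recompute_W()

    # -- W maintenance ---------------------------------------------------
    def recompute_W(self) -> None:
        s = self.state
        alpha = s.alpha.astype(float)
        log_w = alpha @ np.log(s.lam).T - (0.5 * (np.abs(alpha) @ s.phi))[:, None]
        self.W = np.exp(log_w)

    def loglik(self) -> float:
        s = self.state
        with np.errstate(divide="ignore"):
            log_mu = np.log(s.beta)[:, None] + np.log(np.maximum(self.W, 1e-300))
        return float(np.sum(self.yf * log_mu) - np.sum(s.beta[:, None] * self.W)
                     - self._lgamma_const)

    # -- conjugate steps -------------------------------------------------
    def sweep_beta(self) -> None:
        s, pr = self.state, self.prior
        shape = pr.beta_shape + self.ysum
        rate = pr.beta_rate + self.W.sum(axis=1)
        if not np.all(np.isfinite(rate)):
            raise FloatingPointError("non-finite Gamma rate in the beta update")
        s.beta = self.rngs["beta"].gamma(shape, 1.0 / rate)

    def beta_mode(self) -> None:
        """Conditional posterior mode of beta (stochastic-EM step)."""
        s, pr = self.state, self.prior
        shape = pr.beta_shape + self.ysum
        rate = pr.beta_rate + self.W.sum(axis=1)
        s.beta = np.maximum((shape - 1.0) / rate, 1e-4)

    def sweep_theta(self) -> None:
        s, pr = self.state, self.prior
        G = s.n_genes
        k = np.abs(s.alpha).sum(axis=0).astype(float)
        s.theta = self.rngs["theta"].beta(pr.theta_a + k, pr.theta_b + G - k)

    def sweep_h1(self) -> None:
        s, pr = self.state, self.prior
        F = s.n_factors
        prec = 1.0 / pr.h1_var + F / s.h2
        mean = (pr.h1_mean / pr.h1_var + np.sum(np.log(s.phi)) / s.h2) / prec
        s.h1 = float(self.rngs["h1"].normal(mean, np.sqrt(1.0 / prec)))

    def sweep_h2(self) -> None:
        s, pr = self.state, self.prior
        F = s.n_factors
        shape = pr.h2_shape + F / 2.0
        scale = pr.h2_scale + 0.5 * np.sum((np.log(s.phi) - s.h1) ** 2)
        s.h2 = float(1.0 / self.rngs["h2"].gamma(shape, 1.0 / scale))

    # -- alpha -----------------------------------------------------------
    def _alpha_logweights(self, f: int) -> np.ndarray:
        """(3, G) log-weights for alpha_gf in {0, 1, -1} given the rest."""
        s = self.state
        lam_f = s.lam[:, f]
        inv_f = 1.0 / lam_f
        phi_f = s.phi[f]
        a = s.alpha[:, f]
        # psi: product over the other factors, recovered from W by dividing
        # out factor f's own contribution per gene
        own_inv = np.ones(s.n_genes)
        own_inv[a != 0] = np.exp(0.5 * phi_f)
        psi = self.W * own_inv[:, None]
        pos = a == 1
        neg = a == -1
        psi[pos] *= inv_f[None, :]
        psi[neg] *= lam_f[None, :]
        e = np.exp(-0.5 * phi_f)
        S0 = psi @ np.ones_like(lam_f)
        S1 = e * (psi @ lam_f)
        S2 = e * (psi @ inv_f)
        ylog = self.yf @ np.log(lam_f)
        theta_f = s.theta[f]
        with np.errstate(divide="ignore"):
            log_inactive = np.log1p(-theta_f) if theta_f < 1 else -np.inf
            log_active = np.log(theta_f / 2.0) if theta_f > 0 else -np.inf
        lw = np.empty((3, s.n_genes))
        lw[0] = log_inactive - s.beta * S0
        lw[1] = log_active + ylog - 0.5 * phi_f * self.ysum - s.beta * S1
        lw[2] = log_active - ylog - 0.5 * phi_f * self.ysum - s.beta * S2
        if np.any(np.all(np.isneginf(lw), axis=0)):
            raise FloatingPointError(
                f"all three alpha log-weights are -inf in factor {f}"
            )
        return lw, psi, lam_f, inv_f, e

    def _set_alpha_column(self, f, new_a, psi, lam_f, inv_f, e) -> None:
        s = self.state
        changed = new_a != s.alpha[:, f]
        if np.any(changed):
            rows = np.flatnonzero(changed)
            for g in rows:
                if new_a[g] == 0:
                    self.W[g] = psi[g]
                elif new_a[g] == 1:
                    self.W[g] = psi[g] * (e * lam_f)
                else:
                    self.W[g] = psi[g] * (e * inv_f)
            s.alpha[:, f] = new_a

    def sweep_alpha(self, optimize: bool = False) -> None:
        s = self.state
        rng = self.rngs["alpha"]
        values = np.array([0, 1, -1], dtype=np.int8)
        for f in range(s.n_factors):
            lw, psi, lam_f, inv_f, e = self._alpha_logweights(f)
            if optimize:
                choice = np.argmax(lw, axis=0)
            else:
                m = lw.max(axis=0)
                p = np.exp(lw - m)
                p /= p.sum(axis=0)
                u = rng.random(s.n_genes)
                choice = (u >= p[0]).astype(int) + (u >= p[0] + p[1]).astype(int)
            self._set_alpha_column(f, values[choice], psi, lam_f, inv_f, e)

    # -- phi ---------------------------------------------------------------
    def _phi_logpost_terms(self, f: int):
        """Sufficient pieces of log p(phi_f | ...) as a closure over phi."""
        s = self.state
        a = s.alpha[:, f]
        active = a != 0
        N = s.n_cells
        T1 = float(self.ysum @ np.abs(a))
        T2 = float(np.sum(np.log(s.lam[:, f]) ** 2))
        # sum of mu over genes active in f, computed at the current phi_f
        K = float(s.beta[active] @ self.W[active].sum(axis=1))
        phi_old = s.phi[f]

        def logpost(phi):
            return (-(N / 2.0 + 1.0) * np.log(phi)
                    - 0.5 * phi * T1
                    - T2 / (2.0 * phi)
                    - (np.log(phi) - s.h1) ** 2 / (2.0 * s.h2)
                    - K * np.exp(0.5 * (phi_old - phi)))

        return logpost, active, phi_old

    def sweep_phi(self, optimize: bool = False, factors=None) -> None:
        s = self.state
        rng = self.rngs["phi"]
        for f in range(s.n_factors) if factors is None else factors:
            a = s.alpha[:, f]
            if not np.any(a != 0):
                # prior draw; log-scale clamp keeps downstream arithmetic finite
                z = np.clip(rng.normal(s.h1, np.sqrt(s.h2)), -30.0, np.log(PHI_MAX))
                s.phi[f] = float(np.exp(z))
                continue
            logpost, active, phi_old = self._phi_logpost_terms(f)
            if optimize:
                from scipy.optimize import minimize_scalar
                res = minimize_scalar(
                    lambda t: -logpost(np.exp(t)),
                    bounds=(np.log(1e-6), np.log(PHI_MAX)), method="bounded",
                )
                if not res.success:
                    warnings.warn(f"phi optimizer did not converge in factor {f}")
                    continue
                phi_new = float(np.exp(res.x))
                accept = True
            else:
                phi_new = float(np.exp(np.log(phi_old) + self.phi_sd * rng.normal()))
                if phi_new > PHI_MAX:
                    log_ratio = -np.inf
                else:
                    log_ratio = (logpost(phi_new) - logpost(phi_old)
                                 + np.log(phi_new) - np.log(phi_old))
                accept = np.log(rng.random()) < log_ratio
                self.acc["phi"][1] += 1
                self.acc["phi"][0] += int(accept)
            if accept and phi_new != phi_old:
                self.W[active] *= np.exp(0.5 * (phi_old - phi_new))
                s.phi[f] = phi_new

    # -- lambda ------------------------------------------------------------
    def sweep_lambda(self, factors=None) -> None:
        s = self.state
        rng = self.rngs["lam"]
        b = self.cfg.gig_shrink_b
        for f in range(s.n_factors) if factors is None else factors:
            a = s.alpha[:, f]
            pos = a == 1
            neg = a == -1
            phi_f = s.phi[f]
            if not pos.any() and not neg.any():
                z = np.clip(rng.normal(0.0, np.sqrt(phi_f), s.n_cells), -30.0, 30.0)
                s.lam[:, f] = np.exp(z)
                continue
            lam_old = s.lam[:, f]
            kappa = a.astype(float) @ self.yf  # (N,)
            P = s.beta[pos] @ self.W[pos] if pos.any() else np.zeros(s.n_cells)
            M = s.beta[neg] @ self.W[neg] if neg.any() else np.zeros(s.n_cells)
            tau = 2.0 * P / lam_old
            chi = 2.0 * M * lam_old
            log_lam_old = np.log(lam_old)

            def logpost(lam, log_lam):
                return ((kappa - 1.0) * log_lam
                        - 0.5 * (tau * lam + chi / lam + log_lam**2 / phi_f))

            cand = np.empty(s.n_cells)
            dlogq = np.empty(s.n_cells)  # log q(old) - log q(cand)
            if pos.any() and neg.any():
                cand[:] = gig_rvs(kappa, b * tau, b * chi, rng)
                dlogq[:] = (gig_logpdf(lam_old, kappa, b * tau, b * chi)
                            - gig_logpdf(cand, kappa, b * tau, b * chi))
            else:
                rate = 0.5 * b * (tau if pos.any() else chi)
                proper = kappa > 0 if pos.any() else kappa < 0
                k_abs = np.abs(kappa[proper])
                draw = rng.gamma(k_abs, 1.0 / rate[proper])
                if neg.any():
                    draw = 1.0 / draw
                cand[proper] = draw
                x_or_inv = lambda x: x if pos.any() else 1.0 / x
                dlogq[proper] = (
                    (kappa[proper] - 1.0) * np.log(lam_old[proper])
                    - rate[proper] * x_or_inv(lam_old[proper])
                    - (kappa[proper] - 1.0) * np.log(cand[proper])
                    + rate[proper] * x_or_inv(cand[proper])
                )
                # kappa of the "wrong" sign (or zero): lognormal-prior proposal
                rest = ~proper
                if rest.any():
                    z = np.clip(rng.normal(0.0, np.sqrt(phi_f), int(rest.sum())),
                                -30.0, 30.0)
                    cand[rest] = np.exp(z)
                    dlogq[rest] = (
                        -log_lam_old[rest] - log_lam_old[rest] ** 2 / (2 * phi_f)
                        + z + z**2 / (2 * phi_f)
                    )
            log_cand = np.log(cand)
            log_ratio = logpost(cand, log_cand) - logpost(lam_old, log_lam_old) + dlogq
            accept = np.log(rng.random(s.n_cells)) < log_ratio
            self.acc["lam"][1] += s.n_cells
            self.acc["lam"][0] += int(accept.sum())
            if accept.any():
                idx = np.flatnonzero(accept)
                ratio = cand[idx] / lam_old[idx]
                if pos.any():
                    self.W[np.ix_(pos, idx)] *= ratio[None, :]
                if neg.any():
                    self.W[np.ix_(neg, idx)] /= ratio[None, :]
                s.lam[idx, f] = cand[idx]

    # -- orchestration -----------------------------------------------------
    def full_sweep(self, em: bool = False) -> None:
        """One sweep through steps 1-7; EM mode optimizes beta, alpha, phi."""
        if em:
            self.beta_mode()
        else:
            self.sweep_beta()
        self.sweep_theta()
        self.sweep_alpha(optimize=em)
        self.sweep_h1()
        self.sweep_h2()
        self.sweep_phi(optimize=em)
        self.sweep_lambda()

    def adapt_phi_sd(self) -> None:
        acc, tot = self.acc["phi"]
        if tot == 0:
            return
        rate = acc / tot
        if rate < 0.25:
            self.phi_sd *= 0.7
        elif rate > 0.45:
            self.phi_sd *= 1.4
        self.acc["phi"] = [0, 0]


def run_chain(Y: ExpressionCounts, init: ModelState,
              cfg: SamplerConfig | None = None,
              prior: PriorSpec | None = None) -> ChainTrace:
    """Run one chain for ``cfg.n_iter`` sweeps and retain the last
    ``cfg.n_retain`` draws of (rho, beta, phi, alpha, log-likelihood)."""
    cfg = cfg or SamplerConfig()
    sw = GibbsSweeper(Y, init, cfg, prior)
    G, F = init.n_genes, init.n_factors
    M = cfg.n_retain
    rho = np.empty((M, G, G))
    ll = np.empty(M)
    beta_s = np.empty((M, G))
    phi_s = np.empty((M, F))
    alpha_s = np.empty((M, G, F), dtype=np.int8)
    start_retain = cfg.n_iter - M
    failed = None
    m = 0
    try:
        for it in range(cfg.n_iter):
            sw.full_sweep()
            if (it + 1) % cfg.recompute_every == 0:
                sw.recompute_W()
            if cfg.adapt_phi and it < start_retain and (it + 1) % 50 == 0:
                sw.adapt_phi_sd()
            if it == start_retain - 1:
                sw.acc = {"phi": [0, 0], "lam": [0, 0]}
            if it >= start_retain:
                s = sw.state
                rho[m] = pairwise_correlation(s.alpha, s.phi)
                ll[m] = sw.loglik()
                beta_s[m] = s.beta
                phi_s[m] = s.phi
                alpha_s[m] = s.alpha
                m += 1
    except FloatingPointError as exc:  # record the partial trace
        failed = str(exc)
    acc = {k: (v[0] / v[1] if v[1] else np.nan) for k, v in sw.acc.items()}
    return ChainTrace(
        rho_samples=rho[:m], loglik=ll[:m], deviance=-2.0 * ll[:m],
        beta_samples=beta_s[:m], phi_samples=phi_s[:m],
        alpha_samples=alpha_s[:m], acceptance=acc,
        final_state=sw.state.copy(), seed=cfg.seed, config=cfg, failed=failed,
    )


# ---------------------------------------------------------------------------
# Single-step functional wrappers (used heavily in tests and diagnostics).
# Each returns the updated quantity without mutating the input state.

def _sweeper(Y, state, rng, cfg=None, prior=None):
    sw = GibbsSweeper(Y, state, cfg, prior)
    for k in sw.rngs:
        sw.rngs[k] = rng
    return sw


def update_beta(Y, state, rng, prior=None):
    sw = _sweeper(Y, state, rng, prior=prior)
    sw.sweep_beta()
    return sw.state.beta


def update_theta(state, rng, prior=None):
    Y = ExpressionCounts(np.zeros((state.n_genes, state.n_cells), dtype=int))
    sw = _sweeper(Y, state, rng, prior=prior)
    sw.sweep_theta()
    return sw.state.theta


def update_alpha(Y, state, rng, prior=None):
    sw = _sweeper(Y, state, rng, prior=prior)
    sw.sweep_alpha()
    return sw.state.alpha


def update_h1(state, rng, prior=None):
    Y = ExpressionCounts(np.zeros((state.n_genes, state.n_cells), dtype=int))
    sw = _sweeper(Y, state, rng, prior=prior)
    sw.sweep_h1()
    return sw.state.h1


def update_h2(state, rng, prior=None):
    Y = ExpressionCounts(np.zeros((state.n_genes, state.n_cells), dtype=int))
    sw = _sweeper(Y, state, rng, prior=prior)
    sw.sweep_h2()
    return sw.state.h2


def update_phi(Y, state, cfg, rng, prior=None):
    sw = _sweeper(Y, state, rng, cfg=cfg, prior=prior)
    sw.sweep_phi()
    return sw.state.phi


def update_lambda(Y, state, cfg, rng, prior=None):
    sw = _sweeper(Y, state, rng, cfg=cfg, prior=prior)
    sw.sweep_lambda()
    return sw.state.lam
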