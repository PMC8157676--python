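"""Single-site Gibbs sampler for the single-trait BayesC-pi model.

The model for individual i is

    y_i = mu + sum_j m_ij alpha_j + e_i,      e_i ~ N(0, sigma2_e)

with a flat prior on the intercept mu, and for every marker effect the
BayesC-pi spike-and-slab mixture: alpha_j = 0 with probability pi, and
alpha_j ~ N(0, sigma2_alpha) with probability 1 - pi.  Both variances carry
scaled inverse chi-square priors and pi carries a uniform prior.

Each sweep updates, in fixed order: mu from its normal full conditional;
every (delta_j, alpha_j) pair jointly from the exact two-component
conditional, marginalising alpha_j when computing the inclusion odds; pi
from its Beta conjugate; sigma2_alpha and sigma2_e from scaled inverse
chi-square conditionals.  Genotype columns are centered internally (the
intercept absorbs the shift); all downstream variance summaries are
shift-invariant so results are unchanged.

The per-locus loop is compiled with numba; every random number is drawn
from one numpy Generator in the Python driver, so a chain is bit-identical
given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from numba import njit

from .data_io import GenotypeMatrix, PhenotypeVector

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "ModelState",
    "PosteriorDraws",
    "PosteriorSummary",
    "gibbs_sweep",
    "run_bayescpi",
    "posterior_summaries",
]

_PI_EPS = 1e-8  # pi clipped to [eps, 1-eps] unless pinned at an endpoint


@dataclass
class PriorSpec:
    """Hyperparameters for the variance priors.

    ``scale_e`` and ``scale_alpha`` may be left unset; they are then resolved
    from the phenotypic variance following the GenSel/JWAS convention:
    ``scale_e`` makes the prior mean of sigma2_e equal to
    ``Var(y) * (1 - genetic_variance_guess)``, and ``scale_alpha`` makes the
    prior mean of sigma2_alpha equal to
    ``guess * Var(y) / ((1 - pi0) * sum_j 2 f_j (1 - f_j))`` with pi0 = 0.5.
    """

    nu_alpha: float = 4.0
    scale_alpha: float | None = None
    nu_e: float = 4.0
    scale_e: float | None = None
    genetic_variance_guess: float = 0.5

    def __post_init__(self) -> None:
        if self.nu_alpha <= 2 or self.nu_e <= 2:
            raise ValueError("degrees of freedom must exceed 2 for a finite prior mean")
        if not 0.0 < self.genetic_variance_guess < 1.0:
            raise ValueError("genetic_variance_guess must lie in (0, 1)")

    def resolved(self, y: np.ndarray, freqs: np.ndarray) -> "PriorSpec":
        """Fill in unset scales from the data (population Var(y), allele freqs)."""
        var_y = float(np.var(y))
        scale_e = self.scale_e
        if scale_e is None:
            scale_e = var_y * (1.0 - self.genetic_variance_guess) * (self.nu_e - 2) / self.nu_e
        scale_alpha = self.scale_alpha
        if scale_alpha is None:
            het = float(np.sum(2.0 * freqs * (1.0 - freqs)))
            if het <= 0:
                het = 1.0  # intercept-only model; value is inconsequential
            mean_s2a = self.genetic_variance_guess * var_y / (0.5 * het)
            scale_alpha = mean_s2a * (self.nu_alpha - 2) / self.nu_alpha
        return replace(self, scale_e=scale_e, scale_alpha=scale_alpha)


@dataclass
class ChainConfig:
    """MCMC run length; (n_iter - burn_in)/thin >= 100 is advisable for WPPA."""

    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.thin <= 0:
            raise ValueError("n_iter and thin must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ModelState:
    mu: float
    alpha: np.ndarray
    delta: np.ndarray
    pi: float
    sigma2_alpha: float
    sigma2_e: float


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in samples of the model state.

    ``alpha`` and ``include`` are (n_stored, p); scalar chains are 1-D.
    """

    mu: np.ndarray
    alpha: np.ndarray
    include: np.ndarray
    pi: np.ndarray
    sigma2_alpha: np.ndarray
    sigma2_e: np.ndarray
    chain: ChainConfig
    prior: PriorSpec
    n_samples: int

    @property
    def n_stored(self) -> int:
        return len(self.mu)

    @property
    def n_markers(self) -> int:
        return self.alpha.shape[1]

    def save(self, path) -> None:
        """Serialize to an HDF5 container with full chain metadata."""
        with h5py.File(path, "w") as fh:
            for name in ("mu", "alpha", "include", "pi", "sigma2_alpha", "sigma2_e"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.attrs["n_samples"] = self.n_samples
            for k, v in vars(self.chain).items():
                fh.attrs[f"chain_{k}"] = v
            for k, v in vars(self.prior).items():
                fh.attrs[f"prior_{k}"] = -1.0 if v is None else v

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with h5py.File(path, "r") as fh:
            arrays = {
                name: fh[name][...]
                for name in ("mu", "alpha", "include", "pi", "sigma2_alpha", "sigma2_e")
            }
            chain = ChainConfig(
                n_iter=int(fh.attrs["chain_n_iter"]),
                burn_in=int(fh.attrs["chain_burn_in"]),
                thin=int(fh.attrs["chain_thin"]),
                seed=int(fh.attrs["chain_seed"]),
            )
            prior = PriorSpec(
                nu_alpha=float(fh.attrs["prior_nu_alpha"]),
                scale_alpha=float(fh.attrs["prior_scale_alpha"]),
                nu_e=float(fh.attrs["prior_nu_e"]),
                scale_e=float(fh.attrs["prior_scale_e"]),
                genetic_variance_guess=float(fh.attrs["prior_genetic_variance_guess"]),
            )
            n = int(fh.attrs["n_samples"])
        return cls(chain=chain, prior=prior, n_samples=n, **arrays)


@njit(cache=True)
def _locus_sweep(Mc, mjj, e, alpha, delta, log_prior_odds, s2a, s2e,
                 u, z, force, backward):  # pragma: no cover - compiled
    """Joint (delta_j, alpha_j) updates for all loci; mutates e/alpha/delta.

    ``force`` is +1 to always include, -1 to always exclude, 0 to sample with
    ``log_prior_odds`` = log((1-pi)/pi).  ``u`` and ``z`` are per-locus
    uniform/normal variates supplied by the caller.
    """
    n, p = Mc.shape
    for jj in range(p):
        j = p - 1 - jj if backward else jj
        mj2 = mjj[j]
        if mj2 <= 0.0:
            if force == 1:
                return j  # constant column cannot carry an effect
            alpha[j] = 0.0
            delta[j] = 0
            continue
        a_old = alpha[j]
        r = mj2 * a_old
        for i in range(n):
            r += Mc[i, j] * e[i]
        c = mj2 + s2e / s2a
        if force == 1:
            incl = True
        elif force == -1:
            incl = False
        else:
            log_odds = (log_prior_odds
                        + 0.5 * math.log(s2e / (c * s2a))
                        + r * r / (2.0 * s2e * c))
            if log_odds > 35.0:
                incl = True
            elif log_odds < -35.0:
                incl = False
            else:
                incl = u[j] < 1.0 / (1.0 + math.exp(-log_odds))
        if incl:
            a_new = r / c + z[j] * math.sqrt(s2e / c)
            delta[j] = 1
        else:
            a_new = 0.0
            delta[j] = 0
        diff = a_new - a_old
        if diff != 0.0:
            for i in range(n):
                e[i] -= Mc[i, j] * diff
        alpha[j] = a_new
    return -1


def _draw_scaled_inv_chi2(rng: np.random.Generator, nu: float, nu_scale: float) -> float:
    """One draw of sigma2 ~ scaled-inv-chi2(nu, nu_scale/nu): nu_scale / chi2_nu."""
    return nu_scale / rng.chisquare(nu)


class _Sampler:
    """Mutable chain state plus one full-conditional sweep."""

    def __init__(self, G, y, prior, rng, *, pi_fixed=None,
                 sigma2_alpha_fixed=None, sigma2_e_fixed=None,
                 update_order="forward"):
        yv = np.asarray(y.values if isinstance(y, PhenotypeVector) else y, float)
        M = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
        if M.shape[0] != len(yv):
            raise ValueError("genotype rows and phenotype length differ")
        if len(yv) < 2:
            raise ValueError("at least two individuals are required")
        if not np.all(np.isfinite(yv)):
            raise ValueError("phenotypes must be finite")
        self.n, self.p = M.shape
        self.y = yv
        self.Mc = np.asfortranarray(M - M.mean(axis=0))
        self.mjj = np.einsum("ij,ij->j", self.Mc, self.Mc)
        freqs = M.sum(axis=0) / (2.0 * self.n) if self.p else np.empty(0)
        self.prior = prior.resolved(yv, freqs)
        self.rng = rng
        self.pi_fixed = pi_fixed
        self.s2a_fixed = sigma2_alpha_fixed
        self.s2e_fixed = sigma2_e_fixed
        self.backward = update_order == "backward"
        var_y = float(np.var(yv))
        guess = self.prior.genetic_variance_guess
        het = float(np.sum(2.0 * freqs * (1.0 - freqs))) if self.p else 1.0
        # initial state: mu = ybar, all effects out, pi = 1/2
        self.mu = float(np.mean(yv))
        self.alpha = np.zeros(self.p)
        self.delta = np.zeros(self.p, dtype=np.uint8)
        self.pi = 0.5 if pi_fixed is None else float(pi_fixed)
        self.sigma2_e = var_y / 2.0 if sigma2_e_fixed is None else float(sigma2_e_fixed)
        if sigma2_alpha_fixed is not None:
            self.sigma2_alpha = float(sigma2_alpha_fixed)
        else:
            self.sigma2_alpha = guess * var_y / (0.5 * max(het, 1e-12))
        self.e = yv - self.mu  # alpha starts at zero

    def sweep(self) -> None:
        rng = self.rng
        # (1) intercept, flat prior: mu | rest ~ N(mean(y - M alpha), s2e/n)
        mu_new = self.mu + float(np.mean(self.e)) + rng.standard_normal() * math.sqrt(
            self.sigma2_e / self.n
        )
        self.e -= mu_new - self.mu
        self.mu = mu_new
        # (2) joint (delta_j, alpha_j) for every locus
        if self.p:
            if self.pi_fixed is not None and self.pi_fixed <= _PI_EPS:
                force, lpo = 1, 0.0
            elif self.pi_fixed is not None and self.pi_fixed >= 1.0 - _PI_EPS:
                force, lpo = -1, 0.0
            else:
                pi = min(max(self.pi, _PI_EPS), 1.0 - _PI_EPS)
                force, lpo = 0, math.log((1.0 - pi) / pi)
            bad = _locus_sweep(
                self.Mc, self.mjj, self.e, self.alpha, self.delta, lpo,
                self.sigma2_alpha, self.sigma2_e,
                rng.random(self.p), rng.standard_normal(self.p),
                force, self.backward,
            )
            if bad >= 0:
                raise FloatingPointError(
                    f"constant genotype column {bad} with inclusion forced on; "
                    "apply the MAF filter first"
                )
        m = int(self.delta.sum())
        # (3) pi | delta ~ Beta(#excluded + 1, #included + 1)
        if self.pi_fixed is None:
            self.pi = float(np.clip(rng.beta(self.p - m + 1, m + 1), _PI_EPS, 1 - _PI_EPS))
        # (4) sigma2_alpha | alpha, delta
        if self.s2a_fixed is None:
            ssq = float(np.sum(self.alpha[self.delta == 1] ** 2))
            self.sigma2_alpha = _draw_scaled_inv_chi2(
                rng, self.prior.nu_alpha + m,
                ssq + self.prior.nu_alpha * self.prior.scale_alpha,
            )
        # (5) sigma2_e | e
        if self.s2e_fixed is None:
            sse = float(self.e @ self.e)
            self.sigma2_e = _draw_scaled_inv_chi2(
                rng, self.prior.nu_e + self.n,
                sse + self.prior.nu_e * self.prior.scale_e,
            )

    def state(self) -> ModelState:
        return ModelState(self.mu, self.alpha.copy(), self.delta.copy(),
                          self.pi, self.sigma2_alpha, self.sigma2_e)


def gibbs_sweep(state: ModelState, G: GenotypeMatrix, y: PhenotypeVector,
                prior: PriorSpec, rng: np.random.Generator, **pins) -> ModelState:
    """Advance a model state by one full Gibbs sweep and return the new state.

    Convenience wrapper over the same kernel :func:`run_bayescpi` uses;
    ``pins`` forwards ``pi_fixed`` / ``sigma2_alpha_fixed`` /
    ``sigma2_e_fixed`` / ``update_order``.
    """
    s = _Sampler(G, y, prior, rng, **pins)
    s.mu = state.mu
    s.alpha = state.alpha.astype(float).copy()
    s.delta = state.delta.astype(np.uint8).copy()
    if s.pi_fixed is None:
        s.pi = state.pi
    if s.s2a_fixed is None:
        s.sigma2_alpha = state.sigma2_alpha
    if s.s2e_fixed is None:
        s.sigma2_e = state.sigma2_e
    s.e = s.y - s.mu - s.Mc @ s.alpha
    s.sweep()
    return s.state()


def run_bayescpi(G: GenotypeMatrix, y: PhenotypeVector,
                 prior: PriorSpec | None = None,
                 chain: ChainConfig | None = None,
                 *, pi_fixed: float | None = None,
                 sigma2_alpha_fixed: float | None = None,
                 sigma2_e_fixed: float | None = None,
                 update_order: str = "forward") -> PosteriorDraws:
    """Run the BayesC-pi Gibbs chain and return thinned post-burn-in draws.

    Deterministic given ``chain.seed``.  The ``*_fixed`` pins hold a
    parameter constant (used for conjugate-oracle validation); ``pi_fixed=0``
    forces every marker into the model, ``pi_fixed=1`` excludes all.
    """
    prior = prior or PriorSpec()
    chain = chain or ChainConfig()
    rng = np.random.default_rng(chain.seed)
    s = _Sampler(G, y, prior, rng, pi_fixed=pi_fixed,
                 sigma2_alpha_fixed=sigma2_alpha_fixed,
                 sigma2_e_fixed=sigma2_e_fixed, update_order=update_order)
    S = chain.n_stored
    mu = np.empty(S)
    alpha = np.empty((S, s.p))
    include = np.empty((S, s.p), dtype=bool)
    pi = np.empty(S)
    s2a = np.empty(S)
    s2e = np.empty(S)
    k = 0
    for it in range(chain.n_iter):
        s.sweep()
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0 and k < S:
            mu[k] = s.mu
            alpha[k] = s.alpha
            include[k] = s.delta.astype(bool)
            pi[k] = s.pi
            s2a[k] = s.sigma2_alpha
            s2e[k] = s.sigma2_e
            k += 1
    return PosteriorDraws(mu=mu[:k], alpha=alpha[:k], include=include[:k],
                          pi=pi[:k], sigma2_alpha=s2a[:k], sigma2_e=s2e[:k],
                          chain=chain, prior=s.prior, n_samples=s.n)


@dataclass
class PosteriorSummary:
    markers: pd.DataFrame  # effect_mean, inclusion_freq per marker
    pi_mean: float
    sigma2_alpha_mean: float
    sigma2_e_mean: float


def posterior_summaries(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior mean effects, inclusion frequencies and scalar means."""
    if draws.n_stored == 0:
        raise ValueError("no stored draws to summarize")
    markers = pd.DataFrame(
        {
            "effect_mean": draws.alpha.mean(axis=0),
            "inclusion_freq": draws.include.mean(axis=0),
        }
    )
    return PosteriorSummary(
        markers=markers,
        pi_mean=float(draws.pi.mean()),
        sigma2_alpha_mean=float(draws.sigma2_alpha.mean()),
        sigma2_e_mean=float(draws.sigma2_e.mean()),
    )
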