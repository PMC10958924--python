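"""Bayesian two-test latent-class prevalence model.

Two imperfect binary classifiers (here TPBF- and RFM-based obesity calls)
applied to one population cross-classify subjects into four cells.  With
prevalence π, sensitivities δ1, δ2 and specificities γ1, γ2, and errors
conditionally independent given true status, the cell probabilities are

    p11 = π·δ1·δ2 + (1−π)(1−γ1)(1−γ2)
    p10 = π·δ1·(1−δ2) + (1−π)(1−γ1)·γ2
    p01 = π·(1−δ1)·δ2 + (1−π)·γ1·(1−γ2)
    p00 = π·(1−δ1)(1−δ2) + (1−π)·γ1·γ2

and the counts are multinomial.  With two tests and one population the
data carry 3 degrees of freedom against 5 parameters, so the model is
identified only through informative priors; all five parameters get Beta
priors and the posterior is explored by a data-augmented Gibbs sampler
(the latent true-status split of each cell is Binomial-conditional, after
which every parameter update is conjugate Beta).  A dense-lattice
numerical integration over the 5-dimensional unit cube serves as an
independent oracle for small counts, and posterior-predictive replicate
counts check model fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp, xlogy

from adipometry.errors import ConfigurationError, DomainError

PARAM_NAMES = ("pi", "sens1", "spec1", "sens2", "spec2")


@dataclass(frozen=True)
class TwoTestCounts:
    """Cross-classified counts; index 1 = TPBF call, index 2 = RFM call."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        cells = self.as_array()
        if np.any(cells < 0) or not np.issubdtype(cells.dtype, np.integer):
            raise DomainError("cell counts must be non-negative integers")
        if cells.sum() <= 0:
            raise DomainError("total count must be positive")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        return np.array([self.n11, self.n10, self.n01, self.n00])

    @classmethod
    def from_labels(cls, test1, test2) -> "TwoTestCounts":
        t1 = np.asarray(test1).astype(bool)
        t2 = np.asarray(test2).astype(bool)
        if t1.shape != t2.shape:
            raise DomainError("test result vectors must have equal length")
        return cls(
            int((t1 & t2).sum()),
            int((t1 & ~t2).sum()),
            int((~t1 & t2).sum()),
            int((~t1 & ~t2).sum()),
        )


def elicit_beta_prior(center: float, ess: float) -> tuple[float, float]:
    """Beta(a, b) with mean ``center`` and prior effective sample size ``ess``.

    a = center·ess, b = (1−center)·ess; (0.5, 2) gives the uniform prior.
    """
    if not 0 < center < 1:
        raise DomainError("center must lie strictly in (0, 1)")
    if ess <= 0:
        raise DomainError("ess must be positive")
    return center * ess, (1 - center) * ess


@dataclass
class PriorSpec:
    """Independent Beta priors for (π, δ1, γ1, δ2, γ2)."""

    pi: tuple[float, float] = (1.0, 1.0)
    sens1: tuple[float, float] = (1.0, 1.0)
    spec1: tuple[float, float] = (1.0, 1.0)
    sens2: tuple[float, float] = (1.0, 1.0)
    spec2: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        for name in PARAM_NAMES:
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigurationError(f"Beta hyperparameters for {name} must be positive")

    def as_dict(self) -> dict:
        return {name: tuple(getattr(self, name)) for name in PARAM_NAMES}

    def all_uniform(self) -> bool:
        return all(getattr(self, name) == (1.0, 1.0) for name in PARAM_NAMES)

    @classmethod
    def from_accuracy(
        cls,
        sens1: float,
        spec1: float,
        sens2: float,
        spec2: float,
        ess: float = 50.0,
        pi: tuple[float, float] = (1.0, 1.0),
    ) -> "PriorSpec":
        """Informative test-accuracy priors centered at ROC-stage estimates."""
        return cls(
            pi=pi,
            sens1=elicit_beta_prior(sens1, ess),
            spec1=elicit_beta_prior(spec1, ess),
            sens2=elicit_beta_prior(sens2, ess),
            spec2=elicit_beta_prior(spec2, ess),
        )


def cell_probabilities(pi, sens1, spec1, sens2, spec2):
    """(p11, p10, p01, p00) under conditional independence; sums to 1."""
    args = [np.asarray(a, dtype=float) for a in (pi, sens1, spec1, sens2, spec2)]
    if any(np.any((a < 0) | (a > 1)) for a in args):
        raise DomainError("all parameters must lie in [0, 1]")
    pi, d1, g1, d2, g2 = args
    p11 = pi * d1 * d2 + (1 - pi) * (1 - g1) * (1 - g2)
    p10 = pi * d1 * (1 - d2) + (1 - pi) * (1 - g1) * g2
    p01 = pi * (1 - d1) * d2 + (1 - pi) * g1 * (1 - g2)
    p00 = pi * (1 - d1) * (1 - d2) + (1 - pi) * g1 * g2
    return p11, p10, p01, p00


def log_likelihood(counts: TwoTestCounts, params) -> float:
    """Multinomial log-likelihood kernel Σ n_ab·log p_ab (constants dropped).

    ``params`` is (π, δ1, γ1, δ2, γ2).  A zero cell probability facing a
    positive count yields −inf.
    """
    probs = np.array(cell_probabilities(*params))
    n = counts.as_array()
    if np.any((probs == 0) & (n > 0)):
        return float("-inf")
    return float(xlogy(n, probs).sum())


@dataclass
class PrevalencePosterior:
    """Posterior draws and summaries for (π, δ1, γ1, δ2, γ2).

    ``draws[name]`` has shape (chains, iterations) of post-warmup samples.
    """

    draws: dict
    chains: int
    warmup: int
    iterations: int
    seed: int
    priors: PriorSpec
    counts: TwoTestCounts
    warnings: list = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def summary(self) -> pd.DataFrame:
        import arviz as az

        idata = az.from_dict(posterior=self.draws)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        rows = []
        for name in PARAM_NAMES:
            x = self.flat(name)
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append(
                {
                    "param": name,
                    "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)),
                    "median": float(np.median(x)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "rhat": float(rhat[name].values),
                    "ess_bulk": float(ess[name].values),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def credible_interval(self, name: str = "pi", level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed posterior interval."""
        alpha = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.flat(name), [alpha, 100 - alpha])
        return float(lo), float(hi)


def _gibbs_chain(counts, priors, warmup, iters, rng):
    n = counts.as_array().astype(np.int64)
    a_pi, b_pi = priors.pi
    a_d1, b_d1 = priors.sens1
    a_g1, b_g1 = priors.spec1
    a_d2, b_d2 = priors.sens2
    a_g2, b_g2 = priors.spec2

    # overdispersed start from the priors
    pi = rng.beta(a_pi, b_pi)
    d1 = rng.beta(a_d1, b_d1)
    g1 = rng.beta(a_g1, b_g1)
    d2 = rng.beta(a_d2, b_d2)
    g2 = rng.beta(a_g2, b_g2)

    out = np.empty((iters, 5))
    for it in range(warmup + iters):
        # P(diseased | cell): ratio of the diseased term to the cell total
        dis = np.array(
            [d1 * d2, d1 * (1 - d2), (1 - d1) * d2, (1 - d1) * (1 - d2)]
        ) * pi
        hea = np.array(
            [(1 - g1) * (1 - g2), (1 - g1) * g2, g1 * (1 - g2), g1 * g2]
        ) * (1 - pi)
        tot = dis + hea
        theta = np.where(tot > 0, dis / np.where(tot > 0, tot, 1.0), 0.0)
        y = rng.binomial(n, theta)  # latent true positives per cell
        ypos = int(y.sum())
        yneg = int(n.sum() - ypos)
        z = n - y  # true negatives per cell

        pi = rng.beta(a_pi + ypos, b_pi + yneg)
        d1 = rng.beta(a_d1 + y[0] + y[1], b_d1 + y[2] + y[3])
        g1 = rng.beta(a_g1 + z[2] + z[3], b_g1 + z[0] + z[1])
        d2 = rng.beta(a_d2 + y[0] + y[2], b_d2 + y[1] + y[3])
        g2 = rng.beta(a_g2 + z[1] + z[3], b_g2 + z[0] + z[2])
        if it >= warmup:
            out[it - warmup] = (pi, d1, g1, d2, g2)
    return out


def sample_posterior(
    counts: TwoTestCounts,
    priors: PriorSpec,
    chains: int = 4,
    warmup: int = 2000,
    iters: int = 2000,
    seed: int = 0,
    allow_uniform: bool = False,
) -> PrevalencePosterior:
    """Draw from the joint posterior by data-augmented Gibbs sampling.

    Each sweep imputes the latent true-status split of every observed cell
    (Binomial full conditional) and then updates π, δ1, γ1, δ2, γ2 from
    conjugate Beta full conditionals.  Deterministic given ``seed``.

    With all-uniform priors the model is non-identified (3 degrees of
    freedom against 5 parameters) and the call is refused unless
    ``allow_uniform=True``.  Split-R̂ > 1.01 on any parameter attaches a
    non-convergence warning (never silent).
    """
    if chains < 2:
        raise ConfigurationError("at least 2 chains are required for diagnostics")
    if priors.all_uniform() and not allow_uniform:
        raise ConfigurationError(
            "all-uniform priors leave the two-test one-population model "
            "non-identified; supply informative priors or set allow_uniform=True"
        )
    seeds = np.random.SeedSequence(seed).spawn(chains)
    raw = np.stack(
        [
            _gibbs_chain(counts, priors, warmup, iters, np.random.default_rng(s))
            for s in seeds
        ]
    )  # (chains, iters, 5)
    draws = {name: raw[:, :, i] for i, name in enumerate(PARAM_NAMES)}
    post = PrevalencePosterior(
        draws=draws,
        chains=chains,
        warmup=warmup,
        iterations=iters,
        seed=seed,
        priors=priors,
        counts=counts,
    )
    summ = post.summary()
    bad = summ.index[summ["rhat"] > 1.01].tolist()
    if bad:
        msg = f"possible non-convergence: split R-hat > 1.01 for {bad}"
        post.warnings.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return post


def grid_posterior_oracle(
    counts: TwoTestCounts, priors: PriorSpec, grid_size: int = 51
) -> dict:
    """Lattice-integration oracle for the posterior of π (small counts).

    Integrates prior × likelihood over a midpoint-rule lattice in the
    5-dimensional unit cube, marginalizes to π, and returns its posterior
    mean and equal-tailed 95% interval.  Independent of the Gibbs sampler;
    intended to cross-check it on small counts, where the likelihood is
    smooth enough for the lattice to resolve.

    The 5-dimensional lattice sum is evaluated by expanding each cell
    probability binomially over its latent true-status split, after which
    the summand factorizes across the five parameter axes into 1-d lattice
    sums; this reorganization is exact (finite sums commute), so the
    result equals the naive full-lattice sum while the cost stays
    proportional to the number of latent splits times the grid size.
    """
    if grid_size < 51:
        raise ConfigurationError("grid_size must be at least 51")
    n_cells = counts.as_array()
    n_combos = int(np.prod(n_cells + 1))
    if counts.n > 2000 or n_combos > 2_000_000:
        raise ConfigurationError(
            "counts too large for the lattice oracle (likelihood too peaked); "
            "use sample_posterior instead"
        )
    g = grid_size
    q = (np.arange(g) + 0.5) / g
    logq = np.log(q)
    log1mq = np.log1p(-q)
    logw = {name: stats.beta.logpdf(q, *getattr(priors, name)) for name in PARAM_NAMES}
    n_tot = counts.n

    def log_m_table(name: str, s_max: int, f_max: int) -> np.ndarray:
        """log Σ_i w[i]·q_i^s·(1−q_i)^f for s ≤ s_max, f ≤ f_max."""
        # (s, f, grid) log-summands, reduced over the grid axis
        lt = (
            np.arange(s_max + 1)[:, None, None] * logq[None, None, :]
            + np.arange(f_max + 1)[None, :, None] * log1mq[None, None, :]
            + logw[name][None, None, :]
        )
        return logsumexp(lt, axis=2)

    n11, n10, n01, n00 = (int(v) for v in n_cells)
    m_d1 = log_m_table("sens1", n11 + n10, n01 + n00)
    m_g1 = log_m_table("spec1", n01 + n00, n11 + n10)
    m_d2 = log_m_table("sens2", n11 + n01, n10 + n00)
    m_g2 = log_m_table("spec2", n10 + n00, n11 + n01)

    from scipy.special import gammaln

    def log_binom(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    # z_by_total[Y]: log of the summed factorized weight of all latent
    # splits with Y true positives in total
    z_by_total = np.full(n_tot + 1, -np.inf)
    y11 = np.arange(n11 + 1)
    for y10 in range(n10 + 1):
        for y01 in range(n01 + 1):
            for y00 in range(n00 + 1):
                lcoef = (
                    log_binom(n11, y11)
                    + log_binom(n10, y10)
                    + log_binom(n01, y01)
                    + log_binom(n00, y00)
                )
                term = (
                    lcoef
                    + m_d1[y11 + y10, y01 + y00]
                    + m_g1[(n01 - y01) + (n00 - y00), (n11 - y11) + (n10 - y10)]
                    + m_d2[y11 + y01, y10 + y00]
                    + m_g2[(n10 - y10) + (n00 - y00), (n11 - y11) + (n01 - y01)]
                )
                totals = y11 + y10 + y01 + y00
                for t, v in zip(totals, term):
                    z_by_total[t] = np.logaddexp(z_by_total[t], v)

    # marginal posterior of π on its own lattice
    y_tot = np.arange(n_tot + 1)
    logmarg = logsumexp(
        z_by_total[:, None] + y_tot[:, None] * logq[None, :] + (n_tot - y_tot)[:, None] * log1mq[None, :],
        axis=0,
    ) + logw["pi"]
    w = np.exp(logmarg - logmarg.max())
    w /= w.sum()
    mean = float(np.sum(w * q))
    sd = float(np.sqrt(np.sum(w * (q - mean) ** 2)))
    cdf = np.cumsum(w) - 0.5 * w  # CDF evaluated at the bin midpoints
    lo = float(np.interp(0.025, cdf, q))
    hi = float(np.interp(0.975, cdf, q))
    return {"mean": mean, "sd": sd, "ci_low": lo, "ci_high": hi, "grid": q, "weights": w}


def posterior_predictive_check(
    posterior: PrevalencePosterior,
    counts: TwoTestCounts,
    n_rep: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate counts from the posterior and locate the observed cells.

    For ``n_rep`` posterior draws (evenly thinned across chains), simulates
    a multinomial replicate at the observed total n; returns per-cell
    replicate quantiles and the posterior-predictive tail probability
    P(replicate ≤ observed) of each observed cell.  Tail probabilities near
    0 or 1 flag misfit (e.g. conditional dependence the model ignores).
    """
    flat = np.column_stack([posterior.flat(name) for name in PARAM_NAMES])
    if len(flat) < n_rep:
        raise ConfigurationError(f"posterior holds {len(flat)} draws < n_rep={n_rep}")
    idx = np.linspace(0, len(flat) - 1, n_rep).astype(int)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_rep, 4), dtype=np.int64)
    for r, (pi, s1, c1, s2, c2) in enumerate(flat[idx]):
        probs = np.array(cell_probabilities(pi, s1, c1, s2, c2))
        reps[r] = rng.multinomial(counts.n, probs / probs.sum())
    obs = counts.as_array()
    qs = np.percentile(reps, [2.5, 25, 50, 75, 97.5], axis=0)
    return pd.DataFrame(
        {
            "cell": ["n11", "n10", "n01", "n00"],
            "observed": obs,
            "rep_q2.5": qs[0],
            "rep_q25": qs[1],
            "rep_median": qs[2],
            "rep_q75": qs[3],
            "rep_q97.5": qs[4],
            "tail_prob": (reps <= obs).mean(axis=0),
        }
    )
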