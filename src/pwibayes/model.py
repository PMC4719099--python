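"""Robust hierarchical Bayesian estimation for the split-plot naming design.

The observations are participant-condition median latencies. Each group x
distractor cell has its own location, decomposed ANOVA-style as

    location[g, c] = baseline + group_def[g] + cond_def[c] + inter_def[g, c]

with every deflection family constrained to sum to zero (rows and columns of
the interaction grid included). The data are modeled with a Student-t
likelihood whose scale ``sigma`` and normality ``nu`` are shared across all
cells: small ``nu`` means heavy tails, so extreme participants are
accommodated rather than allowed to drag cell locations around.

Priors are deliberately vague, scaled from the data:

* baseline ~ Normal(pooled mean, precision = 1e-6 x pooled precision)
* sigma ~ Uniform(pooled SD / 1000, pooled SD x 1000)
* nu ~ Exponential(mean 29), balancing near-normal and heavy-tailed fits
* deflections ~ Normal(0, 1/tau); tau ~ Gamma(shape, rate) moment-matched to
  the mean and (inflated) SD of the observed per-cell precisions

Sampling uses a Gibbs scheme built on the scale-mixture-of-normals
representation of the t distribution (one latent weight per observation),
with a Metropolis step for ``nu``; deflections are sampled unconstrained and
swept into the sum-to-zero parameterization at each saved draw. An
independent ensemble-sampler backend (emcee) over the joint posterior is
provided for cross-validation of the Gibbs results.

Decisions about effects use the 95% highest-density interval of the relevant
posterior contrast: an effect is credibly positive/negative when its HDI
excludes zero, and a zero difference is a credible value when the HDI
contains it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design import DEFAULT_CONDITIONS
from .hdi import hdi as _hdi
from .preprocess import EFFECT_DEFS, medians_long

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorSamples",
    "ContrastResult",
    "RobustSplitPlotAnova",
    "gamma_from_mean_sd",
    "build_priors",
    "fit_model",
    "cell_means",
    "contrast",
    "named_contrasts",
    "contrast_table",
]

RHAT_THRESHOLD = 1.05


# ---------------------------------------------------------------------------
# Priors


def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a gamma distribution: shape = mean^2/sd^2, rate = mean/sd^2.

    The resulting Gamma(shape, rate) has exactly the requested mean and SD
    (mean = shape/rate, sd = sqrt(shape)/rate).
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    return mean * mean / (sd * sd), mean / (sd * sd)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the vague priors, on the millisecond scale."""

    baseline_mean: float
    baseline_precision: float
    sd_lower: float
    sd_upper: float
    nu_prior_mean: float = 29.0
    deflection_precision_shape: float = 2.3e-12
    deflection_precision_rate: float = 4.6e-8
    #: one shared deflection precision (default) or one per family
    #: (group / distractor / interaction), each under the same gamma prior
    per_family_precision: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.sd_lower < self.sd_upper):
            raise ValueError("need 0 < sd_lower < sd_upper")
        if self.baseline_precision <= 0:
            raise ValueError("baseline_precision must be positive")
        if self.nu_prior_mean <= 0:
            raise ValueError("nu_prior_mean must be positive")
        if self.deflection_precision_shape <= 0 or self.deflection_precision_rate <= 0:
            raise ValueError("gamma hyperparameters must be positive")


def build_priors(medians: pd.DataFrame, sd_inflation: float = 1.0e6) -> PriorSpec:
    """Derive the vague priors from the median table itself.

    * baseline: normal at the pooled mean with 1e-6 times the pooled precision;
    * sigma: uniform between pooled SD / 1000 and pooled SD x 1000;
    * nu: exponential with mean 29;
    * deflection precision: gamma moment-matched to the mean of the observed
      per-cell precisions and ``sd_inflation`` times their SD (the inflation
      is what makes this prior noncommittal).

    Accepts the wide median table of :func:`~pwibayes.preprocess.condition_medians`
    or a long table with a ``median_rt`` column.
    """
    long = _as_long(medians)
    y = long["median_rt"].to_numpy(dtype=float)
    if long["participant_id"].nunique() < 2 or long["condition"].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 conditions")
    pooled_var = float(np.var(y, ddof=1))
    if pooled_var <= 0:
        raise ValueError("pooled variance is zero: degenerate data")
    pooled_sd = math.sqrt(pooled_var)

    cell_precisions = []
    for _, cell in long.groupby(["group", "condition"], sort=True):
        v = cell["median_rt"].to_numpy(dtype=float)
        if len(v) >= 2:
            var = float(np.var(v, ddof=1))
            if var <= 0:
                raise ValueError("a group x condition cell has zero variance")
            cell_precisions.append(1.0 / var)
    if len(cell_precisions) < 2:
        raise ValueError("need >= 2 cells with >= 2 observations for the deflection prior")
    prec = np.asarray(cell_precisions)
    shape, rate = gamma_from_mean_sd(float(prec.mean()), sd_inflation * float(prec.std(ddof=1)))
    return PriorSpec(
        baseline_mean=float(y.mean()),
        baseline_precision=1.0e-6 / pooled_var,
        sd_lower=pooled_sd / 1000.0,
        sd_upper=pooled_sd * 1000.0,
        deflection_precision_shape=shape,
        deflection_precision_rate=rate,
    )


# ---------------------------------------------------------------------------
# Sampler configuration and results


@dataclass(frozen=True)
class McmcConfig:
    """MCMC settings. ``n_samples`` is the total retained draw count across
    chains, after burn-in and thinning (the published defaults: 100,000
    retained, keep every 50th step, 2,000 burn-in steps)."""

    n_samples: int = 100_000
    thin: int = 50
    burn_in: int = 2_000
    n_chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.thin, self.n_chains) < 1 or self.burn_in < 0:
            raise ValueError("all MCMC counts must be positive (burn_in >= 0)")
        if self.n_samples % self.n_chains:
            raise ValueError("n_samples must be divisible by n_chains")

    @property
    def per_chain(self) -> int:
        return self.n_samples // self.n_chains


@dataclass
class PosteriorSamples:
    """Retained posterior draws in the sum-to-zero parameterization.

    Array shapes: S retained draws total, G groups, C conditions.
    Every draw satisfies sum(group_deflection) = 0, sum(distractor_deflection)
    = 0, and row/column sums of the interaction grid = 0, exactly (the sweep
    is algebraic, not approximate).
    """

    groups: tuple[str, ...]
    conditions: tuple[str, ...]
    baseline: np.ndarray  # (S,)
    group_deflection: np.ndarray  # (S, G)
    distractor_deflection: np.ndarray  # (S, C)
    interaction_deflection: np.ndarray  # (S, G, C)
    sigma: np.ndarray  # (S,)
    nu: np.ndarray  # (S,)
    chain: np.ndarray  # (S,) chain index per draw
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    backend: str = "gibbs"

    @property
    def n_draws(self) -> int:
        return int(self.baseline.shape[0])

    def cell_means(self) -> np.ndarray:
        """Draws of the G x C cell locations, shape (S, G, C)."""
        return (
            self.baseline[:, None, None]
            + self.group_deflection[:, :, None]
            + self.distractor_deflection[:, None, :]
            + self.interaction_deflection
        )

    def contrast(self, spec, name: str = "contrast", mass: float = 0.95) -> "ContrastResult":
        return contrast(self, spec, name=name, mass=mass)

    def named_contrasts(self, mass: float = 0.95) -> dict[str, "ContrastResult"]:
        return named_contrasts(self, mass=mass)

    def to_dataframe(self) -> pd.DataFrame:
        """Flat draws table (one column per parameter) for persistence."""
        cols = {"chain": self.chain, "baseline": self.baseline, "sigma": self.sigma, "nu": self.nu}
        for j, g in enumerate(self.groups):
            cols[f"group[{g}]"] = self.group_deflection[:, j]
        for k, c in enumerate(self.conditions):
            cols[f"distractor[{c}]"] = self.distractor_deflection[:, k]
        for j, g in enumerate(self.groups):
            for k, c in enumerate(self.conditions):
                cols[f"interaction[{g},{c}]"] = self.interaction_deflection[:, j, k]
        return pd.DataFrame(cols)


@dataclass
class ContrastResult:
    """Posterior of one linear combination of cell means, with the HDI decision."""

    name: str
    draws: np.ndarray
    mean: float
    hdi_low: float
    hdi_high: float
    mass: float
    pct_above_zero: float
    pct_below_zero: float
    pct_at_zero: float
    decision: str  # credible_positive | credible_negative | credibly_null_candidate
    degenerate: bool = False

    @property
    def hdi_width(self) -> float:
        return self.hdi_high - self.hdi_low

    def includes_zero(self) -> bool:
        return self.hdi_low <= 0.0 <= self.hdi_high


# ---------------------------------------------------------------------------
# Input handling


def _as_long(medians: pd.DataFrame) -> pd.DataFrame:
    if "median_rt" in medians.columns:
        long = medians.dropna(subset=["median_rt"]).copy()
    else:
        long = medians_long(medians)
    needed = {"participant_id", "group", "condition", "median_rt"}
    if not needed.issubset(long.columns):
        raise ValueError(f"median table needs columns {sorted(needed)}")
    return long


def _ordered_levels(values, preferred: tuple[str, ...]) -> tuple[str, ...]:
    present = list(dict.fromkeys(values))
    ordered = [v for v in preferred if v in present]
    ordered += sorted(v for v in present if v not in preferred)
    return tuple(ordered)


def _prepare(medians: pd.DataFrame):
    long = _as_long(medians)
    groups = _ordered_levels(long["group"], ("control", "patient"))
    conditions = _ordered_levels(long["condition"], DEFAULT_CONDITIONS)
    if len(groups) < 2 or len(conditions) < 2:
        raise ValueError("need >= 2 groups and >= 2 conditions")
    y = long["median_rt"].to_numpy(dtype=float)
    if y.size < 4:
        raise ValueError("need >= 4 observations")
    gi = np.array([groups.index(g) for g in long["group"]], dtype=np.intp)
    ci = np.array([conditions.index(c) for c in long["condition"]], dtype=np.intp)
    return y, gi, ci, groups, conditions


def _sweep(b0, bg, bc, bgc):
    """Recenter unconstrained parameters into the sum-to-zero parameterization."""
    m = b0 + bg[:, None] + bc[None, :] + bgc
    base = m.mean()
    g = m.mean(axis=1) - base
    c = m.mean(axis=0) - base
    inter = m - base - g[:, None] - c[None, :]
    return base, g, c, inter


# ---------------------------------------------------------------------------
# Gibbs backend


def _log_nu_conditional(nu: float, lam: np.ndarray, slog: float, ssum: float, nu_mean: float) -> float:
    n = lam.size
    h = nu / 2.0
    return n * (h * math.log(h) - gammaln(h)) + (h - 1.0) * slog - h * ssum - nu / nu_mean


def _run_gibbs_chain(y, gi, ci, priors: PriorSpec, n_iter: int, burn_in: int, thin: int,
                     n_keep: int, rng: np.random.Generator, jitter_scale: float):
    n = y.size
    n_g = int(gi.max()) + 1
    n_c = int(ci.max()) + 1
    cell = gi * n_c + ci
    m_defl = n_g + n_c + n_g * n_c

    # data-based initial values (pooled and factor summaries), jittered per chain
    b0 = float(y.mean()) + rng.normal(0.0, jitter_scale)
    bg = np.bincount(gi, y, minlength=n_g) / np.bincount(gi, minlength=n_g) - y.mean()
    bc = np.bincount(ci, y, minlength=n_c) / np.bincount(ci, minlength=n_c) - y.mean()
    cell_counts = np.bincount(cell, minlength=n_g * n_c).astype(float)
    cell_counts[cell_counts == 0] = 1.0
    cell_mean = np.bincount(cell, y, minlength=n_g * n_c) / cell_counts
    bgc = cell_mean.reshape(n_g, n_c) - y.mean() - bg[:, None] - bc[None, :]
    bg = bg + rng.normal(0.0, jitter_scale, n_g)
    bc = bc + rng.normal(0.0, jitter_scale, n_c)
    bgc = bgc + rng.normal(0.0, jitter_scale, (n_g, n_c))
    sigma2 = float(np.var(y, ddof=1))
    sigma2 = min(max(sigma2, priors.sd_lower**2 * 1.01), priors.sd_upper**2 * 0.99)
    nu = 10.0
    defl_sq = float(np.sum(bg**2) + np.sum(bc**2) + np.sum(bgc**2))
    # deflection precisions per family (group, distractor, interaction);
    # kept identical at every step when the prior is shared
    tau = np.full(3, m_defl / max(defl_sq, 1e-6))
    lam = np.ones(n)

    p0 = priors.baseline_precision
    m0 = priors.baseline_mean
    lo2, hi2 = 1.0 / priors.sd_upper**2, 1.0 / priors.sd_lower**2
    a_tau, b_tau = priors.deflection_precision_shape, priors.deflection_precision_rate
    sig_shape = (n - 1) / 2.0

    nu_step = 0.5
    nu_acc = 0

    out_b0 = np.empty(n_keep)
    out_bg = np.empty((n_keep, n_g))
    out_bc = np.empty((n_keep, n_c))
    out_bgc = np.empty((n_keep, n_g, n_c))
    out_sigma = np.empty(n_keep)
    out_nu = np.empty(n_keep)
    kept = 0

    for it in range(n_iter):
        bgc_flat = bgc.ravel()
        # latent t weights
        mu = b0 + bg[gi] + bc[ci] + bgc_flat[cell]
        r2 = (y - mu) ** 2
        lam = rng.gamma((nu + 1.0) / 2.0, 2.0 / (nu + r2 / sigma2))
        w = lam / sigma2

        # baseline
        e = y - (bg[gi] + bc[ci] + bgc_flat[cell])
        prec = p0 + w.sum()
        b0 = rng.normal((p0 * m0 + np.dot(w, e)) / prec, 1.0 / math.sqrt(prec))

        # group deflections
        e = y - b0 - bc[ci] - bgc_flat[cell]
        sw = np.bincount(gi, w, minlength=n_g)
        swe = np.bincount(gi, w * e, minlength=n_g)
        prec = tau[0] + sw
        bg = rng.normal(swe / prec, 1.0 / np.sqrt(prec))

        # distractor deflections
        e = y - b0 - bg[gi] - bgc_flat[cell]
        sw = np.bincount(ci, w, minlength=n_c)
        swe = np.bincount(ci, w * e, minlength=n_c)
        prec = tau[1] + sw
        bc = rng.normal(swe / prec, 1.0 / np.sqrt(prec))

        # interaction deflections
        e = y - b0 - bg[gi] - bc[ci]
        sw = np.bincount(cell, w, minlength=n_g * n_c)
        swe = np.bincount(cell, w * e, minlength=n_g * n_c)
        prec = tau[2] + sw
        bgc = rng.normal(swe / prec, 1.0 / np.sqrt(prec)).reshape(n_g, n_c)

        # deflection precision(s)
        if priors.per_family_precision:
            tau[0] = rng.gamma(a_tau + n_g / 2.0, 1.0 / (b_tau + np.sum(bg**2) / 2.0))
            tau[1] = rng.gamma(a_tau + n_c / 2.0, 1.0 / (b_tau + np.sum(bc**2) / 2.0))
            tau[2] = rng.gamma(a_tau + n_g * n_c / 2.0, 1.0 / (b_tau + np.sum(bgc**2) / 2.0))
        else:
            defl_sq = float(np.sum(bg**2) + np.sum(bc**2) + np.sum(bgc**2))
            tau[:] = rng.gamma(a_tau + m_defl / 2.0, 1.0 / (b_tau + defl_sq / 2.0))

        # scale, as truncated precision
        mu = b0 + bg[gi] + bc[ci] + bgc.ravel()[cell]
        s = float(np.dot(lam, (y - mu) ** 2))
        for _ in range(10):
            x = rng.gamma(sig_shape, 2.0 / s)
            if lo2 <= x <= hi2:
                break
        else:
            x = min(max(x, lo2), hi2)
        sigma2 = 1.0 / x

        # normality parameter, Metropolis on log nu
        slog = float(np.log(lam).sum())
        ssum = float(lam.sum())
        prop = nu * math.exp(rng.normal(0.0, nu_step))
        log_ratio = (
            _log_nu_conditional(prop, lam, slog, ssum, priors.nu_prior_mean)
            - _log_nu_conditional(nu, lam, slog, ssum, priors.nu_prior_mean)
            + math.log(prop) - math.log(nu)
        )
        if math.log(rng.random()) < log_ratio:
            nu = prop
            nu_acc += 1
        if it < burn_in and (it + 1) % 50 == 0:
            rate = nu_acc / 50.0
            nu_step = float(np.clip(nu_step * math.exp(0.7 * (rate - 0.44)), 0.01, 5.0))
            nu_acc = 0

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            base, g_c, c_c, gc_c = _sweep(b0, bg, bc, bgc)
            out_b0[kept] = base
            out_bg[kept] = g_c
            out_bc[kept] = c_c
            out_bgc[kept] = gc_c
            out_sigma[kept] = math.sqrt(sigma2)
            out_nu[kept] = nu
            kept += 1

    return out_b0, out_bg, out_bc, out_bgc, out_sigma, out_nu


# ---------------------------------------------------------------------------
# emcee backend (independent cross-check)


def _log_posterior_factory(y, gi, ci, n_g, n_c, priors: PriorSpec):
    cell = gi * n_c + ci
    m_defl = n_g + n_c + n_g * n_c
    log_lo, log_hi = math.log(priors.sd_lower), math.log(priors.sd_upper)

    def log_post(theta: np.ndarray) -> float:
        b0 = theta[0]
        bg = theta[1 : 1 + n_g]
        bc = theta[1 + n_g : 1 + n_g + n_c]
        bgc = theta[1 + n_g + n_c : 1 + n_g + n_c + n_g * n_c]
        log_sigma, log_nu, log_tau = theta[-3:]
        if not (log_lo <= log_sigma <= log_hi) or log_nu > 12 or abs(log_tau) > 80:
            return -np.inf
        sigma = math.exp(log_sigma)
        nu = math.exp(log_nu)
        tau = math.exp(log_tau)
        mu = b0 + bg[gi] + bc[ci] + bgc[cell]
        r2 = (y - mu) ** 2
        ll = y.size * (
            gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * math.log(nu * math.pi) - log_sigma
        ) - (nu + 1) / 2 * float(np.log1p(r2 / (nu * sigma * sigma)).sum())
        defl_sq = float(np.dot(bg, bg) + np.dot(bc, bc) + np.dot(bgc, bgc))
        lp = (
            -0.5 * priors.baseline_precision * (b0 - priors.baseline_mean) ** 2
            + 0.5 * m_defl * math.log(tau) - 0.5 * tau * defl_sq
            + priors.deflection_precision_shape * log_tau - priors.deflection_precision_rate * tau
            - nu / priors.nu_prior_mean + log_nu
        )
        # log-sigma Jacobian of the uniform-on-sigma prior
        lp += log_sigma
        return ll + lp

    return log_post


def _run_emcee(y, gi, ci, n_g, n_c, priors: PriorSpec, mcmc: McmcConfig):
    import emcee

    if priors.per_family_precision:
        raise ValueError("the emcee backend implements only the shared deflection precision")
    ndim = 1 + n_g + n_c + n_g * n_c + 3
    nwalkers = max(2 * ndim + 2, 44)
    rng = np.random.default_rng(mcmc.seed)

    center = np.zeros(ndim)
    center[0] = y.mean()
    cell = gi * n_c + ci
    counts = np.bincount(cell, minlength=n_g * n_c).astype(float)
    counts[counts == 0] = 1.0
    cm = (np.bincount(cell, y, minlength=n_g * n_c) / counts).reshape(n_g, n_c)
    base, g0, c0, gc0 = _sweep(0.0, np.zeros(n_g), np.zeros(n_c), cm)
    center[0] = base
    center[1 : 1 + n_g] = g0
    center[1 + n_g : 1 + n_g + n_c] = c0
    center[1 + n_g + n_c : 1 + n_g + n_c + n_g * n_c] = gc0.ravel()
    sd = max(float(np.std(y, ddof=1)), 1e-3)
    center[-3] = math.log(sd)
    center[-2] = math.log(10.0)
    center[-1] = math.log(1.0 / max(float(np.dot(center[1:-3], center[1:-3])), 1.0))
    p0 = center + rng.normal(0.0, 0.05 * max(sd, 1.0), size=(nwalkers, ndim))
    p0[:, -3:] = center[-3:] + rng.normal(0.0, 0.05, size=(nwalkers, 3))

    log_post = _log_posterior_factory(y, gi, ci, n_g, n_c, priors)
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post)
    sampler._random = np.random.RandomState(mcmc.seed)

    # the stretch-move ensemble has integrated autocorrelation times of a few
    # hundred steps on this posterior, so burn-in and thinning are set in
    # ensemble steps, independently of the single-site Gibbs settings
    thin = 10
    burn = max(mcmc.burn_in, 3_000)
    steps_keep = (mcmc.n_samples + nwalkers - 1) // nwalkers
    sampler.run_mcmc(p0, burn + steps_keep * thin, progress=False)
    chain = sampler.get_chain(discard=burn, thin=thin)  # (steps, walkers, ndim)
    flat = chain.reshape(-1, ndim)[: mcmc.n_samples]
    s = flat.shape[0]

    out_b0 = np.empty(s)
    out_bg = np.empty((s, n_g))
    out_bc = np.empty((s, n_c))
    out_bgc = np.empty((s, n_g, n_c))
    for i in range(s):
        base, g_c, c_c, gc_c = _sweep(
            flat[i, 0],
            flat[i, 1 : 1 + n_g],
            flat[i, 1 + n_g : 1 + n_g + n_c],
            flat[i, 1 + n_g + n_c : 1 + n_g + n_c + n_g * n_c].reshape(n_g, n_c),
        )
        out_b0[i] = base
        out_bg[i] = g_c
        out_bc[i] = c_c
        out_bgc[i] = gc_c
    return out_b0, out_bg, out_bc, out_bgc, np.exp(flat[:, -3]), np.exp(flat[:, -2])


# ---------------------------------------------------------------------------
# Fitting


def fit_model(
    medians: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    backend: str = "gibbs",
) -> PosteriorSamples:
    """Fit the robust hierarchical split-plot model to a median table.

    ``medians`` is the wide table from
    :func:`~pwibayes.preprocess.condition_medians` (or long form with a
    ``median_rt`` column). Missing cells are simply absent observations.
    Priors default to :func:`build_priors` on the same data. Convergence
    (split-R-hat across chains) is checked when more than one chain is run;
    a non-converged fit is returned with ``converged=False`` and a warning.
    """
    mcmc = mcmc or McmcConfig()
    y, gi, ci, groups, conditions = _prepare(medians)
    if priors is None:
        priors = build_priors(medians)
    n_g, n_c = len(groups), len(conditions)

    if backend == "emcee":
        b0, bg, bc, bgc, sigma, nu = _run_emcee(y, gi, ci, n_g, n_c, priors, mcmc)
        chain_ids = np.zeros(b0.shape[0], dtype=int)
        parts = None
    elif backend == "gibbs":
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
        jitter = 0.05 * max(float(np.std(y, ddof=1)), 1.0)
        parts = []
        n_iter = mcmc.burn_in + mcmc.per_chain * mcmc.thin
        for k in range(mcmc.n_chains):
            rng = np.random.default_rng(seeds[k])
            parts.append(
                _run_gibbs_chain(
                    y, gi, ci, priors, n_iter, mcmc.burn_in, mcmc.thin,
                    mcmc.per_chain, rng, jitter_scale=jitter if k else 0.0,
                )
            )
        b0 = np.concatenate([p[0] for p in parts])
        bg = np.concatenate([p[1] for p in parts])
        bc = np.concatenate([p[2] for p in parts])
        bgc = np.concatenate([p[3] for p in parts])
        sigma = np.concatenate([p[4] for p in parts])
        nu = np.concatenate([p[5] for p in parts])
        chain_ids = np.repeat(np.arange(mcmc.n_chains), mcmc.per_chain)
    else:
        raise ValueError(f"unknown backend: {backend!r}")

    samples = PosteriorSamples(
        groups=groups,
        conditions=conditions,
        baseline=b0,
        group_deflection=bg,
        distractor_deflection=bc,
        interaction_deflection=bgc,
        sigma=sigma,
        nu=nu,
        chain=chain_ids,
        backend=backend,
    )

    if backend == "gibbs" and mcmc.n_chains >= 2:
        samples.rhat, samples.ess = _diagnostics(samples, mcmc)
        max_rhat = max(samples.rhat.values())
        samples.converged = bool(max_rhat < RHAT_THRESHOLD)
        if not samples.converged:
            warnings.warn(
                f"MCMC may not have converged: max split-R-hat = {max_rhat:.3f}",
                RuntimeWarning,
                stacklevel=2,
            )
    return samples


def _diagnostics(samples: PosteriorSamples, mcmc: McmcConfig) -> tuple[dict, dict]:
    import arviz as az

    per = mcmc.per_chain
    k = mcmc.n_chains

    def stack(a):  # (S, ...) -> (chain, draw, ...)
        return a.reshape(k, per, *a.shape[1:])

    cm = samples.cell_means()
    post = {
        "baseline": stack(samples.baseline),
        "sigma": stack(samples.sigma),
        "log_nu": stack(np.log(samples.nu)),
        "cell_mean": stack(cm.reshape(cm.shape[0], -1)),
    }
    idata = az.from_dict(posterior=post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat, ess = {}, {}
    for name in post:
        r = np.asarray(rhat_ds[name]).ravel()
        e = np.asarray(ess_ds[name]).ravel()
        rhat[name] = float(np.nanmax(r))
        ess[name] = float(np.nanmin(e))
    return rhat, ess


# ---------------------------------------------------------------------------
# Contrasts


def cell_means(samples: PosteriorSamples) -> np.ndarray:
    """Draws of the group x condition cell locations, shape (S, G, C)."""
    return samples.cell_means()


def _coef_matrix(samples: PosteriorSamples, spec) -> np.ndarray:
    n_g, n_c = len(samples.groups), len(samples.conditions)
    coefs = np.zeros((n_g, n_c))
    if isinstance(spec, dict):
        for (g, c), v in spec.items():
            coefs[samples.groups.index(g), samples.conditions.index(c)] = v
    else:
        coefs = np.asarray(spec, dtype=float).reshape(n_g, n_c)
    if not np.any(coefs):
        raise ValueError("contrast coefficients are all zero")
    return coefs


def contrast(
    samples: PosteriorSamples, spec, name: str = "contrast", mass: float = 0.95
) -> ContrastResult:
    """Posterior of a linear combination of cell means.

    ``spec`` is either a {(group, condition): coefficient} dict (unlisted
    cells get 0) or a full G x C coefficient array. The decision is
    ``credible_positive`` when the HDI lies above zero, ``credible_negative``
    when below, else ``credibly_null_candidate`` (the HDI contains zero, so
    zero is a credible value).
    """
    coefs = _coef_matrix(samples, spec)
    draws = np.tensordot(samples.cell_means(), coefs, axes=([1, 2], [0, 1]))
    mean = float(draws.mean())
    degenerate = bool(np.ptp(draws) < 1e-9)
    if degenerate:
        lo = hi = float(draws[0])
    else:
        lo, hi = _hdi(draws, mass)
    above = 100.0 * float(np.mean(draws > 0))
    below = 100.0 * float(np.mean(draws < 0))
    at = 100.0 - above - below
    if lo > 0:
        decision = "credible_positive"
    elif hi < 0:
        decision = "credible_negative"
    else:
        decision = "credibly_null_candidate"
    return ContrastResult(
        name=name, draws=draws, mean=mean, hdi_low=lo, hdi_high=hi, mass=mass,
        pct_above_zero=above, pct_below_zero=below, pct_at_zero=at,
        decision=decision, degenerate=degenerate,
    )


def _named_specs(samples: PosteriorSamples) -> dict[str, dict]:
    """The report's standard contrasts over the 2 x 4 design.

    Group effect: patient - control averaged over conditions (positive =
    patients slower). Per-group effects follow the interference-positive /
    facilitation-negative convention. Group differences are signed
    control - patient, so values below zero mean a larger patient effect
    (decreased performance for the interference effects).
    """
    g1, g2 = "control", "patient"
    if set((g1, g2)) - set(samples.groups):
        raise ValueError("named contrasts require control and patient groups")
    n_c = len(samples.conditions)
    specs: dict[str, dict] = {
        "group": {
            **{(g2, c): 1.0 / n_c for c in samples.conditions},
            **{(g1, c): -1.0 / n_c for c in samples.conditions},
        }
    }
    for eff, (a, b) in EFFECT_DEFS.items():
        if a not in samples.conditions or b not in samples.conditions:
            continue
        specs[f"control_{eff}"] = {(g1, a): 1.0, (g1, b): -1.0}
        specs[f"patient_{eff}"] = {(g2, a): 1.0, (g2, b): -1.0}
        specs[f"groupdiff_{eff}"] = {(g1, a): 1.0, (g1, b): -1.0, (g2, a): -1.0, (g2, b): 1.0}
    return specs


def named_contrasts(samples: PosteriorSamples, mass: float = 0.95) -> dict[str, ContrastResult]:
    """All standard contrasts: overall group effect, the three distractor
    effects per group, and each effect's group difference."""
    return {
        name: contrast(samples, spec, name=name, mass=mass)
        for name, spec in _named_specs(samples).items()
    }


def contrast_table(results: dict[str, ContrastResult]) -> pd.DataFrame:
    """Summary table: mean, HDI, tail percentages, decision per contrast."""
    rows = [
        {
            "contrast": r.name,
            "mean": r.mean,
            "hdi_low": r.hdi_low,
            "hdi_high": r.hdi_high,
            "mass": r.mass,
            "pct_above_zero": r.pct_above_zero,
            "pct_below_zero": r.pct_below_zero,
            "decision": r.decision,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model class (thin convenience over fit_model)


class RobustSplitPlotAnova:
    """Model object bundling priors, MCMC settings and fit results.

    >>> model = RobustSplitPlotAnova(mcmc=McmcConfig(n_samples=8000, thin=2,
    ...                                              burn_in=500, n_chains=2, seed=3))
    >>> res = model.fit(medians)            # doctest: +SKIP
    >>> res.named_contrasts()["group"].decision   # doctest: +SKIP
    'credible_positive'
    """

    def __init__(
        self,
        priors: PriorSpec | None = None,
        mcmc: McmcConfig | None = None,
        backend: str = "gibbs",
    ):
        self.priors = priors
        self.mcmc = mcmc or McmcConfig()
        self.backend = backend

    def fit(self, medians: pd.DataFrame) -> PosteriorSamples:
        self.priors_ = self.priors if self.priors is not None else build_priors(medians)
        self.posterior_ = fit_model(medians, self.priors_, self.mcmc, self.backend)
        return self.posterior_
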