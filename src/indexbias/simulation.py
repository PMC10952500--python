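"""Collider-bias simulation for case-ascertained survival analysis.

The generative model, per simulated individual *i*:

1. genotype ``G_i`` in {0, 1, 2}, additively coded, in Hardy-Weinberg
   equilibrium at minor allele frequency ``maf``;
2. an unmeasured confounder ``U_i ~ N(0, 1)`` standing in for all non-genetic
   risk factors;
3. disease with probability ``p_i`` from the logistic model
   ``logit(p_i) = beta0 + beta_gx * G_i + beta_ux * U_i``, with ``beta0``
   solved numerically so the population mean risk equals
   ``target_prevalence``;
4. for disease cases only, an (uncensored) survival time from a Weibull
   proportional-hazards model via inverse-probability sampling,
   ``t_i = ((-log v_i) / (lambda * exp(U_i)))**(1/rho)``, ``v_i ~ Unif(0,1)``.

The genotype has *no* effect on survival, so the Cox log hazard ratio of
``G`` estimated among cases is pure index event (collider) bias: conditioning
on disease induces a negative G-U correlation, and U drives the hazard.
Averaging that spurious log HR over replicates and subtracting it from an
observed log HR back-calculates the true hazard ratio the observation would
imply.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect
from scipy.special import expit
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger(__name__)

GH_NODES_DEFAULT = 201
MIN_CASES_FOR_COX = 10


@dataclass
class SimConfig:
    """Full parameterisation of one simulation cell.

    Defaults are the study conditions of the motivating IPF analysis: a
    MUC5B-like SNP (MAF 0.11, odds ratio 5), population prevalence 0.05%,
    2 million individuals per replicate (~1000 cases on average), Weibull
    baseline hazard lambda = exp(-12.5), rho = 1.7, and an observed hazard
    ratio of 0.766 to back-calculate from.
    """

    n_individuals: int = 2_000_000
    maf: float = 0.11
    beta_gx: float = math.log(5.0)
    beta_ux: float = 0.0
    target_prevalence: float = 0.0005
    weibull_lambda: float = math.exp(-12.5)
    weibull_rho: float = 1.7
    n_reps: int = 1000
    observed_log_hr: float = math.log(0.766)
    seed: int = 0
    censor_time: float | None = None  # administrative censoring; off by default
    gh_nodes: int = GH_NODES_DEFAULT

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0.0 < self.target_prevalence < 0.5:
            raise ValueError("target_prevalence must be in (0, 0.5)")
        if self.beta_ux < 0:
            raise ValueError("beta_ux must be >= 0")
        if self.weibull_lambda <= 0 or self.weibull_rho <= 0:
            raise ValueError("Weibull parameters must be strictly positive")
        if self.n_individuals < 1 or self.n_reps < 1:
            raise ValueError("n_individuals and n_reps must be >= 1")


@dataclass(frozen=True)
class RepResult:
    """One replicate: case count and the spurious Cox log HR of G."""

    n_cases: int
    bias_hat: float
    se_bias: float


@dataclass(frozen=True)
class GridResult:
    """Summary of one grid cell (one confounder effect size)."""

    beta_ux: float
    beta0: float
    mean_bias: float
    mc_se_bias: float
    true_log_hr: float
    true_hr: float
    mean_n_cases: float
    n_reps_used: int
    n_reps_failed: int
    reliable: bool


def genotype_probs(maf: float) -> np.ndarray:
    """HWE genotype probabilities ((1-f)^2, 2f(1-f), f^2)."""
    f = maf
    return np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Additively coded genotypes under HWE (binomial allele count)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.binomial(2, maf, size=n)


def mean_risk(
    beta0: float,
    beta_gx: float,
    beta_ux: float,
    maf: float,
    gh_nodes: int = GH_NODES_DEFAULT,
) -> float:
    """Population mean disease risk E[p] by Gauss-Hermite quadrature over U.

    E[p] = sum_g P(g) * int expit(beta0 + beta_gx*g + beta_ux*u) phi(u) du,
    with the integral on >= 201 Gauss-Hermite nodes (change of variables
    u = sqrt(2) x), which resolves the near-step integrand even at
    beta_ux = 20.
    """
    x, w = np.polynomial.hermite.hermgauss(gh_nodes)
    u = math.sqrt(2.0) * x
    w = w / math.sqrt(math.pi)
    pg = genotype_probs(maf)
    total = 0.0
    for g, p_g in enumerate(pg):
        total += p_g * float(np.sum(w * expit(beta0 + beta_gx * g + beta_ux * u)))
    return total


def mean_risk_mc(
    beta0: float,
    beta_gx: float,
    beta_ux: float,
    maf: float,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte Carlo oracle for the population mean risk: (estimate, MC se)."""
    block = 2_000_000
    total = 0.0
    total_sq = 0.0
    done = 0
    while done < n_draws:
        m = min(block, n_draws - done)
        g = rng.binomial(2, maf, size=m)
        u = rng.standard_normal(m)
        p = expit(beta0 + beta_gx * g + beta_ux * u)
        total += float(p.sum())
        total_sq += float((p * p).sum())
        done += m
    mean = total / n_draws
    var = total_sq / n_draws - mean**2
    return mean, math.sqrt(max(var, 0.0) / n_draws)


def solve_beta0(config: SimConfig) -> float:
    """Solve the logistic intercept so the mean risk hits the target prevalence.

    Bisection on the monotone map beta0 -> E[p] over the bracket [-2000, 0]
    (beta0 > 0 would imply prevalence above 1/2).  The returned root satisfies
    |E[p] - target| <= 1e-8 * target.
    """
    target = config.target_prevalence

    def f(b0: float) -> float:
        return mean_risk(b0, config.beta_gx, config.beta_ux, config.maf, config.gh_nodes) - target

    lo, hi = -2000.0, 0.0
    if not (f(lo) < 0 < f(hi)):
        raise RuntimeError(
            f"solve_beta0: target prevalence {target} not bracketed by beta0 in [{lo}, {hi}]"
        )
    beta0 = bisect(f, lo, hi, xtol=1e-12, maxiter=300)
    achieved = mean_risk(beta0, config.beta_gx, config.beta_ux, config.maf, config.gh_nodes)
    if abs(achieved - target) > 1e-8 * target:
        raise RuntimeError(
            f"solve_beta0 did not converge: E[p]={achieved:.12g} vs target {target:.12g} "
            f"at beta0={beta0:.9g}"
        )
    return float(beta0)


def simulate_cohort(
    config: SimConfig, beta0: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one population and return (genotype, confounder) among cases."""
    n = config.n_individuals
    g = simulate_genotypes(n, config.maf, rng)
    u = rng.standard_normal(n)
    p = expit(beta0 + config.beta_gx * g + config.beta_ux * u)
    disease = rng.random(n) < p
    return g[disease], u[disease]


def simulate_survival(
    u: np.ndarray, lam: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Weibull proportional-hazards survival times by inverse probability.

    t = ((-log v) / (lam * exp(u)))**(1/rho) with v ~ Unif(0,1), i.e. hazard
    lam * rho * t**(rho-1) * exp(u).  No censoring.
    """
    if lam <= 0 or rho <= 0:
        raise ValueError("lam and rho must be strictly positive")
    u = np.asarray(u, dtype=float)
    v = rng.random(u.shape)
    return weibull_time_from_uniform(v, u, lam, rho)


def weibull_time_from_uniform(v, u, lam: float, rho: float) -> np.ndarray:
    """Deterministic inverse-probability transform t(v, u)."""
    return ((-np.log(v)) / (lam * np.exp(u))) ** (1.0 / rho)


def fit_cox_loghr(
    times: np.ndarray,
    covariate: np.ndarray,
    events: np.ndarray | None = None,
) -> tuple[float, float]:
    """Single-covariate Cox log hazard ratio by maximum partial likelihood.

    All observations are treated as events unless ``events`` is given.  Ties,
    improbable with continuous times, use the Breslow approximation.
    """
    times = np.asarray(times, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if times.size < 2 or np.unique(times).size < 2:
        raise ValueError("need at least 2 distinct event times")
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant")
    status = np.ones(times.size) if events is None else np.asarray(events, dtype=float)
    res = PHReg(times, covariate[:, None], status=status, ties="breslow").fit()
    return float(res.params[0]), float(res.bse[0])


def run_replicate(config: SimConfig, beta0: float, rng: np.random.Generator) -> RepResult:
    """One replicate: simulate, ascertain cases, fit the spurious Cox model."""
    g_cases, u_cases = simulate_cohort(config, beta0, rng)
    n_cases = int(g_cases.size)
    if n_cases < MIN_CASES_FOR_COX:
        raise RuntimeError(f"replicate produced too few cases ({n_cases})")
    t = simulate_survival(u_cases, config.weibull_lambda, config.weibull_rho, rng)
    if config.censor_time is not None:
        events = (t <= config.censor_time).astype(int)
        t = np.minimum(t, config.censor_time)
        loghr, se = fit_cox_loghr(t, g_cases, events)
    else:
        loghr, se = fit_cox_loghr(t, g_cases)
    return RepResult(n_cases=n_cases, bias_hat=loghr, se_bias=se)


def run_cell(config: SimConfig) -> GridResult:
    """Run all replicates of one grid cell and summarise.

    Replicates use independent child seeds spawned from ``config.seed`` so a
    cell is reproducible in isolation.  A cell with more than 10% failed
    replicates (too few cases, or a Cox fit that does not converge) is marked
    unreliable.
    """
    beta0 = solve_beta0(config)
    children = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    biases = []
    case_counts = []
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        try:
            rep = run_replicate(config, beta0, rng)
        except Exception as exc:  # noqa: BLE001 - replicate-level containment
            n_failed += 1
            logger.warning("replicate failed (beta_ux=%g): %s", config.beta_ux, exc)
            continue
        biases.append(rep.bias_hat)
        case_counts.append(rep.n_cases)
    if not biases:
        raise RuntimeError(f"all replicates failed for beta_ux={config.beta_ux}")
    biases = np.asarray(biases)
    mean_bias = float(biases.mean())
    mc_se = float(biases.std(ddof=1) / math.sqrt(biases.size)) if biases.size > 1 else float("nan")
    true_log_hr = config.observed_log_hr - mean_bias
    return GridResult(
        beta_ux=config.beta_ux,
        beta0=beta0,
        mean_bias=mean_bias,
        mc_se_bias=mc_se,
        true_log_hr=true_log_hr,
        true_hr=float(np.exp(true_log_hr)),
        mean_n_cases=float(np.mean(case_counts)),
        n_reps_used=int(biases.size),
        n_reps_failed=n_failed,
        reliable=n_failed <= 0.1 * config.n_reps,
    )


def make_grid(
    base: SimConfig, beta_ux_values: Sequence[float] | None = None
) -> list[SimConfig]:
    """Expand a base config over a confounder-effect grid.

    Default grid {0, 2, ..., 20}.  Each cell gets an independent child seed
    derived from the base seed (kept below 2**31).
    """
    if beta_ux_values is None:
        beta_ux_values = np.arange(0.0, 20.0 + 1e-9, 2.0)
    seeds = np.random.SeedSequence(base.seed).generate_state(len(list(beta_ux_values)))
    return [
        replace(base, beta_ux=float(bux), seed=int(s % (2**31)))
        for bux, s in zip(beta_ux_values, seeds)
    ]


def run_grid(configs: Sequence[SimConfig]) -> pd.DataFrame:
    """Run each cell and return a tidy table keyed by beta_ux and seed."""
    rows = []
    for cfg in configs:
        res = run_cell(cfg)
        rows.append(
            {
                "beta_ux": res.beta_ux,
                "beta0": res.beta0,
                "mean_bias": res.mean_bias,
                "mc_se_bias": res.mc_se_bias,
                "true_log_hr": res.true_log_hr,
                "true_hr": res.true_hr,
                "mean_n_cases": res.mean_n_cases,
                "n_reps_used": res.n_reps_used,
                "n_reps_failed": res.n_reps_failed,
                "reliable": res.reliable,
                "seed": cfg.seed,
            }
        )
    return pd.DataFrame(rows)
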