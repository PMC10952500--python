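"""Synthetic two-trait GWAS summary statistics with a known bias slope.

Generative model per SNP j, matching the assumptions under which the bias
slope is identified (risk effects uncorrelated with true survival effects):

    true beta_gx_j      ~ Normal(0, tau_gx^2)
    direct beta_gy_j    = 0 with prob. 1 - prop_direct,
                          else Normal(0, tau_gy^2)   (point-normal pleiotropy)
    observed beta_gx_j  = beta_gx_j + Normal(0, se_gx_j^2)
    observed beta_gy'_j = b_true * beta_gx_j + beta_gy_j + Normal(0, se_gy_j^2)

with per-SNP standard errors drawn uniformly from their ranges.  The sampling
error in the observed risk effects is what attenuates a naive regression of
beta_gy' on observed beta_gx towards zero (regression dilution) — the exact
phenomenon the corrected weighted least squares estimator removes — so the
generator supports parameter-recovery tests for every estimator without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PAIR_COLUMNS

# non-palindromic allele pairs only, so harmonization round trips are exact
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass
class SyntheticSumstatsConfig:
    """Generative parameters for synthetic summary statistics.

    The default panel size mirrors a genome-wide LD-pruned SNP set
    (140,092 SNPs); recovery tests typically run at 10^4.  Effect-size and
    standard-error scales are on the order seen in moderately sized
    case-control GWAS (a few hundred to a few thousand cases).
    """

    n_snps: int = 140_092
    b_true: float = -0.025
    tau_gx: float = 0.08
    prop_direct: float = 0.1
    tau_gy: float = 0.05
    se_gx_range: tuple[float, float] = (0.03, 0.07)
    se_gy_range: tuple[float, float] = (0.10, 0.20)
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 3:
            raise ValueError("n_snps must be >= 3")
        if self.tau_gx <= 0 or self.tau_gy < 0:
            raise ValueError("tau_gx must be > 0 and tau_gy >= 0")
        if not 0.0 <= self.prop_direct <= 1.0:
            raise ValueError("prop_direct must be in [0, 1]")
        lo, hi = self.se_gx_range
        if lo < 0 or hi < lo:
            raise ValueError("se_gx_range must be ordered and non-negative")
        lo, hi = self.se_gy_range
        if lo <= 0 or hi < lo:
            # se_gy must stay positive: it feeds the inverse-variance weights
            raise ValueError("se_gy_range must be ordered and strictly positive")


@dataclass(frozen=True)
class GenerationTruth:
    """Ground truth stored alongside a generation, never seen by estimators."""

    b_true: float
    beta_gx_true: np.ndarray
    beta_gy_direct: np.ndarray


def generate(config: SyntheticSumstatsConfig) -> tuple[pd.DataFrame, GenerationTruth]:
    """Generate a harmonized-pairs frame and its generation truth.

    Deterministic given ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    beta_gx_true = rng.normal(0.0, config.tau_gx, size=n)
    direct = np.zeros(n)
    if config.prop_direct > 0 and config.tau_gy > 0:
        mask = rng.random(n) < config.prop_direct
        direct[mask] = rng.normal(0.0, config.tau_gy, size=int(mask.sum()))
    se_gx = rng.uniform(*config.se_gx_range, size=n)
    se_gy = rng.uniform(*config.se_gy_range, size=n)
    beta_gx_obs = beta_gx_true + rng.normal(0.0, 1.0, size=n) * se_gx
    beta_gy_obs = (
        config.b_true * beta_gx_true + direct + rng.normal(0.0, 1.0, size=n) * se_gy
    )
    pairs = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1}" for j in range(n)],
            "beta_gx": beta_gx_obs,
            "se_gx": se_gx,
            "beta_gy": beta_gy_obs,
            "se_gy": se_gy,
            "flipped": np.zeros(n, dtype=bool),
        }
    )[list(PAIR_COLUMNS)]
    truth = GenerationTruth(
        b_true=config.b_true, beta_gx_true=beta_gx_true, beta_gy_direct=direct
    )
    return pairs, truth


def to_sumstats(
    pairs: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a pairs frame into two writable summary-statistics frames.

    Alleles (non-palindromic) and positions are synthesized; p-values are the
    two-sided normal p-values of beta/se.  Reading the two frames back and
    harmonizing reproduces the pairs exactly.
    """
    rng = np.random.default_rng(seed)
    n = len(pairs)
    idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in idx])
    pos = np.arange(1, n + 1) * 1000
    chrom = np.full(n, "1")

    def frame(beta, se):
        beta = np.asarray(beta, dtype=float)
        se = np.asarray(se, dtype=float)
        p = np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), np.finfo(float).tiny, 1.0)
        return pd.DataFrame(
            {
                "snp_id": pairs["snp_id"].to_numpy(),
                "chrom": chrom,
                "pos": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "beta": beta,
                "se": se,
                "pvalue": p,
            }
        )

    risk = frame(pairs["beta_gx"], pairs["se_gx"])
    survival = frame(pairs["beta_gy"], pairs["se_gy"])
    return risk, survival
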