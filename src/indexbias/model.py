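"""Bias-slope estimation and index-event-bias adjustment of SNP effects.

The model: for a SNP with log odds ratio :math:`\\beta_{GX}` on disease risk
and case-only log hazard ratio :math:`\\beta_{GY}'` on survival, conditioning
on disease status induces a bias proportional to the risk effect,

.. math:: \\beta_{GY} \\approx \\beta_{GY}' - b\\,\\beta_{GX},

where :math:`\\beta_{GY}` is the bias-adjusted effect on survival.  The slope
``b`` is estimated by regressing survival effects on risk effects across many
independent SNPs, under the assumption that true survival effects are
uncorrelated with risk effects.  Three estimators are provided:

``ols``
    ordinary least squares;
``wls``
    inverse-variance weighting with weights :math:`1/\\mathrm{se}_{GY'}^2`
    (the squared standard errors of the log hazard ratios);
``cwls``
    corrected weighted least squares: the WLS slope is attenuated towards zero
    by sampling error in the risk-effect estimates (regression dilution), and
    is multiplied by the correction factor

    .. math:: \\hat c = \\frac{\\sum_j w_j \\hat\\beta_{GX,j}^2}
                             {\\sum_j w_j (\\hat\\beta_{GX,j}^2 -
                              \\mathrm{se}_{GX,j}^2)}.

Usage follows the model/results idiom::

    model = IndexEventBias.from_pairs(pairs)
    res = model.fit(method="cwls")
    print(res.summary())
    adj = res.adjust(beta_gy_prime, se_gy_prime, beta_gx, se_gx)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class SlopeEstimate:
    """A fitted bias slope with its uncertainty.

    ``correction_factor`` is 1 for ``ols``/``wls`` and the dilution factor
    :math:`\\hat c` for ``cwls``; ``intercept`` is 0 for through-origin fits.
    """

    b: float
    se_b: float
    ci_low: float
    ci_high: float
    pvalue: float
    intercept: float
    method: str
    n_snps: int
    correction_factor: float = 1.0


@dataclass(frozen=True)
class AdjustedEffect:
    """A bias-adjusted log hazard ratio with delta-method uncertainty."""

    beta_adj: float
    se_adj: float
    hr_adj: float
    ci_low_hr: float
    ci_high_hr: float


@dataclass(frozen=True)
class DiagnosticsBundle:
    """Regression diagnostics for normal QQ and scale-location plots.

    ``std_residuals`` are internally studentized residuals in observation
    order; ``qq_theoretical`` are standard-normal quantiles at plotting
    positions (i - 0.5)/n, paired with ``qq_sample`` (the sorted studentized
    residuals).
    """

    fitted: np.ndarray
    std_residuals: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    sqrt_abs_std_residuals: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fitted": self.fitted,
                "std_residual": self.std_residuals,
                "sqrt_abs_std_residual": self.sqrt_abs_std_residuals,
                "qq_theoretical": self.qq_theoretical,
                "qq_sample": self.qq_sample,
            }
        )


class IndexEventBias:
    """Regression model for the bias slope across independent SNPs.

    Parameters
    ----------
    beta_gx, beta_gy : array-like
        Per-SNP log odds ratios on disease risk and case-only log hazard
        ratios on survival, aligned to the same effect allele.
    se_gx, se_gy : array-like, optional
        Standard errors; ``se_gy`` is required for ``wls``/``cwls`` and
        ``se_gx`` for ``cwls``.
    """

    def __init__(self, beta_gx, beta_gy, se_gx=None, se_gy=None, snp_id=None):
        self.beta_gx = np.asarray(beta_gx, dtype=float)
        self.beta_gy = np.asarray(beta_gy, dtype=float)
        if self.beta_gx.shape != self.beta_gy.shape or self.beta_gx.ndim != 1:
            raise ValueError("beta_gx and beta_gy must be 1-d arrays of equal length")
        n = self.beta_gx.size
        if n < 3:
            raise ValueError("at least 3 SNPs are required to estimate a slope")
        if np.ptp(self.beta_gx) == 0:
            raise ValueError("degenerate design: beta_gx has zero variance")
        self.se_gx = None if se_gx is None else np.asarray(se_gx, dtype=float)
        self.se_gy = None if se_gy is None else np.asarray(se_gy, dtype=float)
        if self.se_gy is not None and np.any(self.se_gy <= 0):
            raise ValueError("se_gy must be strictly positive")
        self.snp_id = None if snp_id is None else np.asarray(snp_id)
        self.nobs = n

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame) -> "IndexEventBias":
        """Build the model from a harmonized-pairs frame (see ``indexbias.io``)."""
        return cls(
            pairs["beta_gx"],
            pairs["beta_gy"],
            se_gx=pairs["se_gx"] if "se_gx" in pairs else None,
            se_gy=pairs["se_gy"] if "se_gy" in pairs else None,
            snp_id=pairs["snp_id"] if "snp_id" in pairs else None,
        )

    # alias for DataFrame-first callers
    from_dataframe = from_pairs

    def fit(self, method: str = "wls", intercept: bool = True) -> "BiasSlopeResults":
        """Estimate the bias slope.

        Parameters
        ----------
        method : {"ols", "wls", "cwls"}
        intercept : bool
            Fit an intercept (default).  The bias relation itself has none,
            but an intercept absorbs directional pleiotropy in the SNP panel;
            ``intercept=False`` forces the regression through the origin.

        Confidence intervals and p-values use the normal approximation on the
        slope's standard error.
        """
        if method not in ("ols", "wls", "cwls"):
            raise ValueError(f"unknown method {method!r}")
        if method in ("wls", "cwls") and self.se_gy is None:
            raise ValueError(f"method {method!r} requires se_gy")
        weights = None if method == "ols" else 1.0 / self.se_gy**2
        x = self.beta_gx
        exog = sm.add_constant(x) if intercept else x[:, None]
        if weights is None:
            fit = sm.OLS(self.beta_gy, exog).fit()
        else:
            fit = sm.WLS(self.beta_gy, exog, weights=weights).fit()
        slope_ix = 1 if intercept else 0
        b = float(fit.params[slope_ix])
        se_b = float(fit.bse[slope_ix])
        icept = float(fit.params[0]) if intercept else 0.0
        correction = 1.0
        if method == "cwls":
            correction = self._dilution_factor(weights)
            b *= correction
            se_b *= abs(correction)
        est = SlopeEstimate(
            b=b,
            se_b=se_b,
            ci_low=b - Z975 * se_b,
            ci_high=b + Z975 * se_b,
            pvalue=_normal_pvalue(b, se_b),
            intercept=icept,
            method=method,
            n_snps=self.nobs,
            correction_factor=correction,
        )
        return BiasSlopeResults(self, est, weights=weights, has_intercept=intercept)

    def _dilution_factor(self, weights: np.ndarray) -> float:
        if self.se_gx is None:
            raise ValueError("cwls requires se_gx")
        num = float(np.sum(weights * self.beta_gx**2))
        den = float(np.sum(weights * (self.beta_gx**2 - self.se_gx**2)))
        if den <= 0:
            raise ValueError(
                "cwls correction undefined: weighted sum of beta_gx^2 - se_gx^2 "
                f"is {den:.3g} <= 0 (measurement error dominates the risk-effect signal)"
            )
        return num / den


def _normal_pvalue(b: float, se: float) -> float:
    if se == 0.0:
        # exact fit: the null is either certain or impossible
        return 1.0 if b == 0.0 else float(np.finfo(float).tiny)
    p = 2.0 * stats.norm.sf(abs(b) / se)
    # keep within the (0, 1] contract despite floating underflow
    return float(max(p, np.finfo(float).tiny))


class BiasSlopeResults:
    """Results of an :class:`IndexEventBias` fit.

    Exposes the slope estimate fields directly (``b``, ``se_b``, ``ci_low``,
    ``ci_high``, ``pvalue``, ``intercept``, ``method``, ``n_snps``,
    ``correction_factor``) plus diagnostics and the effect adjustment.
    """

    def __init__(self, model, estimate: SlopeEstimate, weights, has_intercept):
        self.model = model
        self.estimate = estimate
        self.weights = weights
        self.has_intercept = has_intercept

    def __getattr__(self, name):
        est = object.__getattribute__(self, "estimate")
        if hasattr(est, name):
            return getattr(est, name)
        raise AttributeError(name)

    @property
    def fittedvalues(self) -> np.ndarray:
        # fitted values on the uncorrected (ols/wls) regression line
        b_fit = self.b / self.correction_factor
        return self.intercept + b_fit * self.model.beta_gx

    def diagnostics(self) -> DiagnosticsBundle:
        """Internally studentized residuals, QQ and scale-location material.

        Residuals are studentized as :math:`r_i/(\\hat\\sigma\\sqrt{1-h_{ii}})`
        on the weighted (whitened) scale, using the same weights as the fit,
        so WLS diagnostics reflect the weighted regression exactly.  QQ
        theoretical quantiles use plotting positions (i - 0.5)/n.
        """
        n = self.model.nobs
        p = 2 if self.has_intercept else 1
        if n < 4:
            raise ValueError("diagnostics require at least 4 SNPs")
        x = self.model.beta_gx
        y = self.model.beta_gy
        w = np.ones(n) if self.weights is None else self.weights
        sw = np.sqrt(w)
        X = np.column_stack([np.ones(n), x]) if self.has_intercept else x[:, None]
        Xw = X * sw[:, None]
        fitted = self.fittedvalues
        resid_w = sw * (y - fitted)
        # hat diagonal of the whitened design
        Q, _ = np.linalg.qr(Xw)
        h = np.sum(Q**2, axis=1)
        dof = n - p
        sigma2 = float(resid_w @ resid_w) / dof
        # an exact fit leaves only rounding noise; report zero residuals
        scale = max(1.0, float(np.max(np.abs(y * sw))))
        if sigma2 <= (1e-10 * scale) ** 2:
            std = np.zeros(n)
        else:
            denom = np.sqrt(sigma2 * np.clip(1.0 - h, np.finfo(float).eps, None))
            std = resid_w / denom
        order = np.argsort(std, kind="stable")
        qq_theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        return DiagnosticsBundle(
            fitted=fitted,
            std_residuals=std,
            qq_theoretical=qq_theo,
            qq_sample=std[order],
            sqrt_abs_std_residuals=np.sqrt(np.abs(std)),
        )

    def adjust(
        self, beta_gy_prime: float, se_gy_prime: float, beta_gx: float, se_gx: float
    ) -> AdjustedEffect:
        """Bias-adjust one SNP's log hazard ratio.

        ``beta_adj = beta_gy_prime - b * beta_gx``; the standard error is
        propagated by the delta method ignoring covariances,
        ``se_adj^2 = se_gy'^2 + b^2 se_gx^2 + beta_gx^2 se_b^2`` (the target
        SNP's leverage on the fitted slope is negligible in a panel of many
        SNPs).  The hazard ratio and its 95% CI are the exponentials.
        """
        if se_gy_prime <= 0 or se_gx < 0:
            raise ValueError("standard errors must be positive")
        beta_adj = beta_gy_prime - self.b * beta_gx
        se_adj = float(
            np.sqrt(
                se_gy_prime**2 + self.b**2 * se_gx**2 + beta_gx**2 * self.se_b**2
            )
        )
        return AdjustedEffect(
            beta_adj=float(beta_adj),
            se_adj=se_adj,
            hr_adj=float(np.exp(beta_adj)),
            ci_low_hr=float(np.exp(beta_adj - Z975 * se_adj)),
            ci_high_hr=float(np.exp(beta_adj + Z975 * se_adj)),
        )

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Index event bias slope",
            "=" * 58,
            f"method:            {e.method}",
            f"n SNPs:            {e.n_snps}",
            f"intercept:         {e.intercept:.6g}"
            + ("" if self.has_intercept else "  (through origin)"),
            f"slope b:           {e.b:.6g}",
            f"se(b):             {e.se_b:.6g}",
            f"95% CI:            [{e.ci_low:.6g}, {e.ci_high:.6g}]",
            f"p-value:           {e.pvalue:.3g}",
        ]
        if e.method == "cwls":
            lines.append(f"dilution factor c: {e.correction_factor:.6g}")
        return "\n".join(lines)

    def __repr__(self):
        e = self.estimate
        return (
            f"<BiasSlopeResults method={e.method} b={e.b:.4g} "
            f"se={e.se_b:.4g} n={e.n_snps}>"
        )


# ---------------------------------------------------------------------------
# flat functional surface


def fit_slope_ols(pairs: pd.DataFrame, intercept: bool = True) -> BiasSlopeResults:
    """Unweighted least-squares bias slope from a harmonized-pairs frame."""
    return IndexEventBias.from_pairs(pairs).fit(method="ols", intercept=intercept)


def fit_slope_wls(pairs: pd.DataFrame, intercept: bool = True) -> BiasSlopeResults:
    """Inverse-variance-weighted bias slope (weights 1/se_gy^2)."""
    return IndexEventBias.from_pairs(pairs).fit(method="wls", intercept=intercept)


def cwls_correct(wls: BiasSlopeResults, pairs: pd.DataFrame) -> BiasSlopeResults:
    """Apply the regression-dilution correction to a fitted WLS slope."""
    if wls.method != "wls":
        raise ValueError("cwls_correct expects a WLS fit")
    return IndexEventBias.from_pairs(pairs).fit(
        method="cwls", intercept=wls.has_intercept
    )


def regression_diagnostics(pairs: pd.DataFrame, slope: BiasSlopeResults) -> DiagnosticsBundle:
    """Diagnostics for a slope fitted on the same pairs."""
    return slope.diagnostics()


def adjust_effect(
    beta_gy_prime: float,
    se_gy_prime: float,
    beta_gx: float,
    se_gx: float,
    slope: BiasSlopeResults,
) -> AdjustedEffect:
    """Bias-adjust a single SNP's log hazard ratio given a fitted slope."""
    return slope.adjust(beta_gy_prime, se_gy_prime, beta_gx, se_gx)
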