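"""Bayesian simple linear regression with a 95% credible-interval
zero criterion.

The model is y_i = alpha + beta x_i + eps_i, eps_i ~ N(0, sigma^2).
Two conjugate prior families are offered:

``reference``
    The improper prior p(alpha, beta, log sigma) proportional to 1.
    The marginal posterior of the slope is a location-scale t with
    n - 2 degrees of freedom centered on the OLS estimate, so the 95%
    credible interval coincides exactly with the classical OLS
    t-interval -- a testable identity, and the reason the
    includes-zero criterion agrees with a two-sided test at alpha=0.05
    under this prior.

``nig``
    A proper Normal-inverse-gamma prior: (alpha, beta) | sigma^2 ~
    N(m0, sigma^2 V0), sigma^2 ~ InvGamma(a0, b0).  The slope marginal
    is again a location-scale t (df 2 a_n) with closed-form updates.
    A shrinkage prior can move a borderline interval across zero,
    which is why both families are exposed.

A relationship is declared when the credible interval of the slope
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class RegressionError(ValueError):
    pass


@dataclass(frozen=True)
class BayesRegressionResults:
    """Posterior summary of the slope (and intercept) of a simple
    regression, with the credible-interval zero criterion."""

    slope_mean: float
    ci95_lo: float
    ci95_hi: float
    includes_zero: bool
    prior: str
    n: int
    intercept_mean: float
    slope_sd: float
    df: float
    sigma2_mean: float
    degenerate: bool = False
    ci_level: float = 0.95

    def summary(self) -> str:
        lines = [
            "Bayesian simple linear regression",
            f"  prior: {self.prior}    n: {self.n}    posterior df: {self.df:g}",
            f"  slope:     {self.slope_mean: .6g}  "
            f"[{self.ci95_lo: .6g}, {self.ci95_hi: .6g}] "
            f"({self.ci_level:.0%} credible interval)",
            f"  intercept: {self.intercept_mean: .6g}",
            "  E[sigma^2]: " + (
                f"{self.sigma2_mean: .6g}" if np.isfinite(self.sigma2_mean)
                else "undefined (posterior df <= 2)"),
            f"  interval includes zero: {self.includes_zero}",
        ]
        if self.degenerate:
            lines.append("  NOTE: zero residual variance; point interval")
        return "\n".join(lines)


class BayesSimpleRegression:
    """Simple linear regression fitted by conjugate Bayesian analysis.

    Parameters
    ----------
    y, x : array-like, equal length >= 3; ``x`` must be non-constant.
    prior : "reference" (default) or "nig".
    m0, v0, a0, b0 : NIG hyperparameters (ignored for the reference
        prior). ``v0`` is the prior covariance scale of (intercept,
        slope) in units of sigma^2; scalars are promoted to tau^2 I.
    """

    def __init__(self, y, x, prior: str = "reference",
                 m0=(0.0, 0.0), v0=100.0, a0: float = 0.01, b0: float = 0.01):
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise RegressionError("x and y must be equal-length vectors")
        if y.size < 3:
            raise RegressionError("need at least 3 observations")
        if np.ptp(x) == 0:
            raise RegressionError("x is constant; the slope is not identified")
        if prior not in ("reference", "nig"):
            raise RegressionError(f"unknown prior {prior!r}")
        self.y, self.x, self.prior = y, x, prior
        self.m0 = np.asarray(m0, dtype=float)
        self.v0 = (np.eye(2) * float(v0) if np.isscalar(v0)
                   else np.asarray(v0, dtype=float))
        self.a0, self.b0 = float(a0), float(b0)

    @classmethod
    def from_dataframe(cls, data, y: str, x: str, **kwargs):
        return cls(data[y].to_numpy(), data[x].to_numpy(), **kwargs)

    def fit(self, ci_level: float = 0.95) -> BayesRegressionResults:
        n = self.y.size
        design = np.column_stack([np.ones(n), self.x])
        xtx = design.T @ design
        xty = design.T @ self.y

        if self.prior == "reference":
            beta_hat = np.linalg.solve(xtx, xty)
            resid = self.y - design @ beta_hat
            sse = float(resid @ resid)
            df = n - 2
            cov_unscaled = np.linalg.inv(xtx)
            if sse <= 1e-14 * float(self.y @ self.y + 1.0):
                return BayesRegressionResults(
                    slope_mean=float(beta_hat[1]),
                    ci95_lo=float(beta_hat[1]), ci95_hi=float(beta_hat[1]),
                    includes_zero=bool(beta_hat[1] == 0.0),
                    prior=self.prior, n=n,
                    intercept_mean=float(beta_hat[0]), slope_sd=0.0,
                    df=df, sigma2_mean=0.0, degenerate=True,
                    ci_level=ci_level,
                )
            s2 = sse / df
            scale = float(np.sqrt(s2 * cov_unscaled[1, 1]))
            tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)
            lo = float(beta_hat[1] - tcrit * scale)
            hi = float(beta_hat[1] + tcrit * scale)
            sigma2_mean = sse / (df - 2) if df > 2 else float("nan")
            mean_slope, mean_icept = float(beta_hat[1]), float(beta_hat[0])
        else:
            v0_inv = np.linalg.inv(self.v0)
            vn = np.linalg.inv(v0_inv + xtx)
            mn = vn @ (v0_inv @ self.m0 + xty)
            an = self.a0 + n / 2.0
            bn = self.b0 + 0.5 * float(
                self.y @ self.y + self.m0 @ v0_inv @ self.m0
                - mn @ (v0_inv + xtx) @ mn
            )
            df = 2.0 * an
            scale = float(np.sqrt(bn / an * vn[1, 1]))
            tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)
            lo = float(mn[1] - tcrit * scale)
            hi = float(mn[1] + tcrit * scale)
            sigma2_mean = bn / (an - 1.0) if an > 1 else float("nan")
            mean_slope, mean_icept = float(mn[1]), float(mn[0])

        return BayesRegressionResults(
            slope_mean=mean_slope, ci95_lo=lo, ci95_hi=hi,
            includes_zero=bool(lo <= 0.0 <= hi),
            prior=self.prior, n=n, intercept_mean=mean_icept,
            slope_sd=scale * np.sqrt(df / (df - 2)) if df > 2 else float("nan"),
            df=float(df), sigma2_mean=float(sigma2_mean),
            ci_level=ci_level,
        )


def bayes_simple_regression(x, y, prior: str = "reference",
                            ci_level: float = 0.95,
                            **prior_kwargs) -> BayesRegressionResults:
    """Functional wrapper: fit y on x and return the posterior summary."""
    return BayesSimpleRegression(y, x, prior=prior, **prior_kwargs).fit(
        ci_level=ci_level
    )
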