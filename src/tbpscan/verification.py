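"""Predicted-vs-measured verification battery for K_D ratios.

The package's predictions are verified against measured dissociation
constants by comparing the per-SNP ratio K_D(mut)/K_D(wt) predicted in
silico with the ratio measured in vitro, using four association statistics
that cross-check one another — Pearson's linear correlation r, Spearman's
rank correlation R, Kendall's rank correlation tau, and the Goodman-Kruskal
generalized correlation gamma — plus an ordinary least-squares regression
with a 95% confidence band of the mean response.

Ratios are analysed on the given scale by default (mirroring the ratio
plane the verification is usually plotted on); ``log_scale=True`` switches
to natural-log ratios.  Kendall's statistic is tau-b, which reduces to
tau-a when the data are ties-free.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDataError


@dataclass(frozen=True)
class CorrelationReport:
    """The four association statistics, their significance, and the OLS fit."""

    r: float
    spearman_R: float
    kendall_tau: float
    gamma: float
    alphas: dict[str, float]
    slope: float
    intercept: float
    ci95_lower: np.ndarray
    ci95_upper: np.ndarray
    n: int

    def summary(self) -> str:
        a = self.alphas
        return "\n".join([
            f"n = {self.n}",
            f"linear r        = {self.r: .3f}  (alpha = {a['r']:.2g})",
            f"Spearman R      = {self.spearman_R: .3f}  (alpha = {a['spearman_R']:.2g})",
            f"Kendall tau     = {self.kendall_tau: .3f}  (alpha = {a['kendall_tau']:.2g})",
            f"Goodman-Kruskal = {self.gamma: .3f}  (alpha = {a['gamma']:.2g})",
            f"OLS: measured = {self.slope:.3f} * predicted + {self.intercept:.3f}",
        ])


def goodman_kruskal_gamma(x, y) -> tuple[float, float]:
    """Goodman-Kruskal gamma with its normal-approximation significance.

    gamma = (C - D) / (C + D) over all point pairs, where C counts
    concordant and D discordant pairs; pairs tied in either variable are
    excluded from both counts.  The significance uses the classic
    z = gamma * sqrt((C + D) / (n * (1 - gamma^2))) approximation; a
    perfectly concordant or discordant sample reports p = 0.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    concordant = discordant = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[j] - x[i], y[j] - y[i]
        if dx == 0 or dy == 0:
            continue
        if dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    pairs = concordant + discordant
    if pairs == 0:
        raise DegenerateDataError("all pairs tied; gamma undefined")
    gamma = (concordant - discordant) / pairs
    if abs(gamma) >= 1.0:
        return gamma, 0.0
    z = gamma * math.sqrt(pairs / (n * (1.0 - gamma ** 2)))
    return gamma, float(2.0 * stats.norm.sf(abs(z)))


def correlation_suite(predicted_ratio, measured_ratio,
                      log_scale: bool = False) -> CorrelationReport:
    """Run the full verification battery on paired K_D ratios."""
    x = np.asarray(predicted_ratio, dtype=float)
    y = np.asarray(measured_ratio, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sequences must be paired and 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("K_D ratios must be positive")
    if log_scale:
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in one of the sequences")

    r, p_r = stats.pearsonr(x, y)
    rho, p_rho = stats.spearmanr(x, y)
    tau, p_tau = stats.kendalltau(x, y)  # tau-b; equals tau-a without ties
    gamma, p_gamma = goodman_kruskal_gamma(x, y)

    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    band = fit.get_prediction(design).conf_int(alpha=0.05)

    return CorrelationReport(
        r=float(r), spearman_R=float(rho), kendall_tau=float(tau), gamma=gamma,
        alphas={"r": float(p_r), "spearman_R": float(p_rho),
                "kendall_tau": float(p_tau), "gamma": p_gamma},
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        ci95_lower=band[:, 0], ci95_upper=band[:, 1],
        n=len(x),
    )
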