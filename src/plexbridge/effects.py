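"""Hedges' g effect sizes and FDR-controlled prospective power analysis.

Hedges' g is the bias-corrected standardized mean difference

    g = J * (mean_x - mean_y) / s_pooled,
    s_pooled^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2),
    J = 1 - 3 / (4 df - 1),  df = n1 + n2 - 2.

The 95% CI comes from inverting the noncentral-t pivot on the Cohen's-d
scale (the observed t = d * sqrt(n1 n2 / (n1 + n2)) has a noncentral t
distribution whose noncentrality is the population standardized difference
times the same factor); a normal approximation is used for df > 200.

Prospective power under FDR control: for an assumed per-protein effect g,
per-group sample size n, target false discovery rate f and null proportion
pi0, the per-comparison significance level alpha is the solution of

    f = pi0 * alpha / (pi0 * alpha + (1 - pi0) * (1 - beta(alpha))),

where 1 - beta is the power of the two-sided two-sample t-test with
noncentrality g * sqrt(n/2) on 2n - 2 degrees of freedom. The power at the
solved alpha is the protein's predicted power; sweeping n gives the
power-versus-sample-size curve and the minimum n reaching a target power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EffectSizeResult",
    "PowerCurve",
    "hedges_g",
    "effect_table",
    "effect_scatter_table",
    "fdr_alpha",
    "power_curve",
    "t_test_power",
]


def _nct_cdf(x: float, df: float, ncp: float) -> float:
    """Noncentral-t CDF, robust in the deep tails.

    scipy's implementation can return NaN for extreme noncentrality; fall
    back to the standard normal approximation of the noncentral t there
    (the probabilities involved are ~0 or ~1 anyway).
    """
    v = stats.nct.cdf(x, df, ncp)
    if np.isnan(v):
        z = (x * (1.0 - 1.0 / (4.0 * df)) - ncp) / np.sqrt(1.0 + x * x / (2.0 * df))
        v = stats.norm.cdf(z)
    return float(v)


def _nct_sf(x: float, df: float, ncp: float) -> float:
    v = stats.nct.sf(x, df, ncp)
    if np.isnan(v):
        v = 1.0 - _nct_cdf(x, df, ncp)
    return float(v)


@dataclass
class EffectSizeResult:
    """Per-entry standardized effect with CI and (optionally) percentile rank."""

    entry_id: str
    n1: int
    n2: int
    delta: float  # mean_x - mean_y (PDR - CTL in the study orientation)
    s_pooled: float
    g: float
    ci_low: float
    ci_high: float
    percentile_rank: float = float("nan")  # of |g| among all entries, in [0, 100]
    assumption_warning: bool = False

    @property
    def correction_j(self) -> float:
        df = self.n1 + self.n2 - 2
        return 1.0 - 3.0 / (4.0 * df - 1.0)


def _nct_ci(t_obs: float, df: int, scale: float, level: float = 0.95):
    """CI for the population standardized difference by noncentral-t inversion.

    ``scale`` is sqrt(n1*n2/(n1+n2)); bounds are returned on the d scale.
    """
    alpha = 1.0 - level
    if df > 200:  # normal approximation for large df
        d = t_obs / scale
        n = scale**2
        se = np.sqrt(1.0 / n + d * d / (2.0 * df))
        zc = stats.norm.ppf(1 - alpha / 2)
        return d - zc * se, d + zc * se

    def lo_eq(ncp):
        return _nct_cdf(t_obs, df, ncp) - (1 - alpha / 2)

    def hi_eq(ncp):
        return _nct_cdf(t_obs, df, ncp) - alpha / 2

    span = max(10.0, 4.0 * abs(t_obs) + 10.0)
    lo = optimize.brentq(lo_eq, t_obs - span, t_obs + span, xtol=1e-10)
    hi = optimize.brentq(hi_eq, t_obs - span, t_obs + span, xtol=1e-10)
    return lo / scale, hi / scale


def hedges_g(
    x: Sequence[float],
    y: Sequence[float],
    entry_id: str = "",
    ci_level: float = 0.95,
) -> EffectSizeResult:
    """Bias-corrected standardized difference of two groups (x minus y).

    Requires n1, n2 >= 2. Zero pooled SD (no dispersion in either group)
    yields an undefined standardized effect: the result carries
    ``assumption_warning=True`` with NaN g/CI rather than failing, so batch
    callers can report it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")
    df = n1 + n2 - 2
    delta = float(x.mean() - y.mean())
    s_pooled = float(
        np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df)
    )
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    if s_pooled == 0.0:
        return EffectSizeResult(
            entry_id=entry_id,
            n1=n1,
            n2=n2,
            delta=delta,
            s_pooled=0.0,
            g=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            assumption_warning=True,
        )
    d = delta / s_pooled
    g = j * d
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    lo, hi = _nct_ci(d * scale, df, scale, level=ci_level)
    return EffectSizeResult(
        entry_id=entry_id,
        n1=n1,
        n2=n2,
        delta=delta,
        s_pooled=s_pooled,
        g=g,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def effect_table(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    group_order: tuple[str, str] = ("CTL", "PDR"),
    ci_level: float = 0.95,
) -> list[EffectSizeResult]:
    """Per-entry Hedges' g (second group minus first) with percentile ranks.

    Percentile rank is the fraction of entries with |g| less than or equal
    to the entry's own |g|, times 100 (entries with undefined g excluded
    from the ranking).
    """
    g = np.asarray(list(groups))
    a = matrix.loc[:, g == group_order[0]].to_numpy(dtype=float)
    b = matrix.loc[:, g == group_order[1]].to_numpy(dtype=float)
    results = [
        hedges_g(b[i], a[i], entry_id=str(e), ci_level=ci_level)
        for i, e in enumerate(matrix.index)
    ]
    abs_g = np.array([abs(r.g) for r in results])
    defined = ~np.isnan(abs_g)
    m = defined.sum()
    for r, ag, ok in zip(results, abs_g, defined):
        if ok:
            r.percentile_rank = float(100.0 * (abs_g[defined] <= ag).sum() / m)
    return results


def effect_scatter_table(effects: Sequence[EffectSizeResult]) -> pd.DataFrame:
    """Delta-magnitude vs dispersion table behind the effect-size scatter view.

    The product |delta| * inv_dispersion * J reproduces |g| exactly; the
    signed g, CI, and percentile rank are carried alongside.
    """
    if len(effects) == 0:
        raise ValueError("need at least one effect")
    return pd.DataFrame(
        {
            "entry_id": [e.entry_id for e in effects],
            "abs_delta": [abs(e.delta) for e in effects],
            "dispersion": [e.s_pooled for e in effects],
            "inv_dispersion": [
                (1.0 / e.s_pooled if e.s_pooled > 0 else float("nan")) for e in effects
            ],
            "J": [e.correction_j for e in effects],
            "g": [e.g for e in effects],
            "ci_low": [e.ci_low for e in effects],
            "ci_high": [e.ci_high for e in effects],
            "percentile_rank": [e.percentile_rank for e in effects],
            "assumption_warning": [e.assumption_warning for e in effects],
        }
    ).set_index("entry_id")


def t_test_power(alpha: float, n: int, g: float, n2: int | None = None) -> float:
    """Power of the two-sided two-sample t-test at per-comparison level alpha.

    Equal group sizes n (noncentrality g*sqrt(n/2)) unless ``n2`` is given,
    in which case the unequal-n noncentrality g*sqrt(n*n2/(n+n2)) on
    n + n2 - 2 df is used.
    """
    if n2 is None:
        df = 2 * n - 2
        ncp = abs(g) * np.sqrt(n / 2.0)
    else:
        df = n + n2 - 2
        ncp = abs(g) * np.sqrt(n * n2 / (n + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return _nct_sf(tcrit, df, ncp) + _nct_cdf(-tcrit, df, ncp)


def fdr_alpha(
    n: int,
    g: float,
    fdr: float = 0.05,
    pi0: float = 0.7,
    n2: int | None = None,
) -> tuple[float, float, bool]:
    """Per-comparison alpha (and its power) that controls the FDR at ``fdr``.

    Solves  fdr = pi0*alpha / (pi0*alpha + (1-pi0)*power(alpha))  for alpha
    in (0, 1) by bracketed root-finding to |residual| < 1e-10. Returns
    (alpha, power, attained); when no root exists in (0, 1) — e.g. the
    requested fdr is at or above pi0 — (nan, 0.0, False) is returned.
    """
    if not (0 < fdr < 1 and 0 < pi0 < 1):
        raise ValueError("fdr and pi0 must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    if g == 0:
        raise ValueError("effect size must be nonzero")

    def residual(alpha: float) -> float:
        pw = t_test_power(alpha, n, g, n2=n2)
        return pi0 * alpha / (pi0 * alpha + (1.0 - pi0) * pw) - fdr

    # The analytic residual increases from -fdr (alpha -> 0) toward pi0 - fdr
    # (alpha -> 1), but in floating point the t power underflows at extreme
    # alpha and the ratio saturates at 1. Scan a log-spaced grid and bracket
    # the genuine negative-to-positive crossing (the largest one).
    grid = np.concatenate([np.logspace(-200.0, -0.01, 60), [1.0 - 1e-12]])
    res = np.array([residual(a) for a in grid])
    bracket = None
    for i in range(len(grid) - 1, 0, -1):
        if res[i - 1] < 0.0 <= res[i]:
            bracket = (grid[i - 1], grid[i])
            break
    if bracket is None:
        return float("nan"), 0.0, False
    alpha = optimize.brentq(
        residual, bracket[0], bracket[1], xtol=1e-300, rtol=1e-15, maxiter=200
    )
    if abs(residual(alpha)) > 1e-10:
        return float("nan"), 0.0, False
    return float(alpha), t_test_power(alpha, n, g, n2=n2), True


@dataclass
class PowerCurve:
    """Predicted power versus per-group sample size under FDR control."""

    g: float
    fdr: float
    pi0: float
    n_grid: np.ndarray
    power: np.ndarray
    alpha: np.ndarray = field(default_factory=lambda: np.array([]))

    def n_min(self, target_power: float = 0.8) -> int | None:
        """Smallest per-group n with power >= target (None if never reached)."""
        hits = np.nonzero(self.power >= target_power)[0]
        return int(self.n_grid[hits[0]]) if hits.size else None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n_grid, "power": self.power, "alpha": self.alpha})

    def plot(self, ax=None, target_power: float = 0.8, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.plot(self.n_grid, self.power, marker="o", ms=3, label=label)
        ax.axhline(target_power, color="0.5", lw=0.8)
        ax.set_xlabel("samples per group")
        ax.set_ylabel("predicted power")
        ax.set_ylim(0, 1.02)
        return ax


def power_curve(
    g: float,
    fdr: float = 0.05,
    pi0: float = 0.7,
    n_max: int = 30,
) -> PowerCurve:
    """Evaluate FDR-controlled power over per-group sizes n = 2..n_max."""
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    ns = np.arange(2, n_max + 1)
    alphas = np.empty(ns.size)
    powers = np.empty(ns.size)
    for i, n in enumerate(ns):
        a, p, ok = fdr_alpha(int(n), g, fdr=fdr, pi0=pi0)
        alphas[i] = a if ok else np.nan
        powers[i] = p
    return PowerCurve(g=g, fdr=fdr, pi0=pi0, n_grid=ns, power=powers, alpha=alphas)
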