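"""Moderated-t differential expression with Storey q-values.

The model is the empirical-Bayes two-group comparison used throughout
microarray/proteomics practice: per protein, an ordinary two-sample
pooled-variance t is stabilized by shrinking the residual variance s2_g
toward a prior s0^2 fitted across all proteins,

    s2_post = (d0 * s0^2 + df_g * s2_g) / (d0 + df_g)
    t_mod   = log2fc / sqrt(s2_post * (1/n1 + 1/n2))
    p       = 2 * P(T_{d0 + df_g} > |t_mod|)

with hyperparameters (d0, s0^2) estimated by matching the moments of the
log sample variances to a scaled F distribution (digamma/trigamma moment
equations, Newton root-finding for d0; d0 = +inf when the observed
dispersion of variances falls below the theoretical minimum, in which case
every posterior variance equals s0^2 and the reference distribution is
normal).

Multiple testing uses Storey's q-value: pi0 is estimated with the fixed-
lambda estimator  pi0 = #{p > lambda} / ((1 - lambda) m)  (default
lambda = 0.5, optional smoother over a lambda grid), and
q_(i) = min_{j >= i} pi0 * m * p_(j) / j. With pi0 = 1 this reduces
exactly to Benjamini-Hochberg.

Organized as a statsmodels-style pair: :class:`DifferentialExpressionModel`
built from a matrix + group labels, whose :meth:`fit` returns a
:class:`DifferentialExpressionResults` carrying estimates, hyperparameters,
and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import PlexDesign, QuantMatrix

__all__ = [
    "EBayesHyper",
    "DifferentialExpressionModel",
    "DifferentialExpressionResults",
    "trim_matrix",
    "fit_moderated_t",
    "storey_q",
    "volcano_table",
]


@dataclass(frozen=True)
class EBayesHyper:
    """Fitted prior: degrees of freedom d0 (may be +inf) and variance s0sq."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("d0 must be nonnegative")
        if not self.s0sq > 0:
            raise ValueError("s0sq must be positive")


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y (Newton iteration on 1/trigamma)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif / y) < 1e-10):
            break
    return y


def fit_f_dist(s2: np.ndarray, df: float) -> EBayesHyper:
    """Moment-match log sample variances to a scaled F to get (d0, s0sq).

    Uses E[log s2] and Var[log s2] under s2 ~ s0sq * F(df, d0); the excess of
    the observed variance of log s2 over trigamma(df/2) identifies
    trigamma(d0/2). Nonpositive excess means the variances are less dispersed
    than a chi-square with df degrees of freedom allows -> d0 = +inf.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 0.0)
    if s2.size < 2:
        raise ValueError("need >= 2 sample variances to fit hyperparameters")
    m = np.median(s2)
    if m == 0:
        raise ValueError("more than half of the sample variances are exactly zero")
    s2 = np.maximum(s2, 1e-5 * m)  # offset exact zeros away from log(0)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array(evar)))
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # variances less dispersed than chi-square sampling noise alone:
        # infinite prior df, prior variance is the plain mean
        d0 = np.inf
        s0sq = float(s2.mean())
    return EBayesHyper(d0=d0, s0sq=s0sq)


def _two_sided_p(t: np.ndarray, df: float | np.ndarray) -> np.ndarray:
    if np.isscalar(df) and np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


def storey_q(
    pvalues: Sequence[float],
    lam: float = 0.5,
    smoother: bool = False,
) -> tuple[np.ndarray, float]:
    """Storey q-values and the pi0 estimate.

    pi0 = #{p > lam} / ((1 - lam) * m), capped at 1 (and floored at 1/m so a
    degenerate 0 never zeroes every q). With ``smoother=True``, pi0(lam) is
    evaluated on a lambda grid and a cubic smoothing spline is read off at
    the largest lambda (Storey's smoother variant). q-values are the step-up
    running minima of pi0 * m * p_(j) / j, monotone nondecreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), 1.0
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size

    if smoother:
        from scipy.interpolate import UnivariateSpline

        grid = np.arange(0.05, 0.96, 0.05)
        pi0s = np.array([(p > g).sum() / ((1 - g) * m) for g in grid])
        spl = UnivariateSpline(grid, pi0s, k=3)
        pi0 = float(spl(grid.max()))
    else:
        pi0 = (p > lam).sum() / ((1 - lam) * m)
    pi0 = float(min(max(pi0, 1.0 / m), 1.0))

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def trim_matrix(a: QuantMatrix, designs: Sequence[PlexDesign]) -> QuantMatrix:
    """Drop pool columns and any entry not measured across all remaining samples.

    Pool-role channels (bridge/validation pools) are technical material and
    are excluded from differential analysis; only entries with zero missing
    cells across the individual samples are kept.
    """
    individual = {
        d.global_sample_id(c)
        for d in designs
        for c in d.sample_channels()
        if c.role == "individual"
    }
    cols = [s for s in a.sample_ids if s in individual]
    sub = a.values[cols]
    complete = sub.dropna(axis=0, how="any")
    if complete.shape[0] == 0:
        raise ValueError("no complete entries remain after trimming")
    return QuantMatrix(complete, level=a.level, kind=a.kind)


def _group_arrays(
    matrix: pd.DataFrame, groups: Sequence[str], labels: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(groups)
    a = matrix.loc[:, g == labels[0]].to_numpy(dtype=float)
    b = matrix.loc[:, g == labels[1]].to_numpy(dtype=float)
    return a, b


class DifferentialExpressionModel:
    """Two-group moderated-t model on an entries x samples log2 matrix.

    Parameters
    ----------
    matrix : complete (no-missing) DataFrame, entries as rows, samples as
        columns.
    groups : per-column phenotype labels; the contrast is
        ``group_order[1] - group_order[0]`` (default PDR minus CTL).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        groups: Sequence[str],
        group_order: tuple[str, str] = ("CTL", "PDR"),
    ) -> None:
        if matrix.isna().to_numpy().any():
            raise ValueError("matrix must be complete; trim incomplete entries first")
        g = pd.Series(list(groups))
        counts = g.value_counts()
        for label in group_order:
            if counts.get(label, 0) < 2:
                raise ValueError(f"group '{label}' needs >= 2 samples")
        self.matrix = matrix
        self.groups = list(groups)
        self.group_order = group_order

    @classmethod
    def from_abundance(
        cls,
        a: QuantMatrix,
        designs: Sequence[PlexDesign],
        group_order: tuple[str, str] = ("CTL", "PDR"),
    ) -> "DifferentialExpressionModel":
        """Build from a unified abundance matrix: trim pools/incomplete entries,
        take phenotype labels from the design."""
        trimmed = trim_matrix(a, designs)
        phen = {
            d.global_sample_id(c): c.phenotype
            for d in designs
            for c in d.sample_channels()
        }
        groups = [phen[s] for s in trimmed.sample_ids]
        return cls(trimmed.values, groups, group_order=group_order)

    def fit(
        self,
        d0: float | None = None,
        s0sq: float | None = None,
        storey_lambda: float = 0.5,
        storey_smoother: bool = False,
        annotation: Mapping[str, str] | None = None,
    ) -> "DifferentialExpressionResults":
        """Fit hyperparameters (unless fixed) and compute per-entry statistics.

        ``d0``/``s0sq`` may be fixed for testing: d0=0 reproduces the
        ordinary pooled-variance t; d0=inf forces every posterior variance
        to s0sq.
        """
        x, y = _group_arrays(self.matrix, self.groups, self.group_order)
        n1, n2 = x.shape[1], y.shape[1]
        df_g = n1 + n2 - 2
        hyper_fitted = d0 is None or s0sq is None

        mean_a = x.mean(axis=1)
        mean_b = y.mean(axis=1)
        log2fc = mean_b - mean_a  # PDR minus CTL by default
        s2 = ((x.var(axis=1, ddof=1) * (n1 - 1)) + (y.var(axis=1, ddof=1) * (n2 - 1))) / df_g

        if d0 is None or s0sq is None:
            if (s2 > 0).sum() < 2:
                warnings.warn(
                    "all entries have zero variance; falling back to ordinary t",
                    RuntimeWarning,
                )
                hyper = EBayesHyper(d0=0.0 + 1e-300, s0sq=1.0)
                d0_eff, s0_eff = 0.0, 1.0
            else:
                hyper = fit_f_dist(s2, df_g)
                d0_eff, s0_eff = hyper.d0, hyper.s0sq
        else:
            d0_eff, s0_eff = float(d0), float(s0sq)
            hyper = EBayesHyper(d0=max(d0_eff, 1e-300), s0sq=s0_eff)

        if np.isinf(d0_eff):
            s2_post = np.full_like(s2, s0_eff)
            df_total = np.inf
        else:
            s2_post = (d0_eff * s0_eff + df_g * s2) / (d0_eff + df_g)
            df_total = d0_eff + df_g
        if hyper_fitted:
            # an estimated prior cannot carry more information than the pooled
            # residual df across all entries (a supplied prior can)
            df_total = min(df_total, len(s2) * df_g)

        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = log2fc / se
        pvals = _two_sided_p(t_mod, df_total)
        q, pi0 = storey_q(pvals, lam=storey_lambda, smoother=storey_smoother)

        frame = pd.DataFrame(
            {
                "entry_id": self.matrix.index,
                f"mean_{self.group_order[0].lower()}": mean_a,
                f"mean_{self.group_order[1].lower()}": mean_b,
                "log2fc": log2fc,
                "linear_fc": np.sign(log2fc) * 2.0 ** np.abs(log2fc),
                "s2": s2,
                "s2_posterior": s2_post,
                "t_mod": t_mod,
                "df_total": df_total,
                "p": pvals,
                "q": q,
            }
        ).set_index("entry_id")
        if annotation is not None:
            frame["annotation"] = [annotation.get(e, "other") for e in frame.index]
        else:
            frame["annotation"] = "other"
        return DifferentialExpressionResults(
            model=self,
            frame=frame,
            hyper=hyper,
            pi0_hat=pi0,
            n_per_group=(n1, n2),
        )


@dataclass
class DifferentialExpressionResults:
    """Per-entry estimates plus shared empirical-Bayes hyperparameters."""

    model: DifferentialExpressionModel
    frame: pd.DataFrame
    hyper: EBayesHyper
    pi0_hat: float
    n_per_group: tuple[int, int]

    def summary(self, alpha: float = 0.05) -> str:
        f = self.frame
        n_sig = int((f["q"] < alpha).sum())
        lines = [
            "Moderated-t differential expression",
            "=" * 48,
            f"entries tested:        {len(f)}",
            f"group sizes:           {self.n_per_group[0]} vs {self.n_per_group[1]} "
            f"({self.model.group_order[0]} vs {self.model.group_order[1]})",
            f"prior df (d0):         {self.hyper.d0:.4g}",
            f"prior variance (s0^2): {self.hyper.s0sq:.4g}",
            f"pi0 estimate:          {self.pi0_hat:.4g}",
            f"q < {alpha:g}:              {n_sig} ({100.0 * n_sig / len(f):.1f}%)",
            "=" * 48,
        ]
        return "\n".join(lines)

    def volcano_table(self, fc_cut: float = 1.5, q_cut: float = 0.05) -> pd.DataFrame:
        return volcano_table(self.frame, fc_cut=fc_cut, q_cut=q_cut)

    def plot_volcano(self, fc_cut: float = 1.5, q_cut: float = 0.05, ax=None):
        """Volcano plot: log2 fold change vs -log10 q, cut lines dashed/solid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        f = self.frame
        colors = f["annotation"].map({"rbc": "crimson", "plasma": "royalblue"}).fillna("0.6")
        ax.scatter(f["log2fc"], -np.log10(f["q"].clip(lower=1e-300)), s=8, c=colors)
        lfc = np.log2(fc_cut)
        ax.axvline(lfc, ls="--", c="k", lw=0.8)
        ax.axvline(-lfc, ls="--", c="k", lw=0.8)
        ax.axhline(-np.log10(q_cut), ls="-", c="k", lw=0.8)
        ax.set_xlabel("log2 fold change (PDR - CTL)")
        ax.set_ylabel("-log10 q")
        return ax


def fit_moderated_t(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    group_order: tuple[str, str] = ("CTL", "PDR"),
    **fit_kwargs,
) -> DifferentialExpressionResults:
    """Functional wrapper over the Model/Results pair."""
    return DifferentialExpressionModel(matrix, groups, group_order=group_order).fit(
        **fit_kwargs
    )


def volcano_table(
    results: pd.DataFrame, fc_cut: float = 1.5, q_cut: float = 0.05
) -> pd.DataFrame:
    """Classify entries for the volcano view.

    ``significant``: q strictly below ``q_cut``; ``high_fc``: linear fold
    magnitude strictly above ``fc_cut``; ``both``: their conjunction.
    Annotation (plasma/rbc/other) is carried through.
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    out = results.copy()
    out["significant"] = out["q"] < q_cut
    out["high_fc"] = out["linear_fc"].abs() > fc_cut
    out["both"] = out["significant"] & out["high_fc"]
    return out
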