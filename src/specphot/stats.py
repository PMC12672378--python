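"""Statistical tests for photometry epoch summaries.

Three designs, matching how dose-response and paired-sensor summaries are
analysed in this kind of experiment:

* within-subject (repeated-measures) one-way ANOVA followed by Dunnett's
  each-vs-control multiple comparisons, for the intensity dose-response;
* paired two-tailed t-test, for simultaneous glutamate-vs-GABA recordings;
* between-groups one-way ANOVA followed by Tukey's HSD, for independent
  treatment groups (e.g. vehicle / chemogenetic / electrical conditions).

The repeated-measures sum-of-squares partition is computed in closed form
here.  Dunnett adjusted p-values use the equicorrelated multivariate-t
formulation: with a common control and balanced cells the comparison
t-statistics are equicorrelated at rho = 1/2, and the adjusted p-value is
P(max_j |T_j| >= |t_i|), evaluated by a seeded Monte-Carlo draw from that
multivariate t (exact quantiles have no simple closed form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "Comparison",
    "rm_anova_dunnett",
    "paired_t",
    "oneway_anova_tukey",
    "dunnett_adjust",
]


@dataclass(frozen=True)
class Comparison:
    """One post hoc comparison with raw and adjusted p-values."""

    label: str
    estimate: float
    statistic: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class StatResult:
    """Omnibus test result plus labeled post hoc comparisons."""

    test: str
    statistic: float
    df: tuple
    p_value: float
    comparisons: list = field(default_factory=list)
    alpha: float = 0.05
    flags: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        for c in self.comparisons:
            if c.p_adjusted < c.p_unadjusted - 1e-12:
                raise ValueError("adjusted p below unadjusted p")

    def summary(self) -> str:
        df = "/".join(f"{d:g}" for d in self.df)
        lines = [
            f"{self.test}: statistic = {self.statistic:.4f}, "
            f"df = {df}, p = {self.p_value:.4g}"
        ]
        for c in self.comparisons:
            lines.append(
                f"  {c.label:<28s} estimate = {c.estimate:>9.4f}  "
                f"t = {c.statistic:>8.4f}  p = {c.p_unadjusted:.4g}  "
                f"p_adj = {c.p_adjusted:.4g}"
            )
        for f in self.flags:
            lines.append(f"  note: {f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "alpha": self.alpha,
            "flags": list(self.flags),
            "comparisons": [vars(c).copy() for c in self.comparisons],
            **{k: v for k, v in self.extras.items()},
        }


def _as_table(table) -> tuple[np.ndarray, list]:
    if isinstance(table, pd.DataFrame):
        X = table.to_numpy(dtype=float)
        cols = [str(c) for c in table.columns]
    else:
        X = np.asarray(table, dtype=float)
        cols = [f"cond{j}" for j in range(X.shape[1])]
    if X.ndim != 2:
        raise ValueError("table must be subjects x conditions")
    if np.any(~np.isfinite(X)):
        raise ValueError("table has missing cells")
    return X, cols


def dunnett_adjust(
    t_stats: np.ndarray, df_error: int, n_mc: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Two-sided Dunnett adjusted p-values for each-vs-control t statistics.

    Monte-Carlo evaluation of P(max_j |T_j| >= |t_i|) under the
    equicorrelated (rho = 1/2) multivariate t with ``df_error`` degrees of
    freedom; deterministic for a fixed seed.
    """
    t_stats = np.atleast_1d(np.asarray(t_stats, dtype=float))
    k = t_stats.size
    rng = np.random.default_rng(seed)
    # rho = 1/2 equicorrelated normals via a shared factor
    z0 = rng.standard_normal(n_mc)[:, None]
    z = rng.standard_normal((n_mc, k))
    x = (z0 + z) / np.sqrt(2.0)
    s = np.sqrt(rng.chisquare(df_error, n_mc) / df_error)[:, None]
    max_abs_t = np.max(np.abs(x / s), axis=1)
    p_adj = np.array(
        [np.mean(max_abs_t >= abs(t)) for t in t_stats], dtype=float
    )
    # MC estimate can undercut the raw p for extreme t; enforce monotonicity
    p_raw = 2.0 * sps.t.sf(np.abs(t_stats), df_error)
    return np.maximum(p_adj, p_raw)


def rm_anova_dunnett(
    table,
    control: int | str = 0,
    alpha: float = 0.05,
    comparisons: bool = True,
    sequential: bool = True,
    greenhouse_geisser: bool = False,
    n_mc: int = 100_000,
    seed: int = 0,
) -> StatResult:
    """Within-subjects one-way ANOVA with Dunnett each-vs-control post hocs.

    ``table`` is subjects x conditions (complete, >= 3 subjects, >= 2
    conditions); ``control`` is the column (index or name) every other
    condition is compared against.  A ``sequential`` report of successive
    condition pairs (paired t-tests, labeled, unadjusted) is also emitted,
    since dose-response figures are often annotated with those instead.
    No sphericity correction is applied unless ``greenhouse_geisser``.
    """
    X, cols = _as_table(table)
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    if isinstance(control, str):
        control = cols.index(control)

    grand = X.mean()
    cond_means = X.mean(axis=0)
    subj_means = X.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        raise ValueError("zero residual variance; F undefined")
    F = ms_cond / ms_err

    eps = 1.0
    if greenhouse_geisser:
        S = np.cov(X, rowvar=False, ddof=1)
        p = S.shape[0]
        dbar = np.diag(S).mean()
        sbar = S.mean()
        num = (p * (dbar - sbar)) ** 2
        den = (p - 1) * (np.sum(S**2) - 2 * p * np.sum(S.mean(axis=1) ** 2)
                         + p**2 * sbar**2)
        eps = float(num / den) if den > 0 else 1.0
        eps = min(max(eps, 1.0 / (p - 1)), 1.0)
    p_value = float(sps.f.sf(F, df_cond * eps, df_err * eps))

    comps: list[Comparison] = []
    flags: list[str] = []
    if comparisons:
        se = np.sqrt(2.0 * ms_err / n)
        others = [j for j in range(k) if j != control]
        t_stats = np.array(
            [(cond_means[j] - cond_means[control]) / se for j in others]
        )
        p_adj = dunnett_adjust(t_stats, df_err, n_mc=n_mc, seed=seed)
        p_raw = 2.0 * sps.t.sf(np.abs(t_stats), df_err)
        for j, t_j, pr, pa in zip(others, t_stats, p_raw, p_adj):
            comps.append(
                Comparison(
                    label=f"{cols[j]} vs {cols[control]} (Dunnett)",
                    estimate=float(cond_means[j] - cond_means[control]),
                    statistic=float(t_j),
                    p_unadjusted=float(pr),
                    p_adjusted=float(pa),
                )
            )
    if sequential:
        for j in range(k - 1):
            d = X[:, j + 1] - X[:, j]
            res = paired_t(X[:, j + 1], X[:, j])
            comps.append(
                Comparison(
                    label=f"{cols[j]} vs {cols[j + 1]} (sequential, unadjusted)",
                    estimate=float(d.mean()),
                    statistic=res.statistic,
                    p_unadjusted=res.p_value,
                    p_adjusted=res.p_value,
                )
            )
        flags.append("sequential pairwise comparisons are unadjusted paired t-tests")
    if greenhouse_geisser:
        flags.append(f"Greenhouse-Geisser epsilon = {eps:.4f}")

    return StatResult(
        test="repeated-measures one-way ANOVA",
        statistic=float(F),
        df=(float(df_cond), float(df_err)),
        p_value=p_value,
        comparisons=comps,
        alpha=alpha,
        flags=flags,
        extras={
            "ss_condition": float(ss_cond),
            "ss_subject": float(ss_subj),
            "ss_error": float(ss_err),
            "n_subjects": n,
            "conditions": cols,
        },
    )


def paired_t(x, y, alpha: float = 0.05) -> StatResult:
    """Paired two-tailed t-test: t = mean(d) / (sd(d)/sqrt(n)), d = x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d (paired by subject)")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    flags = []
    if sd == 0.0:
        if d.mean() == 0.0:
            t, p = 0.0, 1.0
        else:
            t = np.inf if d.mean() > 0 else -np.inf
            p = 0.0
            flags.append("zero variance of differences with nonzero mean")
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return StatResult(
        test="paired two-tailed t-test",
        statistic=float(t),
        df=(float(n - 1),),
        p_value=float(p),
        alpha=alpha,
        flags=flags,
        extras={"mean_difference": float(d.mean()), "n": n},
    )


def oneway_anova_tukey(
    groups, labels=None, alpha: float = 0.05, comparisons: bool = True
) -> StatResult:
    """Between-groups one-way ANOVA with Tukey HSD all-pairs post hocs."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{j}" for j in range(len(groups))]
    F, p = sps.f_oneway(*groups)
    k = len(groups)
    N = sum(g.size for g in groups)
    comps: list[Comparison] = []
    if comparisons:
        tukey = sps.tukey_hsd(*groups)
        ms_within = sum(np.sum((g - g.mean()) ** 2) for g in groups) / (N - k)
        for i in range(k):
            for j in range(i + 1, k):
                diff = groups[i].mean() - groups[j].mean()
                se = np.sqrt(ms_within * (1 / groups[i].size + 1 / groups[j].size))
                t_ij = diff / se
                p_raw = float(2.0 * sps.t.sf(abs(t_ij), N - k))
                p_adj = float(max(tukey.pvalue[i, j], p_raw))
                comps.append(
                    Comparison(
                        label=f"{labels[i]} vs {labels[j]} (Tukey HSD)",
                        estimate=float(diff),
                        statistic=float(t_ij),
                        p_unadjusted=p_raw,
                        p_adjusted=p_adj,
                    )
                )
    return StatResult(
        test="one-way ANOVA",
        statistic=float(F),
        df=(float(k - 1), float(N - k)),
        p_value=float(p),
        comparisons=comps,
        alpha=alpha,
        extras={"group_means": [float(g.mean()) for g in groups],
                "labels": list(labels)},
    )
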