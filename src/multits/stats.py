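"""Model-comparison statistics: one-way ANOVA, Dunnett's many-to-one test
against a control, and paired t-tests.

Dunnett's procedure compares k treatment means against one control under a
pooled-variance model.  The k contrast statistics are jointly multivariate-t
distributed with correlation ``rho_ij = lam_i * lam_j`` where
``lam_j = sqrt(n_j / (n_j + n_0))``; two-sided adjusted p-values are tail
probabilities of ``max_j |T_j|`` under that joint null, evaluated here by
seeded Monte Carlo (default 200,000 draws) with the standard error of the
estimate reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sst

from .exceptions import DegenerateDataError, ParameterError

__all__ = ["AnovaResult", "DunnettComparison", "PairedTResult",
           "ComparisonReport", "one_way_anova", "dunnett_many_to_one",
           "dunnett_max_t_samples", "dunnett_critical_value", "paired_t",
           "compare_models"]


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


@dataclass
class DunnettComparison:
    name: str
    mean_diff: float
    t: float
    p_adj: float
    p_mc_se: float
    significant_05: bool
    significant_01: bool


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    if all(np.var(a) == 0 for a in arrays) and \
            len({float(a.mean()) for a in arrays}) == 1:
        raise DegenerateDataError(
            "zero within-group variance with equal means: F undefined")
    F, _ = sst.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    F = max(float(F), 0.0)  # guard the tiny negative F of identical groups
    p = float(sst.f.sf(F, k - 1, n - k))
    return AnovaResult(F=F, p=p, df_between=k - 1, df_within=n - k)


def _dunnett_setup(control, treatments):
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    if len(groups) < 1:
        raise ParameterError("need at least one treatment group")
    if len(control) < 2 or any(len(g) < 2 for g in groups):
        raise ParameterError("every group needs >= 2 values")
    all_groups = [control] + groups
    n = np.array([len(g) for g in all_groups])
    df = int(n.sum() - len(all_groups))
    sse = sum(((g - g.mean()) ** 2).sum() for g in all_groups)
    if sse == 0:
        raise DegenerateDataError("pooled within-group variance is zero")
    s2 = sse / df
    lam = np.sqrt(n[1:] / (n[1:] + n[0]))
    tstats = np.array([
        (g.mean() - control.mean()) / np.sqrt(s2 * (1 / len(g) + 1 / n[0]))
        for g in groups])
    return groups, tstats, lam, df


def dunnett_max_t_samples(lam: np.ndarray, df: int, n_mc: int,
                          seed: int) -> np.ndarray:
    """Monte Carlo draws of ``max_j |T_j|`` under the joint Dunnett null.

    Uses the one-factor structure ``T_j = (Z_j - lam_j * Z_0) /
    sqrt(1 - ... )``: with ``Z_0``, ``Z_j`` iid standard normal,
    ``lam_j Z_0 + sqrt(1 - lam_j^2) Z_j`` has the required correlation
    ``lam_i lam_j``; dividing by a shared ``sqrt(chi2_df / df)`` gives the
    multivariate t.
    """
    rng = np.random.default_rng(seed)
    k = len(lam)
    z0 = rng.standard_normal(n_mc)
    zj = rng.standard_normal((n_mc, k))
    corr = lam * z0[:, None] + np.sqrt(1 - lam ** 2) * zj
    chi = rng.chisquare(df, size=n_mc) / df
    t = corr / np.sqrt(chi)[:, None]
    return np.abs(t).max(axis=1)


def dunnett_critical_value(lam, df, alpha=0.05, n_mc=200_000,
                           seed=0) -> float:
    """Two-sided Dunnett critical value: the (1-alpha) quantile of
    ``max_j |T_j|`` under the joint null."""
    maxt = dunnett_max_t_samples(np.asarray(lam, dtype=float), df, n_mc, seed)
    return float(np.quantile(maxt, 1 - alpha))


def dunnett_many_to_one(control, treatments, alpha: float = 0.05,
                        n_mc: int = 200_000, seed: int = 0,
                        names: Optional[Sequence[str]] = None
                        ) -> list[DunnettComparison]:
    """Two-sided Dunnett comparisons of each treatment against the control.

    The adjusted p-value of treatment j is ``P(max_i |T_i| >= |t_j|)`` under
    the joint multivariate-t null, estimated by seeded Monte Carlo; the
    binomial standard error of each estimate is reported.
    """
    groups, tstats, lam, df = _dunnett_setup(control, treatments)
    maxt = dunnett_max_t_samples(lam, df, n_mc, seed)
    names = list(names) if names is not None else \
        [f"treatment{i}" for i in range(len(groups))]
    out = []
    control_mean = float(np.asarray(control, dtype=float).mean())
    for name, g, t in zip(names, groups, tstats):
        p = float(np.mean(maxt >= abs(t)))
        se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_mc))
        out.append(DunnettComparison(
            name=name, mean_diff=float(g.mean() - control_mean),
            t=float(t), p_adj=p, p_mc_se=se,
            significant_05=p < 0.05, significant_01=p < 0.01))
    return out


def paired_t(a, b) -> PairedTResult:
    """Two-sided paired t-test on a-b with df = n-1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ParameterError("paired_t needs equal-length vectors, n >= 2")
    d = a - b
    if np.var(d, ddof=1) == 0:
        raise DegenerateDataError("zero-variance differences: t undefined")
    res = sst.ttest_rel(a, b)
    return PairedTResult(t=float(res.statistic), df=len(a) - 1,
                         p=float(res.pvalue))


@dataclass
class ComparisonReport:
    """ANOVA + Dunnett results for several models against one control."""

    control: str
    anova: AnovaResult
    dunnett: list
    paired: dict = field(default_factory=dict)
    n_mc: int = 200_000
    seed: int = 0

    def render(self) -> str:
        lines = [
            f"one-way ANOVA: F({self.anova.df_between},"
            f"{self.anova.df_within}) = {self.anova.F:.3f}, "
            f"p = {self.anova.p:.4g}",
            f"Dunnett vs {self.control} (two-sided, Monte Carlo "
            f"{self.n_mc} draws, seed {self.seed}):",
        ]
        for c in self.dunnett:
            stars = "**" if c.significant_01 else \
                ("*" if c.significant_05 else "")
            lines.append(
                f"  {c.name:<20s} diff={c.mean_diff:+.4f}  t={c.t:+.3f}  "
                f"p_adj={c.p_adj:.4f} (±{c.p_mc_se:.4f}) {stars}")
        for pair, res in self.paired.items():
            note = "  [degenerate: zero-variance differences]" \
                if res.degenerate else ""
            lines.append(
                f"paired t {pair}: t({res.df}) = {res.t:+.3f}, "
                f"p = {res.p:.4g}{note}")
        lines.append("(* p<0.05, ** p<0.01)")
        return "\n".join(lines)


def compare_models(accuracies: dict, control: str, alpha: float = 0.05,
                   n_mc: int = 200_000, seed: int = 0,
                   paired_pairs: Optional[Sequence[tuple]] = None
                   ) -> ComparisonReport:
    """Build a full report from ``{model_name: accuracy_vector}``."""
    if control not in accuracies:
        raise ParameterError(f"control {control!r} not among models")
    names = [k for k in accuracies if k != control]
    anova = one_way_anova([accuracies[control]] + [accuracies[k]
                                                   for k in names])
    dunnett = dunnett_many_to_one(
        accuracies[control], [accuracies[k] for k in names],
        alpha=alpha, n_mc=n_mc, seed=seed, names=names)
    paired = {}
    for a, b in (paired_pairs or []):
        try:
            paired[f"{a} vs {b}"] = paired_t(accuracies[a], accuracies[b])
        except DegenerateDataError:
            paired[f"{a} vs {b}"] = PairedTResult(
                t=0.0, df=len(accuracies[a]) - 1, p=1.0, degenerate=True)
    return ComparisonReport(control=control, anova=anova, dunnett=dunnett,
                            paired=paired, n_mc=n_mc, seed=seed)
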