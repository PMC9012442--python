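"""The study's statistical workflow on paired kinematic measurements.

Normality of paired differences is gated by Shapiro-Wilk: normal-looking
differences go to a paired t-test and are summarised as mean +- sd,
non-normal ones to a Wilcoxon signed-rank test summarised as median (range).
Per-vertebral-space effects use a two-way repeated-measures ANOVA (space x
surgical condition, subjects = specimens) with Tukey HSD post-hocs, and
power calculations use the noncentral-t distribution of the paired test.
Significance is p <= 0.05 throughout.

The test statistics themselves are delegated to scipy / pingouin /
statsmodels; the bespoke content is the gating, pairing and reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TestResult",
    "normality_gate",
    "paired_compare",
    "rm_anova_spaces",
    "power_paired",
]

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


@dataclass(frozen=True)
class PairedSample:
    """Per-specimen (pre, post) values of one metric."""

    metric: str
    pre: np.ndarray
    post: np.ndarray
    units: str = "mm"

    def __post_init__(self):
        pre = np.asarray(self.pre, dtype=float).reshape(-1)
        post = np.asarray(self.post, dtype=float).reshape(-1)
        if pre.shape != post.shape:
            raise ValueError("pre and post must pair up one-to-one")
        if np.any(~np.isfinite(pre)) or np.any(~np.isfinite(post)):
            raise ValueError("missing or non-finite values in paired sample")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)

    @property
    def differences(self) -> np.ndarray:
        return self.post - self.pre


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    effect_size: float  # standardized mean paired difference (d_z)
    route: str
    summary_pre: str
    summary_post: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _mean_sd(x: np.ndarray) -> str:
    sd = np.std(x, ddof=1) if len(x) > 1 else 0.0
    return f"{np.mean(x):.1f} ± {sd:.1f}"


def _median_range(x: np.ndarray) -> str:
    return f"{np.median(x):.1f} ({np.min(x):.1f}–{np.max(x):.1f})"


def normality_gate(differences, alpha: float = 0.05) -> str:
    """Shapiro-Wilk on paired differences: "parametric" iff p > alpha."""
    d = np.asarray(differences, dtype=float).reshape(-1)
    if len(d) < 3:
        raise ValueError("normality gate needs at least 3 differences")
    if np.ptp(d) == 0:
        warnings.warn("constant differences: Shapiro-Wilk undefined, routing nonparametric")
        return NONPARAMETRIC
    p = sps.shapiro(d).pvalue
    return PARAMETRIC if p > alpha else NONPARAMETRIC


def paired_compare(sample: PairedSample, alpha: float = 0.05) -> TestResult:
    """Pre/post comparison routed through the normality gate."""
    d = sample.differences
    if len(d) < 3:
        raise ValueError("paired comparison needs at least 3 pairs")
    if np.all(d == 0):
        warnings.warn(f"{sample.metric}: pre and post identical; no test performed")
        return TestResult(
            test="degenerate",
            statistic=0.0,
            p_value=1.0,
            effect_size=0.0,
            route=NONPARAMETRIC,
            summary_pre=_mean_sd(sample.pre),
            summary_post=_mean_sd(sample.post),
        )
    route = normality_gate(d, alpha=alpha)
    sd = np.std(d, ddof=1)
    dz = float(np.mean(d) / sd) if sd > 0 else np.inf * np.sign(np.mean(d))
    if route == PARAMETRIC:
        res = sps.ttest_rel(sample.post, sample.pre)
        return TestResult(
            test="paired t-test",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            effect_size=dz,
            route=route,
            summary_pre=_mean_sd(sample.pre),
            summary_post=_mean_sd(sample.post),
        )
    nz = d[d != 0]  # Wilcoxon convention: zero differences dropped
    method = "exact" if len(nz) <= 25 else "approx"
    res = sps.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return TestResult(
        test="wilcoxon signed-rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=dz,
        route=route,
        summary_pre=_median_range(sample.pre),
        summary_post=_median_range(sample.post),
    )


def rm_anova_spaces(
    records: pd.DataFrame,
    dv: str = "value",
    subject: str = "specimen",
    space: str = "space",
    condition: str = "condition",
) -> dict:
    """Two-way repeated-measures ANOVA (space x condition) + Tukey post-hocs.

    Requires a complete balanced table: one value per (subject, space,
    condition) cell — no imputation is attempted.  The ANOVA table includes
    the Greenhouse-Geisser corrected p-values for the multi-level space
    factor; Tukey HSD is run on each factor's levels pooling over the other.
    """
    import pingouin as pg
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    for col in (dv, subject, space, condition):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    counts = records.groupby([subject, space, condition], observed=True)[dv].count()
    if (counts != 1).any() or len(counts) != (
        records[subject].nunique()
        * records[space].nunique()
        * records[condition].nunique()
    ):
        raise ValueError("unbalanced or incomplete table: need one value per cell")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = pg.rm_anova(
            data=records, dv=dv, within=[space, condition], subject=subject,
            detailed=True,
        )
    tukey = {}
    for factor in (space, condition):
        res = pairwise_tukeyhsd(records[dv].to_numpy(), records[factor].to_numpy())
        tukey[factor] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return {"anova": anova, "tukey": tukey}


def power_paired(
    effect_size_d: float,
    n: int | None = None,
    power: float | None = None,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> float | int:
    """Noncentral-t power of the paired t-test; returns the missing quantity.

    With ``n`` given, returns the achieved power; with ``power`` given,
    returns the smallest integer sample size reaching it.
    """
    if (n is None) == (power is None):
        raise ValueError("exactly one of n and power must be provided")
    d = float(effect_size_d)

    def achieved(nn: float) -> float:
        df = nn - 1
        nc = abs(d) * np.sqrt(nn)
        if two_sided:
            tcrit = sps.t.isf(alpha / 2, df)
            return float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
        tcrit = sps.t.isf(alpha, df)
        return float(1 - sps.nct.cdf(tcrit, df, nc))

    if power is None:
        if n < 2:
            raise ValueError("n must be at least 2")
        return achieved(n)
    if not 0 < power < 1:
        raise ValueError("target power must be in (0, 1)")
    if d == 0:
        raise ValueError("zero effect size can never reach the target power")
    lo, hi = 2, 4
    while achieved(hi) < power:
        lo, hi = hi, hi * 2
        if hi > 1e9:
            raise RuntimeError("required sample size exceeds 1e9")
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(lo)
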