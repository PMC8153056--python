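"""Interbeat-interval and heart-rate-variability statistics.

Post-omission cardiac dynamics are summarized as the first and second
interbeat intervals after each omission ("omission to 1", "1 to 2"),
analyzed with repeated-measures ANOVAs over the attention x delay x
interval-position design, followed by post-hoc paired tests (switching to
the Wilcoxon signed-rank test when normality of the paired differences is
rejected) and default Bayes factors: the JZS Cauchy-prior Bayes factor for
t-tests and the stretched-beta-prior Bayes factor for Pearson
correlations, both by adaptive quadrature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy.stats import (cauchy, beta as beta_dist, f as f_dist, nct,
                         shapiro, t as t_dist, ttest_rel, wilcoxon)

from .cardiac_events import compute_ibis


def sdrr(ibis) -> float:
    """Standard deviation of interbeat intervals (sample SD, n-1), in ms."""
    x = np.asarray(ibis, dtype=float)
    if x.size < 2:
        raise ValueError("SDRR needs at least 2 interbeat intervals")
    return float(np.std(x, ddof=1))


def omission_ibi_table(
    events: pd.DataFrame,
    rpeaks: np.ndarray,
    subject: Optional[str] = None,
) -> pd.DataFrame:
    """Long-format post-omission IBI table for factorial analysis.

    For every omission event, the interval from the triggering R-peak to
    the next beat is "omission to 1", the following one is "1 to 2", and
    the interval ending at the trigger is "baseline".  Values are averaged
    per attention x delay cell so the result has one row per cell x
    position; omissions whose post-beats were never detected are counted in
    the ``n_missing`` column.
    """
    omissions = events[events["kind"] == "omission"]
    rows = []
    for (att, dly), grp in omissions.groupby(["attention", "delay"]):
        labeled = compute_ibis(rpeaks, grp)
        t = np.asarray(rpeaks, dtype=float)
        base_vals = []
        for onset in grp["onset_s"]:
            k = int(np.searchsorted(t, onset + 1e-9) - 1)
            if k >= 1:
                base_vals.append((t[k] - t[k - 1]) * 1e3)
        for pos, vals_src in (
            ("omission to 1", labeled.loc[labeled["label"] == "omission to 1"]),
            ("1 to 2", labeled.loc[labeled["label"] == "1 to 2"]),
        ):
            good = vals_src.loc[~vals_src["missing"], "ibi_ms"]
            rows.append({
                "subject": subject, "attention": att, "delay": dly,
                "position": pos,
                "ibi_ms": float(good.mean()) if len(good) else np.nan,
                "n": int(len(good)),
                "n_missing": int(vals_src["missing"].sum()),
            })
        rows.append({
            "subject": subject, "attention": att, "delay": dly,
            "position": "baseline",
            "ibi_ms": float(np.mean(base_vals)) if base_vals else np.nan,
            "n": len(base_vals), "n_missing": 0,
        })
    return pd.DataFrame(rows)


def partial_eta_squared(F: float, df_effect: float, df_error: float) -> float:
    """partial eta^2 = F * df_eff / (F * df_eff + df_err)."""
    return float(F * df_effect / (F * df_effect + df_error))


def rm_anova(table: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject") -> pd.DataFrame:
    """Repeated-measures ANOVA for fully-within designs with 2-level factors.

    Every main effect and interaction of 2-level within-subject factors has
    one numerator degree of freedom, so each is equivalent to a one-sample
    t-test on the per-subject contrast scores (F = t^2).  Returns one row
    per effect with F, df, partial eta^2 and p.  Cells are averaged within
    subject first; a missing cell raises.
    """
    levels = {f: sorted(table[f].unique()) for f in within}
    for f, lv in levels.items():
        if len(lv) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels")
    cellmeans = table.groupby([subject] + within, observed=True)[dv].mean().unstack(within)
    if cellmeans.isna().any().any():
        raise ValueError("missing cells in the within-subject design")
    n = len(cellmeans)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    cols = cellmeans.columns          # MultiIndex (or Index) over cells
    results = []
    for k in range(1, len(within) + 1):
        for effect in itertools.combinations(within, k):
            w = np.ones(len(cols))
            for i, cell in enumerate(cols):
                cell = (cell,) if not isinstance(cell, tuple) else cell
                for f in effect:
                    lv = cell[within.index(f)]
                    w[i] *= 1.0 if lv == levels[f][0] else -1.0
            # average of +cells minus average of -cells per subject
            scores = (cellmeans.to_numpy() * w).sum(axis=1) / (len(cols) / 2)
            m, sd = scores.mean(), scores.std(ddof=1)
            tval = m / (sd / np.sqrt(n)) if sd > 0 else 0.0
            F = tval ** 2
            df1, df2 = 1, n - 1
            results.append({
                "effect": " * ".join(effect), "F": F, "df1": df1, "df2": df2,
                "partial_eta2": partial_eta_squared(F, df1, df2),
                "p": float(f_dist.sf(F, df1, df2)),
            })
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# default Bayes factors

def jzs_bf10_ttest(t: float, n: int, n2: Optional[int] = None,
                   design: str = "one-sample", rscale: float = 0.707) -> float:
    """Default JZS Bayes factor for a t statistic.

    The alternative places a Cauchy(0, ``rscale``) prior on the
    standardized effect size; BF10 is the ratio of the marginal likelihood
    of ``t`` under that prior (noncentral-t mixture, adaptive quadrature)
    to its likelihood under the point null.  ``design`` "one-sample" and
    "paired" use df = n - 1 and effective size n; "independent" uses
    df = n + n2 - 2 and effective size n*n2/(n + n2).
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if design in ("one-sample", "paired"):
        if n < 2:
            raise ValueError("need n >= 2")
        df, neff = n - 1, float(n)
    elif design == "independent":
        if n2 is None or min(n, n2) < 2:
            raise ValueError("independent design needs two group sizes >= 2")
        df, neff = n + n2 - 2, n * n2 / (n + n2)
    else:
        raise ValueError(f"unknown design {design!r}")
    sq = np.sqrt(neff)

    def integrand(d):
        return nct.pdf(t, df, d * sq) * cauchy.pdf(d, 0.0, rscale)

    num, err = integrate.quad(integrand, -20, 20, points=[0.0, t / sq],
                              limit=400, epsabs=1e-12, epsrel=1e-9)
    den = t_dist.pdf(t, df)
    if not np.isfinite(num) or err > max(1e-8, 1e-5 * num):
        raise RuntimeError("Bayes factor integration failed")
    return float(num / den)


def _corr_log_density(r: float, rho: float, n: int) -> float:
    """Exact log density of the sample Pearson correlation given rho."""
    lognorm = (np.log(n - 2) + special.gammaln(n - 1)
               - 0.5 * np.log(2 * np.pi) - special.gammaln(n - 0.5))
    core = ((n - 1) / 2 * np.log1p(-rho ** 2)
            + (n - 4) / 2 * np.log1p(-r ** 2)
            - (n - 1.5) * np.log1p(-rho * r))
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)
    return lognorm + core + np.log(hyp)


def corr_bf10(r: float, n: int, kappa: float = 1.0) -> float:
    """Two-sided default Bayes factor for a Pearson correlation.

    The alternative places a stretched beta(1/kappa, 1/kappa) prior on rho
    over (-1, 1); kappa = 1 is the uniform prior.  Computed by adaptive
    quadrature of the exact sampling density of r.
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    a = 1.0 / kappa
    den = np.exp(_corr_log_density(r, 0.0, n))

    def integrand(rho):
        prior = beta_dist.pdf((rho + 1) / 2, a, a) / 2
        return np.exp(_corr_log_density(r, rho, n)) * prior

    num, err = integrate.quad(integrand, -1, 1, points=[r], limit=400,
                              epsabs=1e-12, epsrel=1e-9)
    if not np.isfinite(num) or err > max(1e-8, 1e-5 * num):
        raise RuntimeError("Bayes factor integration failed")
    return float(num / den)


# ---------------------------------------------------------------------------
# post-hoc tests

@dataclass
class PosthocResult:
    test: str                  # "t" | "wilcoxon": the selected branch
    statistic: float
    p: float
    bf10: float
    t_statistic: float
    t_p: float
    w_statistic: Optional[float]
    w_p: Optional[float]
    normality_p: float


def posthoc_pair(x, y, alpha_normality: float = 0.05) -> PosthocResult:
    """Paired comparison with automatic nonparametric fallback.

    A paired t-test is the default; when the Shapiro-Wilk test rejects
    normality of the paired differences at ``alpha_normality`` the Wilcoxon
    signed-rank test is selected instead.  Both statistics are reported,
    along with the JZS Bayes factor computed from the t statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length paired samples of size >= 3")
    d = x - y
    n = d.size
    if np.all(d == 0):
        return PosthocResult("t", 0.0, 1.0, jzs_bf10_ttest(0.0, n, design="paired"),
                             0.0, 1.0, None, None, 1.0)
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance paired differences")
    tstat, tp = ttest_rel(x, y)
    sw_p = float(shapiro(d).pvalue)
    wstat = wp = None
    use_wilcoxon = sw_p < alpha_normality
    if use_wilcoxon:
        res = wilcoxon(x, y)
        wstat, wp = float(res.statistic), float(res.pvalue)
    bf = jzs_bf10_ttest(float(tstat), n, design="paired")
    if use_wilcoxon:
        return PosthocResult("wilcoxon", wstat, wp, bf, float(tstat), float(tp),
                             wstat, wp, sw_p)
    return PosthocResult("t", float(tstat), float(tp), bf, float(tstat),
                         float(tp), None, None, sw_p)
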