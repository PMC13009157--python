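"""Group comparisons for step, posture, and phase statistics.

Three tests cover everything the pipeline reports: a linear mixed-effects
model with fly identity as a random intercept (repeated measures within
flies), a Welch two-sided t-test on per-fly means, and a two-sample Kuiper
test for circular phase samples — each with an explicit Bonferroni factor
applied to the significance threshold (decision at alpha / m).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("hairplate")


@dataclass
class ComparisonResult:
    test: str
    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    pvalue: float
    bonferroni_m: int = 1
    alpha: float = 0.05
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha / self.bonferroni_m

    def to_dict(self) -> dict:
        return {
            "test": self.test, "estimate": self.estimate,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "statistic": self.statistic, "pvalue": self.pvalue,
            "bonferroni_m": self.bonferroni_m, "alpha": self.alpha,
            "significant": self.significant, "note": self.note,
        }


def lmm_group_compare(
    values, group, fly_id, alpha: float = 0.05, bonferroni_m: int = 1
) -> ComparisonResult:
    """Two-group comparison with fly as a random intercept.

    Fits value = b0 + b1 * group + u_fly + eps by REML (statsmodels
    MixedLM) and reports the Wald estimate, CI and p-value for b1. The
    reference level is "control" if present, otherwise the first level in
    sorted order. If every fly contributes a single observation the random
    intercept is unidentifiable and the comparison degrades to a Welch
    t-test on the per-fly values (noted in the result).
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "group": np.asarray(group).astype(str),
        "fly": np.asarray(fly_id).astype(str),
    })
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    ref = "control" if "control" in levels else levels[0]
    other = [l for l in levels if l != ref][0]
    for l in levels:
        if df.loc[df["group"] == l, "fly"].nunique() < 2:
            raise ValueError(f"group {l!r} has fewer than 2 flies")
    df["g"] = (df["group"] == other).astype(float)

    if df.groupby("fly")["value"].count().max() == 1:
        a = df.loc[df["g"] == 0, "value"].to_numpy()
        b = df.loc[df["g"] == 1, "value"].to_numpy()
        log.warning(
            "lmm_group_compare: one observation per fly; degrading to a "
            "Welch t-test on per-fly values"
        )
        res = ttest_bonferroni(b, a, m=bonferroni_m, alpha=alpha)
        res.test = "lmm_degraded_ttest"
        res.note = "single observation per fly; random intercept unidentifiable"
        return res

    import statsmodels.api as sm

    exog = sm.add_constant(df["g"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df["value"].to_numpy(), exog, groups=df["fly"].to_numpy())
        fit = model.fit(reml=True)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = beta / se if se > 0 else np.inf
    # the group contrast is a between-fly effect: reference the Wald
    # statistic against t with (number of flies - 2) df, not the normal
    dof = max(df["fly"].nunique() - 2, 1)
    p = float(2 * sps.t.sf(abs(z), dof))
    tcrit = float(sps.t.ppf(0.975, dof))
    return ComparisonResult(
        test="lmm_random_intercept", estimate=beta,
        ci_low=beta - tcrit * se, ci_high=beta + tcrit * se,
        statistic=z, pvalue=p, bonferroni_m=bonferroni_m, alpha=alpha,
        note=f"Wald t inference ({dof} df); reference level {ref!r}",
    )


def ttest_bonferroni(
    a, b, m: int = 1, alpha: float = 0.05
) -> ComparisonResult:
    """Welch two-sided t-test on per-fly means, decided at alpha / m."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 flies")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    est = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    se = math.sqrt(va + vb)
    if se > 0:
        dof = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        tcrit = sps.t.ppf(0.975, dof)
    else:
        tcrit = 0.0
    return ComparisonResult(
        test="welch_ttest", estimate=est,
        ci_low=est - tcrit * se, ci_high=est + tcrit * se,
        statistic=float(t), pvalue=float(p), bonferroni_m=m, alpha=alpha,
    )


def kuiper_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Kuiper statistic V = D+ + D- over the empirical CDFs.

    V is invariant under any common circular rotation of both samples,
    which is what makes it the right test for step-cycle phases.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pts = np.concatenate([x, y])
    fx = np.searchsorted(x, pts, side="right") / len(x)
    fy = np.searchsorted(y, pts, side="right") / len(y)
    d = fx - fy
    return float(d.max() - d.min())


def _kuiper_pvalue_asymptotic(v: float, n_eff: float, tol: float = 1e-10) -> float:
    lam = (math.sqrt(n_eff) + 0.155 + 0.24 / math.sqrt(n_eff)) * v
    if lam < 0.4:
        return 1.0
    p = 0.0
    for j in range(1, 200):
        a = 2.0 * j * j * lam * lam
        term = 2.0 * (2.0 * a - 1.0) * math.exp(-a)
        p += term
        if abs(term) < tol:
            break
    return float(min(max(p, 0.0), 1.0))


def kuiper_two_sample(
    x,
    y,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
    method: str = "asymptotic",
    n_perm: int = 9999,
    seed: int = 0,
    enumerate_limit: int = 200_000,
) -> ComparisonResult:
    """Two-sided two-sample Kuiper test for circular samples in [0, 1).

    The asymptotic p-value uses the Kuiper tail series with the
    Stephens small-sample correction at the effective size
    n_e = n*m/(n+m). method="permutation" uses the permutation null
    instead: all distinct splits when their number is at most
    ``enumerate_limit``, otherwise ``n_perm`` seeded random permutations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("need at least 5 samples per side")
    v = kuiper_statistic(x, y)
    n, m = len(x), len(y)
    n_eff = n * m / (n + m)
    if method == "asymptotic":
        p = _kuiper_pvalue_asymptotic(v, n_eff)
        note = "asymptotic series, Stephens correction"
    elif method == "permutation":
        pooled = np.concatenate([x, y])
        total = math.comb(n + m, n)
        if total <= enumerate_limit:
            ge = 0
            for comb_idx in combinations(range(n + m), n):
                sel = np.zeros(n + m, dtype=bool)
                sel[list(comb_idx)] = True
                if kuiper_statistic(pooled[sel], pooled[~sel]) >= v - 1e-12:
                    ge += 1
            p = ge / total
            note = f"exact permutation over {total} splits"
        else:
            rng = np.random.default_rng(seed)
            ge = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                if kuiper_statistic(perm[:n], perm[n:]) >= v - 1e-12:
                    ge += 1
            p = (ge + 1) / (n_perm + 1)
            note = f"Monte-Carlo permutation, {n_perm} draws, seed {seed}"
    else:
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return ComparisonResult(
        test="kuiper_two_sample", estimate=v, ci_low=np.nan, ci_high=np.nan,
        statistic=v, pvalue=float(p), bonferroni_m=bonferroni_m, alpha=alpha,
        note=note,
    )
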