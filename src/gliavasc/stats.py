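"""Statistical layer of the study.

Normality is screened with Shapiro-Wilk; two-group comparisons use the
two-tailed Welch t-test (unequal variances); rodent group-by-age designs
use a two-way ANOVA (partial, Type-III-style sums of squares with
sum-to-zero coding) followed by Holm-Sidak step-down adjusted pairwise
comparisons; feature-marker association matrices use Spearman's rank
correlation; qPCR expression is summarized with the comparative 2^-ddCt
method against a reference gene and a control group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "shapiro_normality",
    "welch_t",
    "holm_sidak",
    "anova2_holm_sidak",
    "spearman_matrix",
    "ddct_fold_change",
]


@dataclass
class StatsResult:
    test: str
    statistic: float
    df: float | tuple | None
    p: float
    p_adjusted: float | None = None
    comparison: str | None = None


def shapiro_normality(values) -> StatsResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no distribution to test")
    w, p = sps.shapiro(x)
    return StatsResult(test="shapiro", statistic=float(w), df=None, p=float(p))


def welch_t(x, y) -> StatsResult:
    """Two-tailed Welch t-test with Welch-Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # identical constant groups: no evidence of any difference
            return StatsResult(test="welch_t", statistic=0.0, df=float(x.size + y.size - 2), p=1.0)
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=False)
    return StatsResult(
        test="welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Raw p-values are sorted ascending; the i-th (1-based) gets
    ``1 - (1 - p_(i))^(m - i + 1)``, enforced non-decreasing along the
    sequence and capped at 1; adjusted values are returned in the original
    order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        a = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, a)
        adj[idx] = min(running, 1.0)
    return adj


def _anova2_table(df: pd.DataFrame, value: str, factor_a: str, factor_b: str):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols(
        f"Q('{value}') ~ C(Q('{factor_a}'), Sum) * C(Q('{factor_b}'), Sum)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=3)
    return model, table


def anova2_holm_sidak(
    data: pd.DataFrame,
    value: str,
    factor_group: str,
    factor_age: str,
    posthoc: str = "cells",
) -> list[StatsResult]:
    """Two-way ANOVA (group x age) with Holm-Sidak pairwise post hoc tests.

    Main effects and the interaction use partial (Type-III-style) sums of
    squares with sum-to-zero factor coding, so unbalanced layouts are
    handled.  Post hoc comparisons (``posthoc='cells'``: all pairwise
    group-x-age cell comparisons; ``'group'`` / ``'age'``: marginal level
    comparisons) use t statistics on the pooled residual mean square and a
    Holm-Sidak family adjustment.
    """
    for f in (factor_group, factor_age):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    model, table = _anova2_table(data, value, factor_group, factor_age)
    results = []
    name_map = {
        f"C(Q('{factor_group}'), Sum)": factor_group,
        f"C(Q('{factor_age}'), Sum)": factor_age,
        f"C(Q('{factor_group}'), Sum):C(Q('{factor_age}'), Sum)": f"{factor_group}:{factor_age}",
    }
    for row, pretty in name_map.items():
        results.append(
            StatsResult(
                test="anova2",
                statistic=float(table.loc[row, "F"]),
                df=(float(table.loc[row, "df"]), float(table.loc["Residual", "df"])),
                p=float(table.loc[row, "PR(>F)"]),
                comparison=pretty,
            )
        )

    mse = float(model.mse_resid)
    df_resid = float(model.df_resid)
    if posthoc == "cells":
        strata = data.groupby([factor_group, factor_age])[value]
        labels = {f"{g}/{a}": v.to_numpy(dtype=float) for (g, a), v in strata}
    else:
        factor = factor_group if posthoc == "group" else factor_age
        labels = {
            str(lv): data.loc[data[factor] == lv, value].to_numpy(dtype=float)
            for lv in sorted(data[factor].unique())
        }
    pairs = list(itertools.combinations(sorted(labels), 2))
    raw = []
    stats_ = []
    for a, b in pairs:
        xa, xb = labels[a], labels[b]
        se = math.sqrt(mse * (1.0 / len(xa) + 1.0 / len(xb)))
        t = (xa.mean() - xb.mean()) / se
        p = 2.0 * sps.t.sf(abs(t), df_resid)
        raw.append(p)
        stats_.append(t)
    adjusted = holm_sidak(raw) if raw else np.array([])
    for (a, b), t, p, padj in zip(pairs, stats_, raw, adjusted):
        results.append(
            StatsResult(
                test="holm_sidak_t",
                statistic=float(t),
                df=df_resid,
                p=float(p),
                p_adjusted=float(padj),
                comparison=f"{a} vs {b}",
            )
        )
    return results


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho at small n.

    Enumerates every permutation of the y ranks; the tie structure of both
    margins is preserved by permuting the observed (average) ranks
    themselves.
    """
    n = xr.size
    perms = np.array(list(itertools.permutations(yr)))
    xc = xr - xr.mean()
    yc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    rhos = (yc @ xc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_matrix(
    x: pd.DataFrame,
    y: pd.DataFrame | None = None,
    exact_max_n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p matrices between column sets.

    Average ranks handle ties.  With ``y=None`` the square matrix over
    ``x``'s columns is returned (symmetric, unit diagonal).  p-values use
    the t-approximation for n > ``exact_max_n`` and exact permutation
    enumeration otherwise.  Constant columns give missing entries.
    """
    x = pd.DataFrame(x)
    y = x if y is None else pd.DataFrame(y)
    if len(x) != len(y):
        raise ValueError("column sets must be observed on the same samples")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    rho = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    pm = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    for cx in x.columns:
        for cy in y.columns:
            a = x[cx].to_numpy(dtype=float)
            b = y[cy].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue  # leave NaN
            ar = sps.rankdata(a)
            br = sps.rankdata(b)
            r = float(np.corrcoef(ar, br)[0, 1])
            rho.loc[cx, cy] = r
            if cx is cy or (y is x and cx == cy):
                pm.loc[cx, cy] = 0.0
                continue
            if n <= exact_max_n:
                pm.loc[cx, cy] = _spearman_exact_p(ar, br, r)
            else:
                if abs(r) >= 1.0:
                    pm.loc[cx, cy] = 0.0
                else:
                    t = r * math.sqrt((n - 2) / (1.0 - r**2))
                    pm.loc[cx, cy] = 2.0 * sps.t.sf(abs(t), n - 2)
    return rho, pm


def ddct_fold_change(
    qpcr: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
    sample_col: str = "sample_id",
    group_col: str = "group",
    gene_col: str = "gene",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """Per-sample relative expression by the comparative 2^-ddCt method.

    Replicate Ct values are averaged per sample and gene; dCt is the
    target-minus-reference mean Ct per sample; ddCt subtracts the mean dCt
    of the control group; fold change is 2^-ddCt (control-group mean fold
    is 1 by construction when control dCt values are identical).
    """
    ct = pd.to_numeric(qpcr[ct_col])
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    mean_ct = (
        qpcr.assign(**{ct_col: ct})
        .groupby([sample_col, group_col, gene_col])[ct_col]
        .mean()
        .unstack(gene_col)
    )
    for gene in (target_gene, reference_gene):
        if gene not in mean_ct.columns or mean_ct[gene].isna().any():
            raise ValueError(f"gene {gene!r} missing for some samples")
    dct = mean_ct[target_gene] - mean_ct[reference_gene]
    out = dct.reset_index()
    out.columns = [sample_col, group_col, "dct"]
    control = out.loc[out[group_col] == control_group, "dct"]
    if control.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    out["ddct"] = out["dct"] - control.mean()
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out
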