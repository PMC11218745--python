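"""Group-level inference: paired t, Pearson r, and within-subject ANOVA.

The repeated-measures ANOVA over the channels of interest applies the
Greenhouse–Geisser degrees-of-freedom correction whenever Mauchly's
sphericity test rejects at α = 0.05, and follows up with all pairwise
paired t-tests under Bonferroni correction.  scipy and pingouin do the
computing behind this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupResult:
    """One inferential test: statistic, (possibly corrected) dfs, p, effect."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float
    effect_size_name: str = ""
    correction: str = "none"
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def paired_t(a: np.ndarray, b: np.ndarray) -> GroupResult:
    """Two-tailed paired t-test of per-subject values ``a`` vs ``b``.

    Effect size is the correlation-scale ``r = sqrt(t²/(t²+df))``.
    Zero variance of the pairwise differences is flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least three pairs")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return GroupResult("paired t", 0.0 if np.allclose(diff, 0) else np.inf,
                           (n - 1,), 1.0 if np.allclose(diff, 0) else 0.0,
                           np.nan, "r", degenerate=True)
    t, p = stats.ttest_rel(a, b)
    df = n - 1
    r = float(np.sqrt(t ** 2 / (t ** 2 + df)))
    return GroupResult("paired t", float(t), (float(df),), float(p), r, "r")


def pearson(x: np.ndarray, y: np.ndarray) -> GroupResult:
    """Pearson correlation with two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        return GroupResult("pearson", np.nan, (len(x) - 2,), np.nan, np.nan,
                           "r", degenerate=True)
    r, p = stats.pearsonr(x, y)
    return GroupResult("pearson", float(r), (float(len(x) - 2),), float(p),
                       float(r), "r")


def rm_anova_gg(values: np.ndarray,
                condition_names: list[str] | None = None,
                mauchly_alpha: float = 0.05
                ) -> tuple[GroupResult, pd.DataFrame]:
    """One-way within-subject ANOVA of a complete subject × condition matrix.

    Reports Greenhouse–Geisser corrected degrees of freedom and p-value
    whenever Mauchly's test rejects sphericity at ``mauchly_alpha``,
    plus partial eta-squared.  The post-hoc table holds all pairwise
    paired t-tests with Bonferroni-multiplied p-values capped at 1.
    Missing cells are an error; nothing is imputed.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a subject x condition matrix")
    n_sub, n_cond = values.shape
    if n_cond < 2 or n_sub < 3:
        raise ValueError("need >= 2 conditions and >= 3 subjects")
    if not np.isfinite(values).all():
        raise ValueError("missing or non-finite cells are not allowed")
    names = condition_names or [f"c{i}" for i in range(n_cond)]
    if len(names) != n_cond:
        raise ValueError("one name per condition required")

    centered = values - values.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0.0):
        # no within-subject variation beyond a per-subject offset: the
        # condition effect and its error term are both exactly zero
        df = (float(n_cond - 1), float((n_sub - 1) * (n_cond - 1)))
        result = GroupResult("rm-anova", 0.0, df, 1.0, 0.0,
                             "partial eta squared", degenerate=True)
        rows = [{"a": names[i], "b": names[j], "t": 0.0, "df": n_sub - 1,
                 "p_uncorrected": 1.0, "p_bonferroni": 1.0}
                for i, j in combinations(range(n_cond), 2)]
        return result, pd.DataFrame(rows)

    import pingouin as pg

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), n_cond),
        "condition": np.tile(names, n_sub),
        "value": values.ravel(),
    })
    aov = pg.rm_anova(data=long, dv="value", within="condition",
                      subject="subject", correction=True, detailed=True,
                      effsize="np2")
    row = aov.loc[aov["Source"] == "condition"].iloc[0]
    err = aov.loc[aov["Source"] == "Error"].iloc[0]
    f_stat = float(row["F"])
    df1, df2 = float(row["DF"]), float(err["DF"])
    np2 = float(row["np2"])

    mauchly_w = float(row["W_spher"]) if "W_spher" in aov.columns else np.nan
    mauchly_p = float(row["p_spher"]) if "p_spher" in aov.columns else np.nan
    violated = np.isfinite(mauchly_p) and mauchly_p < mauchly_alpha
    if n_cond > 2 and violated:
        eps = float(row["eps"])
        df = (df1 * eps, df2 * eps)
        p = float(stats.f.sf(f_stat, *df))
        correction = "greenhouse-geisser"
    else:
        df = (df1, df2)
        p = float(row["p_unc"])
        correction = "none"

    result = GroupResult(
        "rm-anova", f_stat, df, p, np2, "partial eta squared",
        correction=correction,
        extra={"mauchly_w": mauchly_w, "mauchly_p": mauchly_p})

    m = n_cond * (n_cond - 1) // 2
    rows = []
    for i, j in combinations(range(n_cond), 2):
        t, p_unc = stats.ttest_rel(values[:, i], values[:, j])
        rows.append({
            "a": names[i], "b": names[j], "t": float(t), "df": n_sub - 1,
            "p_uncorrected": float(p_unc),
            "p_bonferroni": float(min(1.0, p_unc * m)),
        })
    posthoc = pd.DataFrame(rows)
    return result, posthoc
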