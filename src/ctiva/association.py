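"""Covariate screening against the estimated interval.

For each covariate x_j the association with the per-sample expected interval
y is scored by one of four tests:

* ``anova``            -- one-way F test of y across the levels of a
                          categorical x (for binary x this is the pooled
                          two-sample t test squared);
* ``linear``           -- two-sided t test on the slope of y ~ x for a
                          continuous x;
* ``permutation``      -- permutation null of the F statistic (categorical)
                          or |Pearson r| (continuous), y permuted, x fixed,
                          p = (1 + #{perm >= obs}) / (n_perm + 1);
* ``rank_correlation`` -- Spearman rank correlation with midranks (binary
                          covariates enter as 0/1 codes).

The ``anova`` battery on a mixed dataset applies the F test to categorical
variables and the regression-slope test to continuous ones, with a single
shared p-value threshold downstream (no multiplicity correction).  Detection
is evaluated by sweeping that threshold: score = -p, AUC by the tie-corrected
Mann-Whitney rank formula, plus sensitivity/specificity at fixed cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "TestResult",
    "ScreenReport",
    "anova_p",
    "linear_p",
    "permutation_p",
    "rank_corr_p",
    "screen",
    "roc_auc",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1)


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    variable_id: object = None


def _clean_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    return x, y


def anova_p(x, y, variable_id=None) -> TestResult:
    """One-way ANOVA of y across the levels of categorical x."""
    x, y = _clean_xy(x, y)
    levels = np.unique(x)
    groups = [y[x == lv] for lv in levels]
    if len(groups) < 2 or min(len(g) for g in groups) < 2:
        raise ValueError("anova needs >= 2 groups with >= 2 members each")
    f, p = stats.f_oneway(*groups)
    return TestResult("anova", float(f), float(p), variable_id)


def linear_p(x, y, variable_id=None) -> TestResult:
    """Two-sided t test on the slope of the simple regression y ~ x."""
    x, y = _clean_xy(x, y)
    if len(x) < 3:
        raise ValueError("linear test needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    res = stats.linregress(x, y)
    with np.errstate(divide="ignore"):
        t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return TestResult("linear", float(t), float(res.pvalue), variable_id)


def _f_statistic(x, y):
    levels = np.unique(x)
    grand = y.mean()
    ssb = sum((y[x == lv].mean() - grand) ** 2 * (x == lv).sum() for lv in levels)
    ssw = sum(((y[x == lv] - y[x == lv].mean()) ** 2).sum() for lv in levels)
    df1, df2 = len(levels) - 1, len(y) - len(levels)
    if ssw == 0:
        return np.inf
    return (ssb / df1) / (ssw / df2)


def _infer_kind(x) -> str:
    vals = np.unique(x)
    if len(vals) <= 10 and np.allclose(vals, np.round(vals)):
        return "categorical"
    return "continuous"


def permutation_p(x, y, n_perm: int = 1000, rng_seed=0, kind=None,
                  variable_id=None) -> TestResult:
    """Permutation test: F for categorical x, |Pearson r| for continuous x."""
    x, y = _clean_xy(x, y)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    kind = kind or _infer_kind(x)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    if kind == "categorical" and len(np.unique(x)) > 2:
        stat = _f_statistic(x, y)
        perm = np.array([_f_statistic(x, rng.permutation(y))
                         for _ in range(n_perm)])
        exceed = np.sum(perm >= stat)
    else:
        # two-level F is strictly increasing in r^2, so counting exceedances
        # of |r| gives the identical permutation p at vectorised cost
        stat = (_f_statistic(x, y) if kind == "categorical"
                else abs(stats.pearsonr(x, y).statistic))
        r_obs = abs(stats.pearsonr(x, y).statistic)
        yc = (y - y.mean()) / y.std()
        xc = (x - x.mean()) / x.std()
        perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
        exceed = np.sum(np.abs(perms @ xc) / len(x) >= r_obs - 1e-12)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return TestResult("permutation", float(stat), float(p), variable_id)


def rank_corr_p(x, y, variable_id=None) -> TestResult:
    """Spearman rank correlation (midranks for ties) with t-approximation p."""
    x, y = _clean_xy(x, y)
    if len(x) < 5:
        raise ValueError("rank correlation needs n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rho, p = stats.spearmanr(x, y)
    return TestResult("rank_correlation", float(rho), float(p), variable_id)


# ---------------------------------------------------------------------------
# batch screening
# ---------------------------------------------------------------------------

def _perm_pvalues_binary_or_continuous(X, y, n_perm, rng):
    """Vectorised permutation p-values for the whole matrix.

    Uses |Pearson r| as the statistic; for a two-level covariate the one-way
    F statistic is a strictly increasing function of r^2, so the permutation
    p-value is identical to the F-based one.
    """
    n, p = X.shape
    yc = (y - y.mean())
    yc = yc / yc.std()
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate in permutation screen")
    Xc = Xc / sd
    r_obs = np.abs(yc @ Xc) / n
    perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
    R = np.abs(perms @ Xc) / n  # (n_perm, p)
    return (1.0 + (R >= r_obs[None, :]).sum(axis=0)) / (n_perm + 1.0)


def screen(X, variable_types, y, tests=("anova",), n_perm: int = 1000,
           rng_seed: int = 0) -> pd.DataFrame:
    """One p-value per variable per requested test battery.

    ``anova`` applies the F test to categorical variables and the
    regression-slope test to continuous ones (the mixed "ANOVA(+linear)"
    battery).  Returns a tidy frame (variable, type, test, statistic,
    p_value).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    variable_types = np.asarray(variable_types)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    if X.shape[1] != len(variable_types):
        raise ValueError("one variable type per column is required")
    rng = np.random.default_rng(rng_seed)
    frames = []
    for test in tests:
        stat = np.full(X.shape[1], np.nan)
        pval = np.full(X.shape[1], np.nan)
        if test == "permutation":
            multi = np.array([len(np.unique(X[:, j])) > 2 and
                              variable_types[j] == "categorical"
                              for j in range(X.shape[1])])
            if multi.any():
                for j in np.nonzero(multi)[0]:
                    r = permutation_p(X[:, j], y, n_perm, rng, "categorical", j)
                    stat[j], pval[j] = r.statistic, r.p_value
            rest = ~multi
            if rest.any():
                pval[rest] = _perm_pvalues_binary_or_continuous(
                    X[:, rest], y, n_perm, rng)
        else:
            for j in range(X.shape[1]):
                if test == "anova":
                    r = (anova_p(X[:, j], y, j)
                         if variable_types[j] == "categorical"
                         else linear_p(X[:, j], y, j))
                elif test == "rank_correlation":
                    r = rank_corr_p(X[:, j], y, j)
                else:
                    raise ValueError(f"unknown test {test!r}")
                stat[j], pval[j] = r.statistic, r.p_value
        frames.append(pd.DataFrame({
            "variable": np.arange(X.shape[1]),
            "type": variable_types,
            "test": test,
            "statistic": stat,
            "p_value": pval,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    auc: float
    roc_points: np.ndarray  # (k, 2) array of (FPR, TPR)
    sensitivity: dict = field(default_factory=dict)
    specificity: dict = field(default_factory=dict)
    n_pos: int = 0
    n_neg: int = 0


def roc_auc(p_values, truth, thresholds=DEFAULT_THRESHOLDS) -> ScreenReport:
    """Detection quality of a p-value vector against binary truth labels.

    Score = -p; AUC is the tie-corrected Mann-Whitney statistic; sensitivity
    and specificity use strict detection p < threshold.
    """
    p = np.asarray(p_values, dtype=float)
    t = np.asarray(truth).astype(int)
    if t.sum() == 0 or t.sum() == len(t):
        raise ValueError("truth needs at least one positive and one negative")
    missing = ~np.isfinite(p)
    if missing.any():
        p = np.where(missing, 1.0, p)  # unfit variables rank last
    auc = float(roc_auc_score(t, -p))
    fpr, tpr, _ = roc_curve(t, -p)
    sens = {tau: float(np.mean(p[t == 1] < tau)) for tau in thresholds}
    spec = {tau: float(np.mean(p[t == 0] >= tau)) for tau in thresholds}
    return ScreenReport(auc=auc, roc_points=np.column_stack([fpr, tpr]),
                        sensitivity=sens, specificity=spec,
                        n_pos=int(t.sum()), n_neg=int((1 - t).sum()))
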