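"""Comparator methods that do not model the censored interval.

* ``baseline_ignored``   -- treat every censoring time as the event time
  (y = V2 - V1 for all samples) and run the screening battery.
* ``baseline_no_censor`` -- complete-case analysis restricted to samples
  with both events observed.
* ``cox_per_variable``   -- univariate Cox proportional-hazards fits of a
  single event (V_k, delta_k) on each covariate, the other event ignored;
  Wald p-value on the coefficient.  Ties are handled with the Breslow
  approximation, and the Newton-Raphson solver is vectorised across
  covariates so 1,000 per-variable fits cost a few matrix passes.

On fully uncensored data all of these coincide with the interval pipeline's
both-observed path at any threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import screen

__all__ = [
    "baseline_ignored",
    "baseline_no_censor",
    "cox_per_variable",
]


def baseline_ignored(obs: pd.DataFrame, X, variable_types, tests=("anova",),
                     n_perm: int = 1000, rng_seed: int = 0) -> pd.DataFrame:
    """Censoring ignored: the censored time is taken as the event time."""
    y = (obs["v2"] - obs["v1"]).to_numpy(dtype=float)
    return screen(X, variable_types, y, tests, n_perm, rng_seed)


def baseline_no_censor(obs: pd.DataFrame, X, variable_types, tests=("anova",),
                       n_perm: int = 1000, rng_seed: int = 0) -> pd.DataFrame:
    """Complete-case analysis: only samples with both events observed."""
    mask = (obs["delta1"] == 1) & (obs["delta2"] == 1)
    if mask.sum() < 3:
        raise ValueError("complete-case analysis needs >= 3 fully observed samples")
    sub = obs.loc[mask]
    y = (sub["v2"] - sub["v1"]).to_numpy(dtype=float)
    out = screen(np.asarray(X, dtype=float)[mask.to_numpy()], variable_types, y,
                 tests, n_perm, rng_seed)
    out.attrs["n_complete"] = int(mask.sum())
    return out


# ---------------------------------------------------------------------------
# univariate Cox regression, vectorised across covariates
# ---------------------------------------------------------------------------

def _cox_newton(time, event, X, max_iter=20, tol=1e-8, clip=30.0):
    """Newton-Raphson on the Breslow partial log-likelihood, one univariate
    model per column of X.  Returns (beta, information, converged)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order].astype(bool)
    Xs = X[order]
    n, p = Xs.shape
    # risk set of an event at time t_i: all samples with time >= t_i; with
    # Breslow ties every tied event shares the denominator starting at the
    # first index of the tied block
    start = np.searchsorted(t, t, side="left")
    ev = np.nonzero(d)[0]
    risk_start = start[ev]  # (n_events,)

    beta = np.zeros(p)
    converged = np.zeros(p, dtype=bool)
    info = np.full(p, np.nan)
    for _ in range(max_iter):
        eta = np.clip(Xs * beta[None, :], -clip, clip)
        w = np.exp(eta)
        xw = Xs * w
        x2w = Xs * xw
        # suffix sums: S(i) = sum_{j >= i}
        s0 = np.cumsum(w[::-1], axis=0)[::-1]
        s1 = np.cumsum(xw[::-1], axis=0)[::-1]
        s2 = np.cumsum(x2w[::-1], axis=0)[::-1]
        r0 = s0[risk_start]
        mu = s1[risk_start] / r0
        grad = (Xs[ev] - mu).sum(axis=0)
        info = (s2[risk_start] / r0 - mu ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 1e-12, grad / info, 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + step
        converged = np.abs(step) < tol
        if converged.all():
            break
    bad = (~np.isfinite(beta)) | (np.abs(beta) > 15) | ~(info > 1e-12)
    return beta, info, ~bad & converged


def cox_per_variable(obs: pd.DataFrame, X, event_index: int = 1,
                     max_iter: int = 20) -> pd.DataFrame:
    """Univariate proportional-hazards screen of one event per covariate.

    Fits (V_k, delta_k) on each covariate column separately and reports the
    Wald test on the coefficient.  Non-converged or separated fits get
    p = NaN (they rank last in ROC construction) with a reason column.
    """
    if event_index not in (1, 2):
        raise ValueError("event_index must be 1 or 2")
    time = obs[f"v{event_index}"].to_numpy(dtype=float)
    event = obs[f"delta{event_index}"].to_numpy(dtype=int)
    X = np.asarray(X, dtype=float)
    if event.sum() < 2:
        raise ValueError("need at least 2 observed events")
    sd = X.std(axis=0)
    fit_cols = sd > 0
    beta = np.full(X.shape[1], np.nan)
    info = np.full(X.shape[1], np.nan)
    ok = np.zeros(X.shape[1], dtype=bool)
    if fit_cols.any():
        b, i, conv = _cox_newton(time, event, X[:, fit_cols], max_iter=max_iter)
        beta[fit_cols] = b
        info[fit_cols] = i
        ok[fit_cols] = conv
    se = np.sqrt(1.0 / np.where(info > 0, info, np.nan))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~ok] = np.nan
    reason = np.where(~fit_cols, "constant",
                      np.where(ok, "", "non-convergence-or-separation"))
    return pd.DataFrame({
        "variable": np.arange(X.shape[1]),
        "test": f"cox_event{event_index}",
        "coef": beta,
        "se": se,
        "statistic": z,
        "p_value": p,
        "reason": reason,
    })
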