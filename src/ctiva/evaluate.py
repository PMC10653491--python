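"""Repeated-simulation experiments.

Runs the full pipeline (simulate -> density fit -> interval estimation ->
screening, plus the comparator methods) on R seeded replicates of one or
more simulation configurations and aggregates detection quality (AUC mean
+/- SD, sensitivity/specificity at fixed p-value cutoffs) into tidy tables.
Positives are always the interval-correlated variables; everything else
(T1-only, T2-only, null) counts as a negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import baselines as _baselines
from .association import DEFAULT_THRESHOLDS, roc_auc, screen
from .interval import estimate_all
from .opt_density import fit_joint
from .simulate import SimConfig, SimReplicate, make_replicate

__all__ = [
    "ExperimentGrid",
    "method_pvalues",
    "run_replicate",
    "run_experiment",
    "make_boxplot_data",
]

METHODS = ("ctiva", "ignored", "no_censor", "cox_event1", "cox_event2")
TESTS = ("anova", "permutation", "rank_correlation")


@dataclass
class ExperimentGrid:
    configs: dict  # name -> SimConfig
    methods: Sequence[str] = METHODS
    tests: Sequence[str] = TESTS
    n_replicates: int = 20
    master_seed: int = 0
    n_mc: int = 1000
    n_perm: int = 1000
    max_depth: int = 8
    max_iter: int = 10
    tol: float = 1e-3
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS


def ctiva_intervals(rep: SimReplicate, n_mc=1000, max_depth=8, max_iter=10,
                    tol=1e-3, rng_seed=0) -> np.ndarray:
    """The CTIVA response: fit the joint density, then the expected interval
    per sample."""
    fit = fit_joint(rep.observations, max_depth=max_depth, max_iter=max_iter,
                    tol=tol)
    est = estimate_all(fit.density, rep.observations, n_mc=n_mc,
                       rng_seed=rng_seed)
    return est["y"].to_numpy()


def method_pvalues(rep: SimReplicate, method: str, tests: Sequence[str],
                   n_mc=1000, n_perm=1000, max_depth=8, max_iter=10, tol=1e-3,
                   rng_seed=0, y_ctiva: Optional[np.ndarray] = None) -> pd.DataFrame:
    """P-values of one method on one replicate, tidy (variable, test, p_value).

    For the Cox comparators the single Wald p-value is reported under the
    test label ``cox``; the screening batteries do not apply.
    """
    if method == "ctiva":
        y = y_ctiva if y_ctiva is not None else ctiva_intervals(
            rep, n_mc, max_depth, max_iter, tol, rng_seed)
        return screen(rep.covariates, rep.variable_types, y, tests,
                      n_perm, rng_seed)
    if method == "ignored":
        return _baselines.baseline_ignored(rep.observations, rep.covariates,
                                           rep.variable_types, tests, n_perm,
                                           rng_seed)
    if method == "no_censor":
        return _baselines.baseline_no_censor(rep.observations, rep.covariates,
                                             rep.variable_types, tests, n_perm,
                                             rng_seed)
    if method in ("cox_event1", "cox_event2"):
        out = _baselines.cox_per_variable(rep.observations, rep.covariates,
                                          event_index=int(method[-1]))
        out = out[["variable", "test", "statistic", "p_value"]].copy()
        out["test"] = "cox"
        out["type"] = rep.variable_types
        return out
    raise ValueError(f"unknown method {method!r}")


def run_replicate(config: SimConfig, replicate_seed: int,
                  methods=METHODS, tests=TESTS, n_mc=1000, n_perm=1000,
                  max_depth=8, max_iter=10, tol=1e-3,
                  thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """All (method, test) metrics for one seeded replicate."""
    cfg = replace(config, seed=replicate_seed)
    rep = make_replicate(cfg)
    truth = (rep.truth == "interval").astype(int)
    y_ctiva = None
    if "ctiva" in methods:
        y_ctiva = ctiva_intervals(rep, n_mc, max_depth, max_iter, tol,
                                  rng_seed=replicate_seed)
    rows = []
    for method in methods:
        pv = method_pvalues(rep, method, tests, n_mc, n_perm, max_depth,
                            max_iter, tol, rng_seed=replicate_seed,
                            y_ctiva=y_ctiva)
        for test, sub in pv.groupby("test", sort=False):
            sub = sub.sort_values("variable")
            report = roc_auc(sub["p_value"].to_numpy(), truth, thresholds)
            row = {"replicate_seed": replicate_seed, "method": method,
                   "test": test, "auc": report.auc}
            for tau in thresholds:
                row[f"sens@{tau}"] = report.sensitivity[tau]
                row[f"spec@{tau}"] = report.specificity[tau]
            rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(grid: ExperimentGrid, out_dir=None):
    """Run every (config, method, test, replicate) cell of the grid.

    Replicate seeds are ``master_seed * 10**4 + replicate index`` so separate
    configs share event-stream seeds but remain distinct across master seeds.
    Returns ``(raw, aggregate)`` DataFrames; any failed cell is recorded and
    excluded from aggregation.
    """
    raw_frames, failures = [], []
    for name, config in grid.configs.items():
        for r in range(grid.n_replicates):
            seed = int(grid.master_seed) * 10_000 + r
            try:
                df = run_replicate(config, seed, grid.methods, grid.tests,
                                   grid.n_mc, grid.n_perm, grid.max_depth,
                                   grid.max_iter, grid.tol, grid.thresholds)
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                failures.append({"config": name, "replicate": r,
                                 "error": repr(exc)})
                continue
            df.insert(0, "config", name)
            df.insert(2, "replicate", r)
            raw_frames.append(df)
    raw = pd.concat(raw_frames, ignore_index=True) if raw_frames else pd.DataFrame()
    metric_cols = [c for c in raw.columns
                   if c == "auc" or c.startswith(("sens@", "spec@"))]
    agg = (raw.groupby(["config", "method", "test"], sort=False)[metric_cols]
              .agg(["mean", "std"]) if len(raw) else pd.DataFrame())
    if len(agg):
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        agg = agg.reset_index()
    agg.attrs["failures"] = failures
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        raw.to_csv(out / "replicates.csv", index=False)
        agg.to_csv(out / "aggregate.csv", index=False)
    return raw, agg


def make_boxplot_data(raw: pd.DataFrame, metric: str = "auc") -> dict:
    """Per-(config, method, test) metric vectors across replicates, for
    box plots.  Empty cells are omitted."""
    if len(raw) < 2:
        raise ValueError("need at least 2 replicates")
    out = {}
    for key, sub in raw.groupby(["config", "method", "test"], sort=False):
        vals = sub[metric].to_numpy()
        if len(vals):
            out[key] = vals
    return out
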