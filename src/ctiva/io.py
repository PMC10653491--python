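"""Dataset readers/writers and the end-to-end pipeline.

The interchange format is a plain CSV with required columns
``v1, delta1, v2, delta2`` followed by zero or more covariate columns, plus
an optional JSON sidecar carrying variable types, truth labels (evaluation
only -- the fitting pipeline never reads them) and the generating config.
Without a sidecar, covariate types are inferred: a column with at most 10
distinct values, all integral, is treated as categorical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import numpy as np
import pandas as pd

from .association import DEFAULT_THRESHOLDS, roc_auc, screen
from .interval import estimate_all
from .opt_density import density_to_json, fit_joint
from .simulate import GroupStructure, SimConfig

logger = logging.getLogger("ctiva")

REQUIRED = ("v1", "delta1", "v2", "delta2")

__all__ = ["read_dataset", "write_dataset", "load_config", "run_pipeline"]


def _sidecar_path(path) -> pathlib.Path:
    p = pathlib.Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_dataset(path, obs: pd.DataFrame, covariates=None,
                  variable_types=None, truth=None, config=None) -> None:
    """Write observations (+ covariates) to CSV with a JSON sidecar."""
    df = obs[list(REQUIRED)].copy()
    if covariates is not None:
        X = np.asarray(covariates)
        names = [f"x{j + 1:04d}" for j in range(X.shape[1])]
        df = pd.concat([df, pd.DataFrame(X, columns=names, index=df.index)], axis=1)
    df.to_csv(path, index=False)
    meta = {}
    if variable_types is not None:
        meta["variable_types"] = list(map(str, variable_types))
    if truth is not None:
        meta["truth"] = list(map(str, truth))
    if config is not None:
        cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
        meta["config"] = json.loads(json.dumps(cfg, default=list))
    if meta:
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_dataset(path):
    """Read and validate a dataset CSV.

    Returns ``(observations, covariates, metadata)`` where metadata holds
    covariate names/types and, when a sidecar is present, truth labels and
    the generating config.  Validation errors name the offending row (1-based
    data rows, header excluded).
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("delta1", "delta2"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise ValueError(f"{path}: non-binary {col} in row {row}")
    for col in ("v1", "v2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise ValueError(f"{path}: invalid {col} (negative or non-finite) "
                             f"in row {row}")
    obs = df[list(REQUIRED)].copy()
    cov_cols = [c for c in df.columns if c not in REQUIRED]
    X = df[cov_cols].to_numpy(dtype=float) if cov_cols else np.empty((len(df), 0))

    meta = {"covariate_names": cov_cols}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    elif cov_cols:
        types = []
        for c in cov_cols:
            vals = df[c].dropna().unique()
            integral = len(vals) <= 10 and np.allclose(vals, np.round(vals))
            types.append("categorical" if integral else "continuous")
        meta["variable_types"] = types
        logger.info("no sidecar for %s: covariate types inferred "
                    "(<=10 integral values -> categorical)", path)
    return obs, X, meta


def load_config(path) -> SimConfig:
    """SimConfig from a YAML or JSON mapping."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "group_structure" in data and data["group_structure"] is not None:
        data["group_structure"] = GroupStructure(**data["group_structure"])
    for key in ("block_sizes", "mu_T", "mu_C"):
        if key in data:
            data[key] = tuple(data[key])
    for key in ("sigma_T", "sigma_C"):
        if key in data:
            data[key] = tuple(tuple(row) for row in data[key])
    return SimConfig(**data)


def run_pipeline(data_path, out_dir, tests=("anova",), n_mc: int = 1000,
                 n_perm: int = 1000, max_depth: int = 8, max_iter: int = 10,
                 tol: float = 1e-3, seed: int = 0,
                 thresholds=DEFAULT_THRESHOLDS) -> pathlib.Path:
    """fit_joint -> estimate_all -> screen, with all artifacts persisted.

    Writes density.json, intervals.csv, results.csv, metrics.json (only when
    the sidecar carries truth labels) and run.log into ``out_dir``.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        import ctiva

        logger.info("ctiva %s | data=%s seed=%d n_mc=%d n_perm=%d depth=%d",
                    ctiva.__version__, data_path, seed, n_mc, n_perm, max_depth)
        obs, X, meta = read_dataset(data_path)

        logger.info("stage fit: n=%d", len(obs))
        fit = fit_joint(obs, max_depth=max_depth, max_iter=max_iter, tol=tol)
        logger.info("fit converged=%s iterations=%d tv=%s fallback=%d",
                    fit.converged, fit.n_iter,
                    [f"{tv:.2e}" for tv in fit.tv_history], fit.n_fallback)
        density_to_json(fit.density, out / "density.json")

        logger.info("stage intervals: n_mc=%d", n_mc)
        est = estimate_all(fit.density, obs, n_mc=n_mc, rng_seed=seed)
        est.to_csv(out / "intervals.csv", index=False)
        logger.info("case counts: %s", est["case"].value_counts().to_dict())

        if X.shape[1]:
            logger.info("stage screen: p=%d tests=%s", X.shape[1], list(tests))
            types = np.asarray(meta.get("variable_types",
                                        ["continuous"] * X.shape[1]))
            results = screen(X, types, est["y"].to_numpy(), tests, n_perm, seed)
            if "truth" in meta:
                results["truth"] = np.tile(meta["truth"], len(tests))
            results.to_csv(out / "results.csv", index=False)
            if "truth" in meta:
                truth = (np.asarray(meta["truth"]) == "interval").astype(int)
                metrics = {}
                for test, sub in results.groupby("test", sort=False):
                    rep = roc_auc(sub.sort_values("variable")["p_value"].to_numpy(),
                                  truth, thresholds)
                    metrics[test] = {
                        "auc": rep.auc,
                        "sensitivity": {str(k): v for k, v in rep.sensitivity.items()},
                        "specificity": {str(k): v for k, v in rep.specificity.items()},
                    }
                (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
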