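"""Bivariate joint density estimation under double right-censoring.

The estimator is an Optional Polya Tree (OPT): a recursion over axis-aligned
rectangles of the (T1, T2) plane that either stops (the rectangle is declared
uniform) or splits at the midpoint of one of the two axes.  For a rectangle A
holding N(A) points the marginal likelihood is

    Phi(A) = 1/2 Phi0(A)
           + 1/4 sum_{i=1,2} B(N(Ai1)+1/2, N(Ai2)+1/2) / B(1/2, 1/2)
                              * Phi(Ai1) * Phi(Ai2)

where Phi0(A) = |A|^(-N(A)) is the uniform (stopped) likelihood, Ai1/Ai2 are
the two halves of A along axis i, and B is the beta function.  A rectangle
with N(A) < 2 is terminal with Phi = Phi0.  The fitted density is piecewise
constant on the stopped rectangles, with leaf density N(A) / (n |A|).

Censoring enters through the counts: N(A) cannot be observed directly, so it
is replaced by the expected count N(A | f) under the current density f --
each observation contributes its posterior probability of lying in A given
its feasible set (a point, a line-column, or an upper quadrant).  Iterating

    f^(i+1) = OPT(N(A | f^(i)))

from an independence initialisation (product of the two univariate
Kaplan-Meier marginals) yields the joint density estimate.  All Phi values
are computed in log space; beta products underflow past depth ~6 otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp

__all__ = [
    "Region",
    "KmCurve",
    "PiecewiseDensity",
    "PartitionNode",
    "OptFit",
    "km_fit",
    "default_domain",
    "initial_joint",
    "expected_count_grid",
    "expected_counts",
    "opt_build",
    "decide_partition",
    "extract_density",
    "fit_joint",
    "density_to_json",
    "density_from_json",
]

_LOG_HALF = math.log(0.5)
_LOG_QUARTER = math.log(0.25)
_BETALN_HALF = betaln(0.5, 0.5)  # log B(1/2,1/2) = log(pi)
_EPS_MASS = 1e-12


@dataclass(frozen=True)
class Region:
    """Half-open axis-aligned rectangle [lo1, hi1) x [lo2, hi2)."""

    lo1: float
    hi1: float
    lo2: float
    hi2: float

    def __post_init__(self):
        if not (self.lo1 < self.hi1 and self.lo2 < self.hi2):
            raise ValueError(f"degenerate region {self}")

    @property
    def area(self) -> float:
        return (self.hi1 - self.lo1) * (self.hi2 - self.lo2)

    def contains(self, x: float, y: float) -> bool:
        return self.lo1 <= x < self.hi1 and self.lo2 <= y < self.hi2


class KmCurve:
    """Right-continuous Kaplan-Meier survival step function, S(0) = 1."""

    def __init__(self, times: np.ndarray, survival: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.survival = np.asarray(survival, dtype=float)
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival curve must be nonincreasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    def cell_masses(self, edges: np.ndarray) -> np.ndarray:
        """Probability mass per cell of a 1-d grid; residual mass beyond the
        last edge (censored tail) is assigned to the outermost cell."""
        s = self(edges)
        masses = s[:-1] - s[1:]
        masses[-1] += s[-1]
        return np.clip(masses, 0.0, None)


def km_fit(times, events) -> KmCurve:
    """Product-limit estimator of the survival function (via lifelines)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("km_fit requires at least one observation")
    if len(times) != len(events):
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KmCurve(sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float))


class PiecewiseDensity:
    """Normalised piecewise-constant density on a rectangular grid.

    The grid need not be uniform: ``edges1``/``edges2`` are the cell
    boundaries and ``masses[i, j]`` the probability mass of cell (i, j).
    A density produced by :func:`extract_density` keeps the OPT leaves as
    ``leaves``; otherwise leaves are the grid cells themselves.
    """

    def __init__(self, edges1, edges2, masses, leaves=None, normalize=True):
        self.edges1 = np.asarray(edges1, dtype=float)
        self.edges2 = np.asarray(edges2, dtype=float)
        self.masses = np.asarray(masses, dtype=float)
        if self.masses.shape != (len(self.edges1) - 1, len(self.edges2) - 1):
            raise ValueError("masses shape does not match the grid")
        if np.any(self.masses < -1e-9):
            raise ValueError("negative cell mass")
        total = self.masses.sum()
        if total <= 0:
            raise ValueError("zero total mass")
        if normalize:
            self.masses = np.clip(self.masses, 0.0, None) / total
        self._leaves = leaves

    # -- geometry -----------------------------------------------------------
    @property
    def domain(self) -> Region:
        return Region(self.edges1[0], self.edges1[-1], self.edges2[0], self.edges2[-1])

    @property
    def cell_areas(self) -> np.ndarray:
        return np.outer(np.diff(self.edges1), np.diff(self.edges2))

    @property
    def density_grid(self) -> np.ndarray:
        return self.masses / self.cell_areas

    @property
    def leaves(self):
        if self._leaves is None:
            w1, w2 = np.diff(self.edges1), np.diff(self.edges2)
            dens = self.masses / np.outer(w1, w2)
            self._leaves = [
                (Region(self.edges1[i], self.edges1[i + 1],
                        self.edges2[j], self.edges2[j + 1]), float(dens[i, j]))
                for i in range(len(w1)) for j in range(len(w2))
            ]
        return self._leaves

    # -- measure ------------------------------------------------------------
    def integral(self) -> float:
        return float(self.masses.sum())

    def mass(self, region: Region) -> float:
        """Probability mass of an arbitrary rectangle (fractional overlap)."""
        f1 = _overlap_frac(self.edges1, region.lo1, region.hi1)
        f2 = _overlap_frac(self.edges2, region.lo2, region.hi2)
        return float(f1 @ self.masses @ f2)

    def refine(self, edges1, edges2) -> "PiecewiseDensity":
        """Re-express the density on another grid (mass-conserving)."""
        o1 = _overlap_lengths(self.edges1, np.asarray(edges1, dtype=float))
        o2 = _overlap_lengths(self.edges2, np.asarray(edges2, dtype=float))
        dens = self.density_grid
        new_masses = o1.T @ dens @ o2
        return PiecewiseDensity(edges1, edges2, new_masses, normalize=False)

    def tv_distance(self, other: "PiecewiseDensity") -> float:
        e1 = np.union1d(self.edges1, other.edges1)
        e2 = np.union1d(self.edges2, other.edges2)
        a = self.refine(e1, e2).masses
        b = other.refine(e1, e2).masses
        return 0.5 * float(np.abs(a - b).sum())

    def marginal_survival(self, axis: int, t: float) -> float:
        """P(T_axis > t) under the fitted joint density."""
        edges = self.edges1 if axis == 1 else self.edges2
        frac = _overlap_frac(edges, t, np.inf)
        m = self.masses.sum(axis=1) if axis == 1 else self.masses.sum(axis=0)
        return float(frac @ m)


def _overlap_frac(edges: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fraction of each cell [edges[i], edges[i+1]) covered by [lo, hi)."""
    left = np.maximum(edges[:-1], lo)
    right = np.minimum(edges[1:], hi)
    return np.clip((right - left) / np.diff(edges), 0.0, 1.0)


def _overlap_lengths(old_edges: np.ndarray, new_edges: np.ndarray) -> np.ndarray:
    """(n_old, n_new) matrix of interval overlap lengths."""
    lo = np.maximum(old_edges[:-1, None], new_edges[None, :-1])
    hi = np.minimum(old_edges[1:, None], new_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def _cell_index(edges: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(edges) - 2)


# ---------------------------------------------------------------------------
# domain and initialisation
# ---------------------------------------------------------------------------

def default_domain(obs: pd.DataFrame, margin: float = 0.05) -> Region:
    """Finite sample space: [0, (1+margin) max V1] x [0, (1+margin) max V2].

    The OPT needs a bounded rectangle; the margin keeps every observation
    interior and the Kaplan-Meier residual tail mass lands in the outermost
    cells.
    """
    hi1 = float(obs["v1"].max()) * (1.0 + margin)
    hi2 = float(obs["v2"].max()) * (1.0 + margin)
    if hi1 <= 0 or hi2 <= 0:
        raise ValueError("observed times must be positive")
    return Region(0.0, hi1, 0.0, hi2)


def _dyadic_edges(lo: float, hi: float, depth: int) -> np.ndarray:
    return np.linspace(lo, hi, 2 ** depth + 1)


def initial_joint(obs: pd.DataFrame, omega: Region, depth: int = 8) -> PiecewiseDensity:
    """Independence initialisation: product of the two KM marginal densities
    discretised on the dyadic grid of the given depth."""
    v1 = obs["v1"].to_numpy(dtype=float)
    v2 = obs["v2"].to_numpy(dtype=float)
    if np.any(v1 >= omega.hi1) or np.any(v2 >= omega.hi2) or \
       np.any(v1 < omega.lo1) or np.any(v2 < omega.lo2):
        raise ValueError("omega does not contain all observed values")
    km1 = km_fit(v1, obs["delta1"].to_numpy())
    km2 = km_fit(v2, obs["delta2"].to_numpy())
    e1 = _dyadic_edges(omega.lo1, omega.hi1, depth)
    e2 = _dyadic_edges(omega.lo2, omega.hi2, depth)
    masses = np.outer(km1.cell_masses(e1), km2.cell_masses(e2))
    return PiecewiseDensity(e1, e2, masses)


# ---------------------------------------------------------------------------
# expected counts under censoring
# ---------------------------------------------------------------------------

def _constraint_fracs(f: PiecewiseDensity, v1, d1, v2, d2):
    """Per-observation cell-coverage fractions of the feasible set.

    Fully observed coordinates give a one-hot column (the resolution cell of
    the density that contains V); censored coordinates give the fractional
    coverage of (V, inf) -- exact because the density is constant per cell.
    """
    e1, e2 = f.edges1, f.edges2
    n = len(v1)
    frac1 = np.empty((n, len(e1) - 1))
    frac2 = np.empty((n, len(e2) - 1))
    for fr, e, v, d in ((frac1, e1, v1, d1), (frac2, e2, v2, d2)):
        obs_rows = d == 1
        fr[obs_rows] = 0.0
        idx = _cell_index(e, v[obs_rows])
        fr[np.nonzero(obs_rows)[0], idx] = 1.0
        cens = ~obs_rows
        left = np.maximum(e[:-1][None, :], v[cens, None])
        fr[cens] = np.clip((e[1:][None, :] - left) / np.diff(e)[None, :], 0.0, 1.0)
    return frac1, frac2


def expected_count_grid(f: PiecewiseDensity, obs: pd.DataFrame,
                        edges1=None, edges2=None):
    """Aggregate expected-count grid M with M[i, j] = N(cell_ij | f).

    Each observation contributes a unit of posterior mass distributed over
    its feasible cells proportionally to f.  Fully observed samples are point
    masses; singly censored samples live on the column (row) of cells through
    V with the other coordinate truncated; doubly censored samples live on
    the upper quadrant.  Observations whose feasible set carries zero mass
    under f fall back to the nearest positive-mass cell (counted and
    returned).

    Returns ``(M, n_fallback)``.
    """
    if edges1 is not None:
        f = f.refine(edges1, edges2)
    e1, e2 = f.edges1, f.edges2
    F = f.masses
    v1 = obs["v1"].to_numpy(dtype=float)
    v2 = obs["v2"].to_numpy(dtype=float)
    d1 = obs["delta1"].to_numpy(dtype=int)
    d2 = obs["delta2"].to_numpy(dtype=int)

    M = np.zeros_like(F)
    both = (d1 == 1) & (d2 == 1)
    if both.any():
        np.add.at(M, (_cell_index(e1, v1[both]), _cell_index(e2, v2[both])), 1.0)

    cens = ~both
    n_fallback = 0
    if cens.any():
        frac1, frac2 = _constraint_fracs(f, v1[cens], d1[cens], v2[cens], d2[cens])
        z = np.einsum("ka,ab,kb->k", frac1, F, frac2)
        ok = z > _EPS_MASS
        if ok.any():
            M += F * (frac1[ok].T @ (frac2[ok] / z[ok, None]))
        if (~ok).any():
            # zero feasible mass under f: snap to the nearest positive cell
            c1 = 0.5 * (e1[:-1] + e1[1:])
            c2 = 0.5 * (e2[:-1] + e2[1:])
            pos = np.argwhere(F > _EPS_MASS)
            for k in np.nonzero(~ok)[0]:
                x, y = v1[cens][k], v2[cens][k]
                d2_ = (c1[pos[:, 0]] - x) ** 2 + (c2[pos[:, 1]] - y) ** 2
                i, j = pos[np.argmin(d2_)]
                M[i, j] += 1.0
                n_fallback += 1
    return M, n_fallback


def expected_counts(f: PiecewiseDensity, obs: pd.DataFrame, region: Region) -> float:
    """Expected number of samples in ``region`` given the density f."""
    M, _ = expected_count_grid(f, obs)
    f1 = _overlap_frac(f.edges1, region.lo1, region.hi1)
    f2 = _overlap_frac(f.edges2, region.lo2, region.hi2)
    return float(f1 @ M @ f2)


# ---------------------------------------------------------------------------
# the OPT recursion
# ---------------------------------------------------------------------------

@dataclass
class PartitionNode:
    region: Region
    n_expected: float
    phi: float  # log Phi(A)
    phi0: float  # log Phi0(A)
    split_axis: Optional[int]  # 1, 2 or None for a leaf
    children: Optional[tuple] = None
    is_uniform: bool = False
    split_terms: dict = field(default_factory=dict)  # log split term per axis

    def leaves(self):
        if self.children is None:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


def decide_partition(n_expected: float, log_phi0: float, split_terms: dict) -> object:
    """Stop-vs-split decision for one rectangle.

    Returns ``"uniform"`` when 1/2 Phi0 exceeds the summed split term (or the
    rectangle is terminal), otherwise the axis (1 or 2) whose weighted child
    product is larger; ties break toward axis 1.
    """
    if n_expected < 2 or not split_terms:
        return "uniform"
    log_split = logsumexp(list(split_terms.values()))
    if _LOG_HALF + log_phi0 > _LOG_QUARTER + log_split:
        return "uniform"
    t1 = split_terms.get(1, -np.inf)
    t2 = split_terms.get(2, -np.inf)
    return 1 if t1 >= t2 else 2


def opt_build(counts_fn: Callable[[Region], float], omega: Region,
              max_depth: int = 8) -> PartitionNode:
    """Evaluate the OPT recursion on midpoint splits and return the decided
    partition tree.

    ``counts_fn`` maps a rectangle to its (expected) sample count and must be
    additive over partitions.  Rectangles are tracked by dyadic indices
    (level, offset) per axis so that no floating-point drift accumulates.
    Terminal rectangles (count < 2, or both axes at ``max_depth``) take
    Phi = Phi0.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    w1 = omega.hi1 - omega.lo1
    w2 = omega.hi2 - omega.lo2

    def region_of(l1, i1, l2, i2) -> Region:
        s1, s2 = w1 / (1 << l1), w2 / (1 << l2)
        return Region(omega.lo1 + i1 * s1, omega.lo1 + (i1 + 1) * s1,
                      omega.lo2 + i2 * s2, omega.lo2 + (i2 + 1) * s2)

    memo = {}

    def phi(l1, i1, l2, i2):
        key = (l1, i1, l2, i2)
        rec = memo.get(key)
        if rec is not None:
            return rec
        reg = region_of(l1, i1, l2, i2)
        n = counts_fn(reg)
        lp0 = -n * math.log(reg.area)
        if n < 2 or (l1 >= max_depth and l2 >= max_depth):
            rec = (lp0, lp0, n, {})
        else:
            terms = {}
            if l1 < max_depth:
                a = phi(l1 + 1, 2 * i1, l2, i2)
                b = phi(l1 + 1, 2 * i1 + 1, l2, i2)
                terms[1] = (betaln(a[2] + 0.5, b[2] + 0.5) - _BETALN_HALF
                            + a[0] + b[0])
            if l2 < max_depth:
                a = phi(l1, i1, l2 + 1, 2 * i2)
                b = phi(l1, i1, l2 + 1, 2 * i2 + 1)
                terms[2] = (betaln(a[2] + 0.5, b[2] + 0.5) - _BETALN_HALF
                            + a[0] + b[0])
            log_split = logsumexp(list(terms.values()))
            log_phi = np.logaddexp(_LOG_HALF + lp0, _LOG_QUARTER + log_split)
            rec = (float(log_phi), lp0, n, terms)
        memo[key] = rec
        return rec

    phi(0, 0, 0, 0)

    def build(l1, i1, l2, i2) -> PartitionNode:
        log_phi, lp0, n, terms = memo[(l1, i1, l2, i2)]
        reg = region_of(l1, i1, l2, i2)
        decision = decide_partition(n, lp0, terms)
        if decision == "uniform":
            return PartitionNode(reg, n, log_phi, lp0, None,
                                 is_uniform=True, split_terms=terms)
        if decision == 1:
            kids = (build(l1 + 1, 2 * i1, l2, i2), build(l1 + 1, 2 * i1 + 1, l2, i2))
        else:
            kids = (build(l1, i1, l2 + 1, 2 * i2), build(l1, i1, l2 + 1, 2 * i2 + 1))
        return PartitionNode(reg, n, log_phi, lp0, decision,
                             children=kids, split_terms=terms)

    return build(0, 0, 0, 0)


def extract_density(tree: PartitionNode, n_total: float) -> PiecewiseDensity:
    """Piecewise-constant density from the decided tree: leaf density
    N(A) / (n_total |A|), renormalised to integrate to exactly one."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    leaves = list(tree.leaves())
    total = sum(leaf.n_expected for leaf in leaves)
    if total <= 0:
        raise ValueError("tree carries zero total mass")
    edges1 = np.unique(np.concatenate(
        [[leaf.region.lo1, leaf.region.hi1] for leaf in leaves]))
    edges2 = np.unique(np.concatenate(
        [[leaf.region.lo2, leaf.region.hi2] for leaf in leaves]))
    masses = np.zeros((len(edges1) - 1, len(edges2) - 1))
    leaf_list = []
    for leaf in leaves:
        r = leaf.region
        dens = leaf.n_expected / (n_total * r.area)
        leaf_list.append((r, dens * n_total / total))  # normalised density
        i0, i1 = np.searchsorted(edges1, [r.lo1, r.hi1])
        j0, j1 = np.searchsorted(edges2, [r.lo2, r.hi2])
        areas = np.outer(np.diff(edges1[i0:i1 + 1]), np.diff(edges2[j0:j1 + 1]))
        masses[i0:i1, j0:j1] = dens * areas
    return PiecewiseDensity(edges1, edges2, masses, leaves=leaf_list)


# ---------------------------------------------------------------------------
# the censored fixed point
# ---------------------------------------------------------------------------

@dataclass
class OptFit:
    density: PiecewiseDensity
    tree: PartitionNode
    tv_history: list
    n_iter: int
    converged: bool
    n_fallback: int = 0


def _prefix_counts_fn(M: np.ndarray, omega: Region):
    """O(1) rectangle count queries for dyadic-aligned regions via a padded
    2-d prefix sum of the expected-count grid."""
    P = np.zeros((M.shape[0] + 1, M.shape[1] + 1))
    P[1:, 1:] = M.cumsum(0).cumsum(1)
    m1, m2 = M.shape
    w1 = omega.hi1 - omega.lo1
    w2 = omega.hi2 - omega.lo2

    def counts(region: Region) -> float:
        a = int(round((region.lo1 - omega.lo1) / w1 * m1))
        b = int(round((region.hi1 - omega.lo1) / w1 * m1))
        c = int(round((region.lo2 - omega.lo2) / w2 * m2))
        d = int(round((region.hi2 - omega.lo2) / w2 * m2))
        return float(P[b, d] - P[a, d] - P[b, c] + P[a, c])

    return counts


def fit_joint(obs: pd.DataFrame, max_depth: int = 8, max_iter: int = 20,
              tol: float = 1e-3, omega: Optional[Region] = None) -> OptFit:
    """Iterate expected counts -> OPT -> density until the total-variation
    distance between successive densities drops below ``tol``.

    With no censoring the expected counts equal the observed counts and the
    iteration is stationary after the first OPT build.  Non-convergence at
    ``max_iter`` returns the last iterate with ``converged=False``.
    """
    if len(obs) < 2:
        raise ValueError("fit_joint requires at least 2 observations")
    if omega is None:
        omega = default_domain(obs)
    e1 = _dyadic_edges(omega.lo1, omega.hi1, max_depth)
    e2 = _dyadic_edges(omega.lo2, omega.hi2, max_depth)

    f = initial_joint(obs, omega, depth=max_depth)
    tv_history: list[float] = []
    n_fallback = 0
    tree = None
    converged = False
    for _ in range(max_iter):
        M, n_fb = expected_count_grid(f, obs, e1, e2)
        n_fallback += n_fb
        tree = opt_build(_prefix_counts_fn(M, omega), omega, max_depth)
        f_new = extract_density(tree, n_total=len(obs))
        tv = f.tv_distance(f_new)
        tv_history.append(tv)
        f = f_new
        if tv < tol:
            converged = True
            break
    return OptFit(density=f, tree=tree, tv_history=tv_history,
                  n_iter=len(tv_history), converged=converged,
                  n_fallback=n_fallback)


# ---------------------------------------------------------------------------
# JSON round-trip for fitted densities
# ---------------------------------------------------------------------------

def density_to_json(f: PiecewiseDensity, path=None) -> str:
    payload = {
        "leaves": [
            {"lo1": r.lo1, "hi1": r.hi1, "lo2": r.lo2, "hi2": r.hi2, "density": d}
            for r, d in f.leaves
        ]
    }
    text = json.dumps(payload)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def density_from_json(source) -> PiecewiseDensity:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    leaves = [
        (Region(d["lo1"], d["hi1"], d["lo2"], d["hi2"]), d["density"])
        for d in payload["leaves"]
    ]
    edges1 = np.unique(np.concatenate([[r.lo1, r.hi1] for r, _ in leaves]))
    edges2 = np.unique(np.concatenate([[r.lo2, r.hi2] for r, _ in leaves]))
    masses = np.zeros((len(edges1) - 1, len(edges2) - 1))
    for r, dens in leaves:
        i0, i1 = np.searchsorted(edges1, [r.lo1, r.hi1])
        j0, j1 = np.searchsorted(edges2, [r.lo2, r.hi2])
        areas = np.outer(np.diff(edges1[i0:i1 + 1]), np.diff(edges2[j0:j1 + 1]))
        masses[i0:i1, j0:j1] = dens * areas
    return PiecewiseDensity(edges1, edges2, masses, leaves=leaves)
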