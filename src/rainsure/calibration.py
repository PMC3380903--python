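"""Calibrate per-dekad minimum water requirements (MWRs) for a rainfall
deficit index.

For one soil within one pixel (a *run*), the calibration substrate is a
table of simulated seasons: dekadal rainfall plus water-limited yield.
Each dekad has an MWR, the rainfall below which the crop loses yield.  A
season's deficit in a dekad is ``min(rain - MWR, 0)`` -- surpluses are
ignored -- and the season total is the sum over dekads, so totals are
always <= 0 and more negative means droughtier.

Only the driest quarter of seasons carries information about where yield
loss begins: the upper and middle yield quartiles sit above every
well-chosen MWR and have zero deficit.  The MWR vector is therefore fitted
on the lowest yield quartile, maximizing the squared Pearson correlation
between season total deficit and yield subject to MWR >= 0 elementwise.
The sum of the fitted MWRs is the season's rainfall index in mm -- the
quantity an insurance contract prints as its MIN row.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .cropmodel import rain_matrix
from .weathergen import DekadalSeason

__all__ = [
    "DeficitResult", "CalibrationResult", "compute_deficit", "deficit_totals",
    "lowest_quartile", "top_quartile", "initial_mwr", "calibrate_mwr",
    "calibrate_run", "rainfall_index", "r_squared",
]


def as_mwr(values) -> np.ndarray:
    """Validate an MWR vector: 1-d, finite, elementwise >= 0."""
    m = np.asarray(values, dtype=float)
    if m.ndim != 1 or m.size == 0:
        raise ValueError("MWR must be a non-empty 1-d vector")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("MWR entries must be finite and >= 0")
    return m


@dataclass(frozen=True)
class DeficitResult:
    """Per-dekad and total rainfall deficit (mm, <= 0) of one season."""

    per_dekad: np.ndarray
    total: float


def compute_deficit(season: DekadalSeason | np.ndarray, mwr) -> DeficitResult:
    """Dekadal deficits ``min(rain - MWR, 0)`` and their season total."""
    rain = np.asarray(getattr(season, "rain_mm", season), dtype=float)
    m = as_mwr(mwr)
    if rain.shape != m.shape:
        raise ValueError(
            f"season has {rain.size} dekads but MWR has {m.size} entries")
    d = np.minimum(rain - m, 0.0)
    return DeficitResult(per_dekad=d, total=float(d.sum()))


def deficit_totals(rain: np.ndarray, mwr: np.ndarray) -> np.ndarray:
    """Season total deficits for a (n_seasons, n_dekads) rainfall matrix."""
    return np.minimum(rain - mwr, 0.0).sum(axis=1)


def _quartile(runs: pd.DataFrame, lowest: bool) -> pd.DataFrame:
    if len(runs) < 4:
        raise ValueError(
            f"need at least 4 runs to take a quartile, got {len(runs)}")
    y = runs["yield"].to_numpy(dtype=float)
    k = len(runs) // 4
    order = np.argsort(-y if not lowest else y, kind="stable")
    if y[order[k - 1]] == y[order[k]]:
        warnings.warn(
            "tied yields at the quartile boundary; ties broken by stable "
            "input order", stacklevel=3)
    return runs.iloc[np.sort(order[:k])]


def lowest_quartile(runs: pd.DataFrame) -> pd.DataFrame:
    """The floor(n/4) lowest-yield rows, in stable input order."""
    return _quartile(runs, lowest=True)


def top_quartile(runs: pd.DataFrame) -> pd.DataFrame:
    """The floor(n/4) highest-yield rows, in stable input order."""
    return _quartile(runs, lowest=False)


def initial_mwr(runs: pd.DataFrame, quantile: float = 0.5) -> np.ndarray:
    """Plausible MWR start values: the per-dekad ``quantile`` of rainfall
    among the top-quartile-yield runs (default: median).

    High-yield seasons had enough water everywhere, so their typical dekad
    rainfall bounds the crop's requirement from above; a low quantile
    (e.g. 0) gives a conservative vector under which well-watered seasons
    show zero deficit.  Serves only as the optimizer start.
    """
    if runs.empty:
        raise ValueError("cannot estimate initial MWR from an empty run table")
    top = top_quartile(runs)
    return np.quantile(rain_matrix(top), quantile, axis=0)


def r_squared(totals, yields) -> float:
    """Squared Pearson correlation of total deficit with yield."""
    x = np.asarray(totals, dtype=float)
    y = np.asarray(yields, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("r_squared is undefined for constant input")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(1.0, r * r))


def rainfall_index(mwr) -> float:
    """The rainfall index (mm): sum of the per-dekad MWRs."""
    return float(as_mwr(mwr).sum())


@dataclass
class CalibrationResult:
    """Fitted MWR vector with its diagnostics.

    ``r2`` is the squared correlation of total deficit with yield over the
    calibration subset; ``index_mm`` the rainfall index (sum of MWRs).
    """

    mwr: np.ndarray
    r2: float
    index_mm: float
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"mwr": np.asarray(self.mwr).tolist(), "r2": self.r2,
                "index_mm": self.index_mm, "diagnostics": self.diagnostics}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mwr=np.asarray(d["mwr"], dtype=float), r2=d["r2"],
                   index_mm=d["index_mm"], diagnostics=d.get("diagnostics", {}))


def _objective(mwr: np.ndarray, rain: np.ndarray, yields: np.ndarray) -> float:
    t = deficit_totals(rain, mwr)
    sx = t.std()
    if sx == 0.0:
        return 0.0
    r = np.corrcoef(t, yields)[0, 1]
    return float(min(1.0, r * r))


def _penalized(mwr: np.ndarray, rain: np.ndarray, yields: np.ndarray,
               anchor_rain: np.ndarray | None, slack_mm: float,
               weight: float) -> float:
    """Search objective: r^2 minus a level-anchoring penalty.

    The correlation is invariant to shifting a dekad's deficits by a
    constant, so r^2 alone leaves the MWR *level* undetermined: an entry
    above every season's rainfall turns the index into a shifted rainfall
    sum with absurd deficits in normal years.  The anchor resolves this
    the way the index is meant to behave -- non-drought (upper and middle
    yield quartile) seasons should carry essentially zero deficit -- by
    charging ``weight`` per mm that the median anchor-season total deficit
    falls below ``-slack_mm``.
    """
    f = _objective(mwr, rain, yields)
    if anchor_rain is None:
        return f
    med = float(np.median(deficit_totals(anchor_rain, mwr)))
    return f - weight * max(0.0, -med - slack_mm)


def calibrate_mwr(runs: pd.DataFrame,
                  init=None,
                  n_starts: int = 8,
                  seed: int = 0,
                  tol: float = 1e-8,
                  max_iter: int = 2000,
                  anchor_rain: np.ndarray | None = None,
                  anchor_slack_mm: float = 10.0,
                  anchor_weight: float = 0.01) -> CalibrationResult:
    """Optimize the MWR vector on a lowest-quartile run subset.

    Maximizes the squared Pearson correlation between season total deficit
    and yield, with every MWR entry bounded below by 0.  The objective is
    piecewise smooth with kinks wherever an MWR entry crosses a season's
    rainfall, so a gradient-free bounded simplex search (Nelder-Mead) is
    restarted from ``n_starts`` diverse start points (``init``, per-dekad
    rainfall quantiles of the subset, and jittered copies of ``init``
    whose order is fixed by ``seed``, so results are deterministic), then
    re-launched from the incumbent until it stops improving, and finished
    with a coordinate-wise golden-section polish across the kinks.  The
    returned objective is never below the objective at ``init``; ties
    between starts go to the earliest.

    Two objective-preserving canonicalisations resolve the optimum's
    plateaus: an entry above every season's rainfall only shifts that
    dekad's deficits by a constant, so entries are capped at the subset's
    per-dekad rainfall maximum; and an entry that binds no season is
    snapped to 0, zeroing dekads the data say nothing about.

    ``anchor_rain`` (the dekadal rainfall of the runs *outside* the
    calibration subset, i.e. the upper and middle yield quartiles) anchors
    the MWR level: the correlation alone is blind to constant shifts of a
    dekad's deficits, while the index is meant to show essentially zero
    deficit in non-drought years.  Candidates whose median anchor-season
    total deficit falls below ``-anchor_slack_mm`` are penalised at
    ``anchor_weight`` per mm.  The reported ``r2`` is always the pure
    squared correlation on the calibration subset.
    """
    rain = rain_matrix(runs)
    y = runs["yield"].to_numpy(dtype=float)
    if y.std() == 0.0:
        raise ValueError(
            "zero yield variance in the calibration subset: the deficit-"
            "yield correlation is undefined")
    n_dekads = rain.shape[1]
    inits = [np.median(rain, axis=0)] if init is None else [
        as_mwr(v) for v in (init if isinstance(init, (list, tuple)) else [init])]
    if any(v.size != n_dekads for v in inits):
        raise ValueError("init length does not match the run table's dekads")
    init = inits[0]

    rng = np.random.default_rng(seed)
    starts = inits + [np.quantile(rain, q, axis=0) for q in (0.25, 0.5, 0.75)]
    while len(starts) < max(1, n_starts):
        jitter = init * rng.uniform(0.5, 1.5, n_dekads) + rng.uniform(0.0, 15.0, n_dekads)
        starts.append(np.maximum(jitter, 0.0))
    starts = starts[:max(len(inits), n_starts)]

    bounds = [(0.0, None)] * n_dekads
    neg = lambda m: -_penalized(m, rain, y, anchor_rain,
                                anchor_slack_mm, anchor_weight)

    def local_search(x0):
        return optimize.minimize(
            neg, x0, method="Nelder-Mead", bounds=bounds,
            options={"maxiter": max_iter, "fatol": min(tol, 1e-10),
                     "xatol": 1e-8})

    best_x, best_f = init, -neg(init)
    objectives, n_iters, converged = [best_f], [0], [True]
    for x0 in starts:
        res = local_search(x0)
        objectives.append(-res.fun)
        n_iters.append(int(res.nit))
        converged.append(bool(res.success))
        if -res.fun > best_f + 1e-15:
            best_f, best_x = -res.fun, np.maximum(res.x, 0.0)

    # the simplex can stall on a kink: relaunch from the incumbent
    for _ in range(6):
        res = local_search(best_x)
        if -res.fun <= best_f + tol:
            break
        best_f, best_x = -res.fun, np.maximum(res.x, 0.0)

    # coordinate-wise polish: the 1-d restriction has its kinks exactly at
    # the subset's rainfall values, so scan every breakpoint interval and
    # refine the best one by golden section
    best_x = best_x.copy()
    for _ in range(10):
        improved = False
        for d in range(n_dekads):
            pts = np.unique(np.concatenate(
                [[0.0], np.sort(rain[:, d]), [rain[:, d].max() + 1.0]]))
            cands = np.concatenate([pts, (pts[:-1] + pts[1:]) / 2])
            m = best_x.copy()
            vals = np.empty(cands.size)
            for j, v in enumerate(cands):
                m[d] = v
                vals[j] = neg(m)
            j = int(np.argmin(vals))
            if vals[j] < -(best_f + 1e-12):
                def f1(v, d=d):
                    mm = best_x.copy()
                    mm[d] = v
                    return neg(mm)
                r = optimize.minimize_scalar(
                    f1, bounds=(max(0.0, cands[j] - 10.0), cands[j] + 10.0),
                    method="bounded", options={"xatol": 1e-7})
                if r.fun < vals[j]:
                    best_x[d], best_f = max(0.0, float(r.x)), -r.fun
                else:
                    best_x[d], best_f = float(cands[j]), -vals[j]
                improved = True
        if not improved:
            break

    # canonicalise the plateaus: cap entries at the per-dekad rainfall
    # maximum (beyond it they only shift deficits by a constant), then
    # zero entries that bind no season
    mwr = np.minimum(np.maximum(best_x, 0.0), rain.max(axis=0))
    nonbinding = (rain >= mwr).all(axis=0)
    mwr[nonbinding] = 0.0
    r2 = _objective(mwr, rain, y)
    diagnostics = {
        "n_starts": len(starts), "objective_trace": objectives,
        "iterations": n_iters, "converged": converged,
        "all_converged": all(converged), "n_runs": int(len(runs)),
    }
    if anchor_rain is not None:
        diagnostics["anchor_median_deficit_mm"] = float(
            np.median(deficit_totals(np.asarray(anchor_rain, dtype=float), mwr)))
    return CalibrationResult(mwr=mwr, r2=r2, index_mm=rainfall_index(mwr),
                             diagnostics=diagnostics)


def calibrate_run(runs: pd.DataFrame, n_starts: int = 10, seed: int = 0,
                  anchored: bool = True) -> CalibrationResult:
    """Full single-run calibration: initial MWR heuristics from the
    top-yield quartile (several quantiles, from the default median down to
    conservative low-quantile vectors under which good years show no
    deficit), then optimization on the lowest yield quartile, with the
    MWR level anchored so the upper and middle quartiles keep near-zero
    deficits (``anchored=False`` drops the anchor)."""
    low = lowest_quartile(runs)
    anchor = rain_matrix(runs.drop(low.index)) if anchored else None
    inits = [initial_mwr(runs, quantile=q) for q in (0.5, 0.25, 0.1)]
    return calibrate_mwr(low, init=inits, n_starts=n_starts, seed=seed,
                         anchor_rain=anchor)
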