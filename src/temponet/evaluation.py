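"""Scoring static representations against the temporal ground truth.

A representation is good if a cheap static predictor of spreading importance
(degree or coreness of the derived graph) ranks vertices the same way as the
expensive temporal truth: the expected outbreak size sigma_i of SIR runs on
the original contact sequence.  The score is the Spearman rank correlation
rho between the two, computed over *all* vertices of the original data —
vertices absent from the derived network enter with predictor value 0, so
that rho is comparable across representations with different edge sets.

``scan`` evaluates rho over a parameter grid (windows as fractions of T, or
log-spaced decay times tau with thresholds Omega) and reports the surface,
the argmax and rho_max with a bootstrap standard error resampled from the
run-level outbreak sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactSequence, UndefinedStatisticError
from . import netstats
from .representations import (
    ExpThreshParams,
    WindowParams,
    accumulated,
    exp_threshold,
    ongoing,
    time_slice,
)
from .sir import ImportanceTable

__all__ = [
    "ScanGrid",
    "ScanResult",
    "spearman",
    "performance",
    "scan",
    "window_grid",
    "exp_threshold_grid",
    "build_representation",
]

ParamPoint = Union[WindowParams, ExpThreshParams, None]

_REPRESENTATIONS = ("time_slice", "ongoing", "exp_threshold", "accumulated")


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties get average ranks.  Raises :class:`UndefinedStatisticError` when a
    vector is constant after ranking (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("constant vector: rho undefined")
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        raise UndefinedStatisticError("rho undefined on this input")
    return float(rho)


def build_representation(cs: ContactSequence, kind: str,
                         params: ParamPoint) -> nx.Graph:
    """Dispatch to the representation named by ``kind``."""
    if kind == "time_slice":
        return time_slice(cs, params)
    if kind == "ongoing":
        return ongoing(cs, params)
    if kind == "exp_threshold":
        return exp_threshold(cs, params)
    if kind == "accumulated":
        return accumulated(cs)
    raise ValueError(f"unknown representation {kind!r}; "
                     f"expected one of {_REPRESENTATIONS}")


def _predictor_vector(cs: ContactSequence, net: nx.Graph,
                      predictor: str) -> np.ndarray:
    if predictor == "degree":
        values = netstats.degree(net)
    elif predictor == "coreness":
        values = netstats.coreness(net)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    # vertices of the original data missing from the static net predict 0
    return np.array([values.get(lab, 0) for lab in cs.labels], dtype=float)


def performance(cs: ContactSequence, net: nx.Graph, imp: ImportanceTable,
                predictor: str = "degree") -> float:
    """rho between sigma_i and the static predictor over all data vertices."""
    sigma = imp.as_dict()
    try:
        truth = np.array([sigma[lab] for lab in cs.labels])
    except KeyError as missing:
        raise ValueError(f"importance table lacks vertex {missing}")
    return spearman(_predictor_vector(cs, net, predictor), truth)


@dataclass(frozen=True)
class ScanGrid:
    """A representation kind plus the parameter points to evaluate."""

    kind: str
    points: tuple[ParamPoint, ...]

    def __post_init__(self):
        if self.kind not in _REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.kind!r}")
        if not self.points:
            raise ValueError("empty scan grid")


@dataclass(frozen=True)
class ScanResult:
    """The rho surface of a scan, its argmax and rho_max +/- se.

    ``table`` is long-format: one row per grid point with the parameters,
    rho and its bootstrap standard error; undefined (degenerate) points are
    kept as rows with NaN rho, never silently dropped.
    """

    kind: str
    table: pd.DataFrame
    argmax: ParamPoint
    rho_max: float
    se_max: float


def window_grid(kind: str, n: int = 21, T: float = 1.0) -> ScanGrid:
    """Triangular n x n grid of (t_start, t_stop) fractions of T, scaled to
    native time units by ``T`` (the grid always contains the full window)."""
    fracs = np.linspace(0.0, 1.0, n)
    points = [WindowParams(a * T, b * T)
              for a in fracs for b in fracs if a <= b]
    return ScanGrid(kind, tuple(points))


def exp_threshold_grid(tau_fracs: Iterable[float] | None = None,
                       omegas: Iterable[float] | None = None,
                       T: float = 1.0) -> ScanGrid:
    """Log-spaced tau/T values crossed with a set of thresholds Omega."""
    if tau_fracs is None:
        tau_fracs = np.logspace(-2, 1, 16)
    if omegas is None:
        omegas = np.logspace(-2, 1, 16)
    points = [ExpThreshParams(tau=f * T, omega=w)
              for f in tau_fracs for w in omegas]
    return ScanGrid("exp_threshold", tuple(points))


def _point_record(kind: str, p: ParamPoint) -> dict:
    if isinstance(p, WindowParams):
        return {"t_start": p.t_start, "t_stop": p.t_stop}
    if isinstance(p, ExpThreshParams):
        return {"tau": p.tau, "omega": p.omega}
    return {}


def _bootstrap_se(pred: np.ndarray, samples: np.ndarray, n_boot: int,
                  rng: np.random.Generator) -> float:
    """Bootstrap se of rho by resampling each vertex's run-level sizes."""
    n_vertices, n_runs = samples.shape
    rhos = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_runs, size=(n_vertices, n_runs))
        means = np.take_along_axis(samples, idx, axis=1).mean(axis=1)
        try:
            rhos[b] = spearman(pred, means)
        except UndefinedStatisticError:
            rhos[b] = np.nan
    return float(np.nanstd(rhos, ddof=1))


def scan(cs: ContactSequence, imp: ImportanceTable, grid: ScanGrid,
         predictor: str = "degree", n_boot: int = 200,
         n_boot_surface: int = 0, rng_seed: int = 0) -> ScanResult:
    """Evaluate rho at every grid point and locate the maximum.

    Degenerate points (edgeless or constant-predictor networks) are recorded
    with NaN rho, never silently dropped.  ``n_boot`` resamples of the
    per-seed run-level outbreak sizes give the standard error at the argmax
    (0 skips it); ``n_boot_surface`` does the same for every grid point,
    which is proportionally more expensive and off by default.
    """
    rng = np.random.default_rng(rng_seed)
    sigma = imp.as_dict()
    try:
        truth = np.array([sigma[lab] for lab in cs.labels])
    except KeyError as missing:
        raise ValueError(f"importance table lacks vertex {missing}")
    samples = None
    if imp.samples is not None:
        row_of = {lab: k for k, lab in enumerate(imp.labels)}
        samples = imp.samples[[row_of[lab] for lab in cs.labels]]
    rows = []
    preds: list[Optional[np.ndarray]] = []
    best_rho = -np.inf
    best_point: ParamPoint = None
    best_pred: Optional[np.ndarray] = None
    for p in grid.points:
        rec = _point_record(grid.kind, p)
        net = build_representation(cs, grid.kind, p)
        try:
            pred = _predictor_vector(cs, net, predictor)
            rho = spearman(pred, truth)
        except (UndefinedStatisticError, ValueError):
            rec.update(rho=np.nan, se=np.nan)
            rows.append(rec)
            preds.append(None)
            continue
        rec.update(rho=rho, se=np.nan)
        rows.append(rec)
        preds.append(pred)
        if rho > best_rho:
            best_rho, best_point, best_pred = rho, p, pred
    if not np.isfinite(best_rho):
        raise RuntimeError("scan failed: rho undefined at every grid point")
    se_max = np.nan
    if samples is not None:
        if n_boot_surface > 0:
            for rec, pred in zip(rows, preds):
                if pred is not None:
                    rec["se"] = _bootstrap_se(pred, samples,
                                              n_boot_surface, rng)
        if n_boot > 0:
            se_max = _bootstrap_se(best_pred, samples, n_boot, rng)
    table = pd.DataFrame(rows)
    return ScanResult(kind=grid.kind, table=table, argmax=best_point,
                      rho_max=float(best_rho), se_max=float(se_max))
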