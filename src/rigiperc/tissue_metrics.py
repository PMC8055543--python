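"""Tissue-level observables computed from tabular inputs.

Covers the quantifications applied to the experimental recordings:
connectivity of cell-contact maps, cell fraction, mean squared relative
displacement (MSRD) of cell pairs, cell shape index, the spatial
heterogeneity coefficient of cell divisions against a binomial null, and
tissue viscosity from micropipette-aspiration creep/recovery traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError
from .lattice import (
    ConnectivityReport,
    Lattice,
    max_connectivity,
    max_connectivity_bulk,
)

__all__ = [
    "ContactMap",
    "AspirationTrace",
    "QuadrantCounts",
    "map_connectivity",
    "cell_fraction",
    "msrd",
    "shape_index",
    "spatial_heterogeneity",
    "mpa_viscosity",
    "variability_stats",
    "fold_change_bins",
]


@dataclass
class ContactMap:
    """A reconstructed cell-contact network at one timepoint.

    ``cells`` needs columns ``id, x, y`` (optionally ``area, perimeter``);
    ``contacts`` is an unordered pair list over cell ids.  ``timestamp`` is
    in minutes relative to the onset of tissue spreading.
    """

    cells: pd.DataFrame
    contacts: list[tuple[int, int]]
    timestamp: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        if not {"id", "x", "y"}.issubset(self.cells.columns):
            raise ValueError("cells table needs id, x, y columns")
        ids = set(self.cells["id"].astype(int))
        for u, v in self.contacts:
            if u == v or int(u) not in ids or int(v) not in ids:
                raise ValueError(f"bad contact ({u}, {v})")
        if not np.all(np.isfinite([self.timestamp])):
            raise ValueError("timestamp must be finite")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_lattice(self) -> Lattice:
        """Re-index to a Lattice for rigidity analysis."""
        order = {int(i): r for r, i in enumerate(self.cells["id"])}
        coords = self.cells[["x", "y"]].to_numpy(float)
        edges = [(order[int(u)], order[int(v)]) for u, v in self.contacts]
        n = self.n_cells
        L = int(round(math.sqrt(n + math.floor(math.sqrt(n)) / 2.0)))
        return Lattice(coords, edges, L=L,
                       meta={"timestamp": self.timestamp,
                             "condition": self.condition})


def map_connectivity(cmap: ContactMap, boundary: str = "sqrt") -> ConnectivityReport:
    """Connectivity of a contact map.

    ``<C> = 2 |contacts| / |cells|``; the maximum connectivity uses the
    square-patch boundary correction, by default at the real-valued side
    ``sqrt(N)`` (the package's normalization for criticality statistics).
    ``boundary="rows"`` instead infers an integer side
    ``L = round(sqrt(N + floor(sqrt(N))/2))`` so that ``N(L) ≈ N``.  Either
    way a map exported from a model lattice reports exactly the lattice's
    own numbers under the matching convention.
    """
    if cmap.n_cells < 1:
        raise ValueError("empty contact map")
    n = cmap.n_cells
    c = 2.0 * len(cmap.contacts) / n
    if boundary == "sqrt":
        cmax = max_connectivity_bulk(n) if n >= 3 else 2.0
    elif boundary == "rows":
        L = int(round(math.sqrt(n + math.floor(math.sqrt(n)) / 2.0)))
        cmax = max_connectivity(max(L, 2), n)
    else:
        raise ValueError("boundary must be 'sqrt' or 'rows'")
    return ConnectivityReport(c, cmax, c / cmax)


def cell_fraction(fluid_fraction: float) -> float:
    """Cell fraction ``cf = 1 - ff`` from the interstitial-fluid fraction."""
    if not 0.0 <= fluid_fraction <= 1.0:
        raise ValueError("fluid fraction must lie in [0, 1]")
    return 1.0 - fluid_fraction


def _traj_at(traj: pd.DataFrame, t: float) -> np.ndarray:
    cols = [c for c in ("x", "y", "z") if c in traj.columns]
    row = traj[np.isclose(traj["t"].to_numpy(float), t)]
    if row.empty:
        raise ValueError(f"trajectory has no sample at t={t}")
    return row.iloc[0][cols].to_numpy(float)


def msrd(traj_a: pd.DataFrame, traj_b: pd.DataFrame, t0: float, t1: float) -> float:
    """Mean squared relative displacement of a cell pair.

    The squared change, between ``t0`` and ``t1``, of the 3D distance
    between the two cells: ``(p_rel(t1) - p_rel(t0))^2``.  Invariant under
    rigid co-translation of the pair; zero for cells keeping their
    spacing.
    """
    d0 = float(np.linalg.norm(_traj_at(traj_a, t0) - _traj_at(traj_b, t0)))
    d1 = float(np.linalg.norm(_traj_at(traj_a, t1) - _traj_at(traj_b, t1)))
    return (d1 - d0) ** 2


def shape_index(perimeter: float, area: float) -> float:
    """Dimensionless cell shape index ``q = P / sqrt(A)``."""
    if perimeter <= 0 or area <= 0:
        raise ValueError("perimeter and area must be > 0")
    return perimeter / math.sqrt(area)


@dataclass(frozen=True)
class QuadrantCounts:
    """Total and dividing nuclei per image quadrant (I..IV)."""

    totals: tuple[int, int, int, int]
    dividing: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for N_i, n_i in zip(self.totals, self.dividing):
            if not 0 <= n_i <= N_i:
                raise ValueError("need 0 <= dividing <= total in each quadrant")


def spatial_heterogeneity(counts: QuadrantCounts) -> float | None:
    """Spatial heterogeneity coefficient of cell divisions.

    Two-stage binomial null: a dividing cell falls in each quadrant with
    probability 1/4 and each cell divides with the pooled probability
    ``q = n/N``; the null standard deviation of per-quadrant dividing
    counts is ``(1/2) sqrt(n (1 - q))``.  The SHC is the variance of the
    four absolute z-scores ``|n_i - n/4| / std``.  Returns None (missing)
    when no division occurred.
    """
    n = sum(counts.dividing)
    N = sum(counts.totals)
    if n == 0:
        return None
    q = n / N
    expected = n / 4.0
    std = 0.5 * math.sqrt(n * (1.0 - q))
    if std == 0.0:
        return None
    z = np.abs((np.asarray(counts.dividing, float) - expected) / std)
    return float(np.var(z, ddof=1))


@dataclass
class AspirationTrace:
    """Micropipette aspiration creep/recovery recording.

    ``t`` in seconds, tongue deformation ``d`` in micrometres,
    ``pipette_radius`` in micrometres, ``pressure`` (applied aspiration
    pressure) in pascal.  ``release_time`` marks the pressure release; when
    absent the maximum of ``d`` is used.
    """

    t: np.ndarray
    d: np.ndarray
    pipette_radius: float
    pressure: float
    release_time: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.d = np.asarray(self.d, float)
        if self.t.shape != self.d.shape or self.t.ndim != 1:
            raise ValueError("t and d must be equal-length 1D arrays")
        if self.pipette_radius <= 0:
            raise ValueError("pipette radius must be > 0")
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")


def _longest_linear_window(
    t: np.ndarray, d: np.ndarray, r2_min: float = 0.98, min_points: int = 8
) -> tuple[float, slice]:
    """Slope of the longest window whose linear fit has R^2 >= r2_min.

    Windows are scanned from longest to shortest over a coarse grid of
    starts; flat segments (no resolvable slope) fail the R^2 gate.
    """
    n = len(t)
    if n < min_points:
        raise EstimationError("trace segment too short for a linear fit")
    lengths = np.unique(np.linspace(min_points, n, 12).astype(int))[::-1]
    for m in lengths:
        starts = range(0, n - m + 1, max(1, (n - m) // 10 + 1))
        best = None
        for s in starts:
            tt, dd = t[s:s + m], d[s:s + m]
            slope, icept = np.polyfit(tt, dd, 1)
            resid = dd - (slope * tt + icept)
            ss_tot = float(np.sum((dd - dd.mean()) ** 2))
            if ss_tot == 0:
                continue
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
            if r2 >= r2_min and (best is None or r2 > best[0]):
                best = (r2, slope, slice(s, s + m))
        if best is not None:
            return best[1], best[2]
    raise EstimationError("no constant-flow window found (R^2 gate not met)")


def mpa_viscosity(trace: AspirationTrace) -> float:
    """Tissue viscosity from an aspiration creep/recovery trace.

    Fits the constant-flow slope during aspiration (``Ldot_asp``) and the
    retraction slope after release (``Ldot_ret``, magnitude of the
    negative slope); then ``eta = Rp dP / (3 pi (Ldot_asp + Ldot_ret))``
    in Pa.s for micrometre/second slopes.  A flat or missing retraction
    phase contributes zero (the aspiration rate dominates).
    """
    t_rel = trace.release_time
    if t_rel is None:
        t_rel = float(trace.t[int(np.argmax(trace.d))])
    asp = trace.t <= t_rel
    ret = trace.t > t_rel
    if asp.sum() < 8:
        raise EstimationError("aspiration phase too short")
    slope_asp, _ = _longest_linear_window(trace.t[asp], trace.d[asp])
    if slope_asp <= 0:
        raise EstimationError("aspiration slope is not positive")
    slope_ret = 0.0
    if ret.sum() >= 8:
        try:
            s, _ = _longest_linear_window(trace.t[ret], trace.d[ret])
            slope_ret = max(0.0, -s)
        except EstimationError:
            slope_ret = 0.0
    return trace.pipette_radius * trace.pressure / (
        3.0 * math.pi * (slope_asp + slope_ret))


def variability_stats(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Coefficient of variation and robustness factor per group.

    ``cv = sd/mean`` (sample sd); the robustness factor is ``1/cv``.
    Groups with fewer than two values or zero mean yield missing entries.
    """
    rows = []
    for g, vals in values_by_group.items():
        v = np.asarray(list(vals), float)
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs >= 2 values")
        mean = v.mean()
        if mean == 0:
            warnings.warn(f"group {g!r} has zero mean; CV undefined")
            cv = np.nan
        else:
            cv = float(v.std(ddof=1) / mean)
        rows.append((g, mean, cv, 1.0 / cv if cv and np.isfinite(cv) and cv > 0 else np.nan))
    return pd.DataFrame(rows, columns=["group", "mean", "cv", "robustness"])


FOLD_BINS = ("0-1", "1-5", "5-10", ">10")


def fold_change_bins(pairs: Iterable[tuple[float, float]]) -> pd.Series:
    """Histogram of viscosity fold-changes ``eta_t1 / eta_t2`` between
    consecutive timepoints, binned into 0-1, 1-5, 5-10, >10 (percent)."""
    counts = dict.fromkeys(FOLD_BINS, 0)
    n = 0
    for eta1, eta2 in pairs:
        if eta2 <= 0:
            raise ValueError("fold change needs positive reference viscosity")
        r = eta1 / eta2
        n += 1
        if r < 1:
            counts["0-1"] += 1
        elif r < 5:
            counts["1-5"] += 1
        elif r < 10:
            counts["5-10"] += 1
        else:
            counts[">10"] += 1
    if n == 0:
        raise ValueError("no pairs given")
    return pd.Series({k: 100.0 * v / n for k, v in counts.items()})
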