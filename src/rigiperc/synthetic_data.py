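"""Synthetic cohorts with the statistical structure of the experimental data.

Every generator carries its ground truth so that recovery tests can close
the loop: contact-map time series are jittered triangular patches diluted
to a scheduled connectivity trajectory (wild-type-like: drop below the
critical point around the onset of spreading, then recovery; a
Chk1-overexpression-like variant uses spatially correlated bond loss with
strength ``lambda``); aspiration traces are forward-simulated from the
creep-slope formulas; division maps draw quadrant counts from the
two-stage binomial null or a clustered alternative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import (
    CorrelationParams,
    Lattice,
    build_full_lattice,
    dilute_correlated,
    dilute_random,
    side_for_size,
)
from .tissue_metrics import AspirationTrace, ContactMap, QuadrantCounts

__all__ = [
    "SyntheticCohortSpec",
    "ContactMapSeries",
    "wt_spec",
    "chk1_spec",
    "synth_contact_series",
    "synth_mpa_trace",
    "synth_division_maps",
]

# Default normalized-connectivity trajectory, (minutes, <k>): high before
# spreading, minimum in the fluidization window around t = 0, recovery
# within the hour — the wild-type temporal profile.
DEFAULT_K_SCHEDULE: tuple[tuple[float, float], ...] = (
    (-60.0, 0.85), (-50.0, 0.83), (-40.0, 0.81), (-30.0, 0.78),
    (-20.0, 0.74), (-10.0, 0.66), (0.0, 0.60), (10.0, 0.66),
    (20.0, 0.70), (30.0, 0.72), (40.0, 0.74), (50.0, 0.77), (60.0, 0.80),
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for a cohort of synthetic contact maps.

    ``n_networks`` defaults to the cohort sizes used throughout (92
    wild-type-like, 95 Chk1-like); network sizes are drawn around a mean
    of ~100 cells; ``k_schedule`` is piecewise-linear in time;
    ``correlation`` is the spatial bond-loss correlation strength (0 for
    the wild-type-like condition, 0.47 for the Chk1-like one);
    ``jitter_sd`` (bond lengths) perturbs node positions for visual
    realism only — the topology is fixed before jitter.
    """

    condition: str = "wt"
    n_networks: int = 92
    size_mean: float = 100.0
    size_sd: float = 15.0
    k_schedule: tuple[tuple[float, float], ...] = DEFAULT_K_SCHEDULE
    k_sd: float = 0.02
    correlation: float = 0.0
    correlation_length: float = 1.0
    jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        ks = [k for _, k in self.k_schedule]
        if any(not 0.0 < k <= 1.0 for k in ks):
            raise ValueError("k schedule must lie in (0, 1]")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")

    def k_at(self, t: float) -> float:
        ts = np.array([p[0] for p in self.k_schedule])
        ks = np.array([p[1] for p in self.k_schedule])
        return float(np.interp(t, ts, ks))


def wt_spec(seed: int = 0, **overrides) -> SyntheticCohortSpec:
    """Wild-type-like cohort: 92 networks, random (uncorrelated) bond loss."""
    kwargs = {"condition": "wt", "n_networks": 92, "correlation": 0.0,
              "seed": seed}
    kwargs.update(overrides)
    return SyntheticCohortSpec(**kwargs)


def chk1_spec(seed: int = 0, **overrides) -> SyntheticCohortSpec:
    """Chk1-overexpression-like cohort: 95 networks, spatially correlated
    bond loss with strength 0.47."""
    kwargs = {"condition": "chk1", "n_networks": 95, "correlation": 0.47,
              "seed": seed}
    kwargs.update(overrides)
    return SyntheticCohortSpec(**kwargs)


@dataclass
class ContactMapSeries:
    """Synthetic contact maps plus the ground truth that generated them."""

    maps: list[ContactMap]
    ground_truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, cmap in enumerate(self.maps):
            doc = {
                "nodes": [
                    {"id": int(r.id), "x": float(r.x), "y": float(r.y)}
                    for r in cmap.cells.itertuples()
                ],
                "edges": [[int(u), int(v)] for u, v in cmap.contacts],
                "meta": {"timestamp": cmap.timestamp, "condition": cmap.condition},
            }
            (outdir / f"network_{i:03d}.json").write_text(json.dumps(doc))
        (outdir / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, default=float))


def synth_contact_series(spec: SyntheticCohortSpec) -> ContactMapSeries:
    """Generate a cohort of time-stamped synthetic contact maps.

    Networks cycle through the schedule's timepoints; each is a triangular
    patch (size drawn around ``size_mean``) diluted to the scheduled
    normalized connectivity (plus per-network noise ``k_sd``), randomly for
    ``correlation = 0`` and with correlated chains otherwise, then
    position-jittered.  Bit-reproducible given the spec (which includes
    its seed).
    """
    rng = np.random.default_rng(spec.seed)
    times = [p[0] for p in spec.k_schedule]
    params = CorrelationParams(spec.correlation_length, spec.correlation)
    maps: list[ContactMap] = []
    truth_rows = []
    lat_cache: dict[int, Lattice] = {}
    for i in range(spec.n_networks):
        t = times[i % len(times)]
        n_req = int(np.clip(rng.normal(spec.size_mean, spec.size_sd), 40, 250))
        L = side_for_size(n_req)
        full = lat_cache.setdefault(L, build_full_lattice(L))
        N = full.n_nodes
        k = float(np.clip(spec.k_at(t) + rng.normal(0.0, spec.k_sd), 0.05, 1.0))
        target_C = k * full.mean_connectivity  # bond-occupation target
        sub_seed = int(rng.integers(2**31))
        if spec.correlation == 0.0:
            dil = dilute_random(full, target_C, seed=sub_seed)
        else:
            dil = dilute_correlated(full, target_C, params, seed=sub_seed)
        coords = dil.coords + rng.normal(0.0, spec.jitter_sd, size=dil.coords.shape)
        cells = pd.DataFrame({"id": np.arange(N), "x": coords[:, 0],
                              "y": coords[:, 1]})
        maps.append(ContactMap(cells, list(dil.edges), timestamp=t,
                               condition=spec.condition))
        truth_rows.append({"index": i, "timestamp": t, "N": N, "L": L,
                           "k_target": k, "seed": sub_seed})
    truth = {
        "spec": asdict(spec),
        "networks": truth_rows,
        "critical_k_scale": "max connectivity 6 - 8/sqrt(N)",
    }
    return ContactMapSeries(maps, truth)


def synth_mpa_trace(
    eta: float,
    pipette_radius: float = 17.5,
    pressure: float = 150.0,
    critical_pressure: float = 30.0,
    aspiration_s: float = 180.0,
    retraction_s: float = 120.0,
    dt_s: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AspirationTrace:
    """Forward-simulate an aspiration creep/recovery trace.

    Aspiration proceeds at the constant creep rate ``Ldot_asp = Rp (dP -
    Pc) / (3 pi eta)`` (micrometre/second for Pa and micrometre inputs)
    for ``aspiration_s`` seconds (3 min default), then the tongue retracts
    at ``Ldot_ret = Rp Pc / (3 pi eta)``; Gaussian noise of ``noise_sd``
    micrometres is added on top.  Sampling every 0.5 s.
    """
    if eta <= 0:
        raise ValueError("viscosity must be > 0")
    if not pressure > critical_pressure >= 0:
        raise ValueError("need pressure > critical_pressure >= 0 to aspirate")
    ldot_asp = pipette_radius * (pressure - critical_pressure) / (3.0 * math.pi * eta)
    ldot_ret = pipette_radius * critical_pressure / (3.0 * math.pi * eta)
    t = np.arange(0.0, aspiration_s + retraction_s + dt_s / 2, dt_s)
    d = np.where(
        t <= aspiration_s,
        ldot_asp * t,
        np.maximum(0.0, ldot_asp * aspiration_s - ldot_ret * (t - aspiration_s)),
    )
    if noise_sd > 0:
        d = d + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return AspirationTrace(
        t, d, pipette_radius, pressure, release_time=aspiration_s,
        meta={"eta_true": eta, "critical_pressure": critical_pressure,
              "noise_sd": noise_sd, "seed": seed},
    )


def synth_division_maps(
    level: str,
    n_maps: int = 50,
    cells_per_map: int = 100,
    division_prob: float = 0.08,
    concentration: float = 4.0,
    seed: int = 0,
) -> tuple[list[QuadrantCounts], dict]:
    """Quadrant division-count maps under a uniform or clustered regime.

    ``uniform`` draws quadrant totals from a multinomial(1/4) and dividing
    cells i.i.d. with the division probability — exactly the two-stage
    binomial null of the heterogeneity statistic.  ``clustered`` skews the
    per-quadrant division probabilities by a Dirichlet draw with the given
    concentration (smaller = stronger clustering), producing overdispersed
    counts.  Ground truth is returned alongside.
    """
    if level not in ("uniform", "clustered"):
        raise ValueError("level must be 'uniform' or 'clustered'")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_maps):
        totals = rng.multinomial(cells_per_map, [0.25] * 4)
        if level == "uniform":
            dividing = rng.binomial(totals, division_prob)
        else:
            w = rng.dirichlet([concentration] * 4)
            p = np.clip(4.0 * division_prob * w, 0.0, 1.0)
            dividing = rng.binomial(totals, p)
        out.append(QuadrantCounts(tuple(int(x) for x in totals),
                                  tuple(int(x) for x in dividing)))
    truth = {"level": level, "division_prob": division_prob,
             "concentration": concentration, "seed": seed}
    return out, truth
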