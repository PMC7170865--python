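"""Validation statistics: MSD diffusion recovery, the ABM:ODE score,
the coefficient of determination against the ODE twin, and the
parallel-scaling arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import N_A
from .timeseries import CountsTimeSeries


@dataclass
class MSDEstimate:
    """Diffusion coefficient recovered from accumulated step displacements.

    ``msd`` is the time-normalised cumulative squared displacement
    sum(dx^2 + dy^2 + dz^2) / t, which equals lambda * D with the
    dimensionality constant lambda = 2 * dim (4 in-plane, 6 in 3D).
    """

    msd: float
    lam: int
    D_hat: float
    t: float


def estimate_D_msd(squared_displacements, t: float, dim: int) -> MSDEstimate:
    """Recover D from per-step squared displacements over elapsed time t."""
    sq = np.atleast_1d(np.asarray(squared_displacements, float))
    if sq.size == 0:
        raise ValueError("empty displacement series")
    if t <= 0:
        raise ValueError("t must be > 0")
    if dim not in (1, 2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    lam = 2 * dim
    msd = float(sq.sum()) / t
    return MSDEstimate(msd, lam, msd / lam, t)


@dataclass
class ScoreResult:
    """Mean per-time product-concentration ratio (ideal value 1)."""

    score: float
    ratios: np.ndarray
    times: np.ndarray
    n_points: int
    window: float
    interval: float
    completion_time: float | None = None
    excluded: list = field(default_factory=list)  # (time, reason)


def abm_ode_score(
    abm: CountsTimeSeries,
    ode: CountsTimeSeries,
    product: str,
    interval: float = 0.05,
    window: float = 300.0,
    reactants: list[str] | None = None,
    completion_fraction: float = 0.005,
) -> ScoreResult:
    """Average ratio of ABM to ODE product concentration over time.

    Ratios are taken at every ``interval`` from the first sample after
    t = 0 up to ``min(window, completion)``, where completion is the
    first time the ODE limiting reactant (the smallest relative
    survivor among ``reactants``) falls below ``completion_fraction``
    of its initial value.  Points where the ODE product is below one
    molecule-equivalent, 1 / (1e3 N_A V_C) M, are excluded so the ratio
    stays finite near t = 0.
    """
    a = abm.to_molar()
    o = ode.to_molar()
    if a.times.size != o.times.size or not np.allclose(a.times, o.times):
        raise ValueError("ABM and ODE series must share a time grid")
    times = a.times
    p_abm = a.column(product)
    p_ode = o.column(product)

    cutoff = window
    completion_time = None
    if reactants:
        rel = np.ones_like(times)
        for name in reactants:
            col = o.column(name)
            if col[0] > 0:
                rel = np.minimum(rel, col / col[0])
        below = np.flatnonzero(rel < completion_fraction)
        if below.size:
            completion_time = float(times[below[0]])
            cutoff = min(cutoff, completion_time)

    step = times[1] - times[0] if times.size > 1 else interval
    tol = 0.5 * step
    phase = np.abs(times / interval - np.round(times / interval))
    on_grid = phase * interval < tol
    sel = (times > 0) & (times <= cutoff + tol) & on_grid

    guard = 1.0 / (1e3 * N_A * a.volume)
    excluded = [(float(t), "ode product below one molecule-equivalent")
                for t in times[sel & (p_ode < guard)]]
    sel &= p_ode >= guard
    if not sel.any():
        raise ValueError("no usable points for the ABM:ODE score")
    ratios = p_abm[sel] / p_ode[sel]
    return ScoreResult(
        float(ratios.mean()),
        ratios,
        times[sel],
        int(sel.sum()),
        window,
        interval,
        completion_time,
        excluded,
    )


def r_squared(abm, ode) -> float:
    """1 - SS_res / SS_tot with the ODE series as the reference."""
    a = np.asarray(abm, float)
    o = np.asarray(ode, float)
    if a.shape != o.shape:
        raise ValueError("series must have equal length")
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("constant reference series: R^2 undefined")
    ss_res = float(((a - o) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass
class ParallelMetrics:
    """Speed-up and efficiency of an N-CPU run relative to serial."""

    N: int
    runtime: float
    theoretical_runtime: float  # runtime(N=1) / N
    speed_up: float  # runtime(N=1) / runtime
    efficiency: float  # speed_up / N * 100, %


def parallel_metrics(runtimes: dict[int, float]) -> list[ParallelMetrics]:
    """Per-CPU-count scaling metrics; requires the serial (N=1) runtime."""
    if 1 not in runtimes:
        raise ValueError("runtimes must include the serial N=1 entry")
    serial = runtimes[1]
    out = []
    for n in sorted(runtimes):
        rt = runtimes[n]
        su = serial / rt
        out.append(ParallelMetrics(n, rt, serial / n, su, su / n * 100.0))
    return out
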