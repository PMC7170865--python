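"""Brownian propagation of agents with reflective box boundaries.

Each substep displaces every alive agent by an isotropic Gaussian step
with per-axis standard deviation sigma = sqrt(2 D dt).  Soluble species
move in 3D; membrane species move in-plane at z = 0 (their z-step
standard deviation is zero).  Proposed coordinates are folded back into
the box by triangular-wave reflection, which handles steps longer than
the box.  The *pre-reflection* squared step displacements are
accumulated per agent for MSD-based diffusion recovery: the cumulative
sum divided by elapsed time converges to lambda * D with lambda = 6 in
3D and 4 in-plane.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model_io import ModelSpec, ParticleState


def sigma_from_D(D: float, dt: float) -> float:
    """Per-axis Gaussian step sd, sigma = sqrt(2 D dt)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return math.sqrt(2.0 * D * dt)


def polar_box_muller(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` standard normals by the polar (Marsaglia) Box-Muller method.

    Reference sampler: pairs of uniforms on (-1, 1) are rejected outside
    the unit disc and transformed exactly; kept for cross-checking the
    engine's default generator, which may use any exact normal sampler.
    """
    out = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        m = need // 2 + 8  # disc acceptance ~0.785, two normals per hit
        u = rng.uniform(-1.0, 1.0, size=(m, 2))
        s = u[:, 0] ** 2 + u[:, 1] ** 2
        ok = (s > 0.0) & (s < 1.0)
        u, s = u[ok], s[ok]
        f = np.sqrt(-2.0 * np.log(s) / s)
        z = np.column_stack((u[:, 0] * f, u[:, 1] * f)).ravel()
        take = min(z.size, need)
        out[filled : filled + take] = z[:take]
        filled += take
    return out


def sample_displacement(
    sigma: float, dim: int, rng: np.random.Generator, sampler=None
) -> np.ndarray:
    """One Gaussian step (dx, dy, dz); ``dim=2`` pins dz to zero."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    draw = sampler if sampler is not None else (lambda n, g: g.standard_normal(n))
    d = sigma * draw(3, rng)
    if dim == 2:
        d[2] = 0.0
    return d


def reflect_coordinate(x, L: float):
    """Fold ``x`` into [0, L] by reflecting off both walls (triangular wave)."""
    if L <= 0:
        raise ValueError("L must be > 0")
    y = np.mod(x, 2.0 * L)
    return np.where(y > L, 2.0 * L - y, y) if np.ndim(x) else (
        2.0 * L - y if y > L else y
    )


@njit(cache=True)
def _walk(pos, steps, active, edges, sq_acc):  # pragma: no cover - jitted
    n_sub = steps.shape[0]
    n_act = active.shape[0]
    for t in range(n_sub):
        for a in range(n_act):
            i = active[a]
            acc = 0.0
            for k in range(3):
                d = steps[t, i, k]
                acc += d * d
                x = pos[i, k] + d
                L = edges[k]
                if x < 0.0 or x > L:
                    x = x % (2.0 * L)
                    if x > L:
                        x = 2.0 * L - x
                pos[i, k] = x
            sq_acc[i] += acc


def _sigma3(model: ModelSpec, dt: float) -> np.ndarray:
    """(n_species, 3) per-axis step sd; z column zero for membrane species."""
    key = float(dt)
    cached = model._sigma_cache.get(key)
    if cached is None:
        s = np.sqrt(2.0 * model.D_array * dt)
        cached = np.repeat(s[:, None], 3, axis=1)
        cached[model.membrane_mask, 2] = 0.0
        model._sigma_cache[key] = cached
    return cached


_CHUNK_ELEMS = 4_000_000  # normals per RNG chunk; stream is chunk-independent


def diffuse(
    state: ParticleState,
    model: ModelSpec,
    dt_diff: float,
    n_substeps: int,
    rng: np.random.Generator,
) -> ParticleState:
    """Advance every alive agent ``n_substeps`` Gaussian steps in place."""
    if n_substeps < 1:
        raise ValueError("n_substeps must be >= 1")
    n = state.n_slots
    sig = _sigma3(model, dt_diff)[state.species]  # (N, 3)
    active = np.flatnonzero(state.alive)
    edges = model.geometry.edges
    per_chunk = max(1, _CHUNK_ELEMS // max(1, 3 * n))
    done = 0
    while done < n_substeps:
        m = min(per_chunk, n_substeps - done)
        steps = rng.standard_normal((m, n, 3))
        steps *= sig
        _walk(state.positions, steps, active, edges, state.sq_disp)
        done += m
    state.time += n_substeps * dt_diff
    return state
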