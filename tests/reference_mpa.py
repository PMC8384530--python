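"""Independent scalar-loop transcription of the Marine Predators Algorithm.

This module is a deliberately naive, entry-by-entry re-implementation of the
published update equations, used only as an oracle: the phase functions take
the random draws as explicit arguments so a test can feed both implementations
the same captured RNG stream, and :func:`ref_optimize` runs the full loop in
scalar code to establish benchmark thresholds independently of the package's
vectorized implementation.  It must never import from :mod:`mpacnn.mpa`.
"""

from __future__ import annotations

import math

import numpy as np


def ref_cf(it: int, max_iter: int) -> float:
    frac = it / max_iter
    if frac == 1.0:
        return 0.0
    return (1.0 - frac) ** (2.0 * frac)


def ref_levy_sigma(alpha: float) -> float:
    return (
        math.gamma(1 + alpha) * math.sin(math.pi * alpha / 2)
        / (math.gamma((1 + alpha) / 2) * alpha * 2 ** ((alpha - 1) / 2))
    ) ** (1 / alpha)


def ref_levy_from_normals(u: np.ndarray, v: np.ndarray, alpha: float) -> np.ndarray:
    """Mantegna sample from two standard-normal blocks, entrywise."""
    out = np.empty_like(u)
    sigma = ref_levy_sigma(alpha)
    for idx in np.ndindex(u.shape):
        out[idx] = sigma * u[idx] / abs(v[idx]) ** (1 / alpha)
    return out


def _clamp(x, lo, hi):
    return np.minimum(np.maximum(x, lo), hi)


def ref_phase1(prey, elite, P, rb, r, lo, hi):
    n, d = prey.shape
    out = prey.copy()
    for i in range(n):
        for j in range(d):
            step = rb[i, j] * (elite[j] - rb[i, j] * prey[i, j])
            out[i, j] = prey[i, j] + P * r[i, j] * step
    return _clamp(out, lo, hi)


def ref_phase2(prey, elite, P, cf, rl, r, rb, lo, hi):
    n, d = prey.shape
    n1 = (n + 1) // 2
    out = prey.copy()
    for i in range(n1):
        for j in range(d):
            step = rl[i, j] * (elite[j] - rl[i, j] * prey[i, j])
            out[i, j] = prey[i, j] + P * r[i, j] * step
    for i in range(n1, n):
        for j in range(d):
            step = rb[i - n1, j] * (rb[i - n1, j] * elite[j] - prey[i, j])
            out[i, j] = elite[j] + P * cf * step
    return _clamp(out, lo, hi)


def ref_phase3(prey, elite, P, cf, rl, lo, hi):
    n, d = prey.shape
    out = prey.copy()
    for i in range(n):
        for j in range(d):
            step = rl[i, j] * (rl[i, j] * elite[j] - prey[i, j])
            out[i, j] = elite[j] + P * cf * step
    return _clamp(out, lo, hi)


def ref_fads(prey, fads, cf, r, u, rand_box, r1, r2, lo, hi):
    """First branch when r <= fads (uses u, rand_box); second otherwise (r1, r2)."""
    n, d = prey.shape
    out = prey.copy()
    if r <= fads:
        for i in range(n):
            for j in range(d):
                out[i, j] = prey[i, j] + cf * rand_box[i, j] * u[i, j]
    else:
        factor = fads * (1 - r) + r
        for i in range(n):
            for j in range(d):
                out[i, j] = prey[i, j] + factor * (prey[r1[i], j] - prey[r2[i], j])
    return _clamp(out, lo, hi)


def ref_optimize(objective, d, lo, hi, n, max_iter, seed,
                 P=0.5, fads=0.2, alpha=1.5, levy_scale=0.05):
    """Full scalar-loop MPA run; returns (best_position, best_cost, history)."""
    rng = np.random.default_rng(seed)
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (d,))
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (d,))
    prey = np.empty((n, d))
    for i in range(n):
        for j in range(d):
            prey[i, j] = lo[j] + rng.random() * (hi[j] - lo[j])
    costs = np.array([objective(prey[i]) for i in range(n)])
    b = int(np.argmin(costs))
    elite, elite_cost = prey[b].copy(), float(costs[b])
    history = []
    for it in range(max_iter):
        cf = ref_cf(it, max_iter)
        old_prey, old_costs = prey.copy(), costs.copy()
        if it < max_iter // 3:
            rb = rng.standard_normal((n, d))
            r = rng.random((n, d))
            prey = ref_phase1(prey, elite, P, rb, r, lo, hi)
        elif it < (2 * max_iter) // 3:
            n1 = (n + 1) // 2
            rl = levy_scale * ref_levy_from_normals(
                rng.standard_normal((n1, d)), rng.standard_normal((n1, d)), alpha)
            r = rng.random((n1, d))
            rb = rng.standard_normal((n - n1, d))
            prey = ref_phase2(prey, elite, P, cf, rl, r, rb, lo, hi)
        else:
            rl = levy_scale * ref_levy_from_normals(
                rng.standard_normal((n, d)), rng.standard_normal((n, d)), alpha)
            prey = ref_phase3(prey, elite, P, cf, rl, lo, hi)
        r_scalar = rng.random()
        if r_scalar <= fads:
            u = (rng.random((n, d)) < fads).astype(float)
            rand_box = np.empty((n, d))
            for i in range(n):
                for j in range(d):
                    rand_box[i, j] = lo[j] + rng.random() * (hi[j] - lo[j])
            prey = ref_fads(prey, fads, cf, r_scalar, u, rand_box, None, None, lo, hi)
        else:
            r1 = rng.permutation(n)
            r2 = rng.permutation(n)
            prey = ref_fads(prey, fads, cf, r_scalar, None, None, r1, r2, lo, hi)
        costs = np.array([objective(prey[i]) for i in range(n)])
        for i in range(n):  # greedy marine-memory rule
            if costs[i] > old_costs[i]:
                prey[i] = old_prey[i]
                costs[i] = old_costs[i]
        b = int(np.argmin(costs))
        if costs[b] < elite_cost:
            elite, elite_cost = prey[b].copy(), float(costs[b])
        history.append(elite_cost)
    return elite, elite_cost, history
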