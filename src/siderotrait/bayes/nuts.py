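"""No-U-Turn sampler with dual-averaging step-size and diagonal metric
adaptation.

A compact, dependency-free implementation of the recursive NUTS algorithm
(slice-variable variant) sufficient for the moderate-dimension hierarchical
models in this package.  Warmup follows the usual windowed scheme: an
initial fast interval for step-size search, a sequence of doubling slow
windows each ending in a diagonal-metric update, and a terminal fast
interval to finalize the step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_DELTA_MAX = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_draws, dim) post-warmup draws
    logp: np.ndarray           # (n_draws,) log density at each draw
    step_size: float
    inv_metric: np.ndarray     # diagonal of the inverse mass matrix
    n_divergent: int
    mean_accept: float
    tree_depths: np.ndarray


class _Hamiltonian:
    __slots__ = ("logp_grad", "inv_metric", "sqrt_metric")

    def __init__(self, logp_grad: Callable, inv_metric: np.ndarray):
        self.logp_grad = logp_grad
        self.inv_metric = inv_metric
        self.sqrt_metric = 1.0 / np.sqrt(inv_metric)

    def sample_momentum(self, rng: np.random.Generator, dim: int) -> np.ndarray:
        return rng.normal(size=dim) * self.sqrt_metric

    def energy(self, logp: float, p: np.ndarray) -> float:
        return -logp + 0.5 * float(p @ (self.inv_metric * p))

    def leapfrog(self, z, p, grad, eps):
        p = p + 0.5 * eps * grad
        z = z + eps * (self.inv_metric * p)
        logp, grad = self.logp_grad(z)
        p = p + 0.5 * eps * grad
        return z, p, logp, grad


def _find_reasonable_epsilon(ham, z, logp, grad, rng) -> float:
    eps = 1.0
    p = ham.sample_momentum(rng, z.size)
    H0 = ham.energy(logp, p)
    _, p1, logp1, _ = ham.leapfrog(z, p, grad, eps)
    H1 = ham.energy(logp1, p1) if np.isfinite(logp1) else np.inf
    direction = 1.0 if H0 - H1 > math.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, logp1, _ = ham.leapfrog(z, p, grad, eps)
        H1 = ham.energy(logp1, p1) if np.isfinite(logp1) else np.inf
        if direction * (H0 - H1) <= direction * math.log(0.5):
            break
    return eps


def _no_uturn(z_minus, z_plus, p_minus, p_plus, inv_metric) -> bool:
    dz = z_plus - z_minus
    return (dz @ (inv_metric * p_minus) >= 0) and (dz @ (inv_metric * p_plus) >= 0)


def _build_tree(ham, rng, log_u, H0, z, p, grad, direction, j, eps):
    """One NUTS subtree.  Returns (z_m, p_m, g_m, z_p, p_p, g_p, z_prop,
    logp_prop, g_prop, n_valid, keep_going, accept_sum, n_accept, divergent)."""
    if j == 0:
        z1, p1, logp1, grad1 = ham.leapfrog(z, p, grad, direction * eps)
        H1 = ham.energy(logp1, p1) if np.isfinite(logp1) else np.inf
        n1 = 1 if log_u <= -H1 else 0
        s1 = log_u < _DELTA_MAX - H1
        a = math.exp(min(0.0, H0 - H1)) if np.isfinite(H1) else 0.0
        return (z1, p1, grad1, z1, p1, grad1, z1,
                logp1 if np.isfinite(logp1) else -np.inf,
                grad1, n1, s1, a, 1, not s1)
    (z_m, p_m, g_m, z_p, p_p, g_p, z1, logp1, g1, n1, s1,
     a, na, div) = _build_tree(ham, rng, log_u, H0, z, p, grad, direction, j - 1, eps)
    if s1:
        if direction == -1:
            (z_m, p_m, g_m, _, _, _, z2, logp2, g2, n2, s2, a2, na2,
             div2) = _build_tree(ham, rng, log_u, H0, z_m, p_m, g_m, direction, j - 1, eps)
        else:
            (_, _, _, z_p, p_p, g_p, z2, logp2, g2, n2, s2, a2, na2,
             div2) = _build_tree(ham, rng, log_u, H0, z_p, p_p, g_p, direction, j - 1, eps)
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            z1, logp1, g1 = z2, logp2, g2
        n1 += n2
        s1 = s2 and _no_uturn(z_m, z_p, p_m, p_p, ham.inv_metric)
        a += a2
        na += na2
        div = div or div2
    return (z_m, p_m, g_m, z_p, p_p, g_p, z1, logp1, g1, n1, s1, a, na, div)


def _adaptation_schedule(n_warmup: int) -> list[int]:
    """End indices of the slow (metric) windows within warmup."""
    init_buffer, term_buffer, base = 75, 50, 25
    if n_warmup < init_buffer + term_buffer + base:
        # short warmup: single window covering the middle 60%
        return [int(0.8 * n_warmup)] if n_warmup >= 20 else []
    ends = []
    start = init_buffer
    size = base
    while True:
        end = start + size
        if end + term_buffer >= n_warmup or end + 2 * size + term_buffer > n_warmup:
            ends.append(n_warmup - term_buffer)
            break
        ends.append(end)
        start = end
        size *= 2
    return ends


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_depth: int = 10,
) -> NutsResult:
    """Run one NUTS chain and return its post-warmup draws."""
    dim = z0.size
    ham = _Hamiltonian(logp_grad, np.ones(dim))
    z = np.array(z0, dtype=float)
    logp, grad = logp_grad(z)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_epsilon(ham, z, logp, grad, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar = math.log(eps)
    H_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    window_ends = _adaptation_schedule(n_warmup)
    window: list[np.ndarray] = []
    in_slow = bool(window_ends)
    slow_start = 75 if n_warmup >= 150 else 0

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    depths = np.empty(n_draws, dtype=int)
    n_div = 0
    accept_sum = 0.0
    accept_n = 0

    for it in range(n_warmup + n_draws):
        adapting = it < n_warmup
        p0 = ham.sample_momentum(rng, dim)
        H0 = ham.energy(logp, p0)
        log_u = math.log(rng.random() + 1e-300) - H0

        z_minus = z_plus = z
        p_minus = p_plus = p0
        grad_minus = grad_plus = grad
        z_prop, logp_prop, grad_prop = z, logp, grad
        n_valid = 1
        keep_going = True
        depth = 0
        alpha_sum = 0.0
        n_alpha = 0
        divergent = False

        while keep_going and depth < max_depth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                (z_minus, p_minus, grad_minus, _, _, _, z1, logp1, g1, n1, s1,
                 a, na, div) = _build_tree(ham, rng, log_u, H0, z_minus, p_minus,
                                           grad_minus, -1, depth, eps)
            else:
                (_, _, _, z_plus, p_plus, grad_plus, z1, logp1, g1, n1, s1,
                 a, na, div) = _build_tree(ham, rng, log_u, H0, z_plus, p_plus,
                                           grad_plus, 1, depth, eps)
            if s1 and n1 > 0 and rng.random() < min(1.0, n1 / n_valid):
                z_prop, logp_prop, grad_prop = z1, logp1, g1
            n_valid += n1
            keep_going = s1 and _no_uturn(z_minus, z_plus, p_minus, p_plus,
                                          ham.inv_metric)
            alpha_sum += a
            n_alpha += na
            divergent = divergent or div
            depth += 1

        z, logp, grad = z_prop, logp_prop, grad_prop
        accept_stat = alpha_sum / max(n_alpha, 1)

        if adapting:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            H_bar = (1.0 - frac) * H_bar + frac * (target_accept - accept_stat)
            log_eps = mu - math.sqrt(da_count) / gamma * H_bar
            w = da_count**-kappa
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if in_slow and it >= slow_start:
                window.append(z.copy())
            if window_ends and it + 1 == window_ends[0]:
                window_ends.pop(0)
                if len(window) >= 10:
                    arr = np.asarray(window)
                    var = np.var(arr, axis=0)
                    n_w = len(window)
                    var = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                    ham = _Hamiltonian(logp_grad, np.maximum(var, 1e-12))
                    eps = _find_reasonable_epsilon(ham, z, logp, grad, rng)
                    mu = math.log(10.0 * eps)
                    log_eps_bar = math.log(eps)
                    H_bar = 0.0
                    da_count = 0
                window = []
                in_slow = bool(window_ends)
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            i = it - n_warmup
            draws[i] = z
            logps[i] = logp
            depths[i] = depth
            if divergent:
                n_div += 1
            accept_sum += accept_stat
            accept_n += 1

    return NutsResult(
        draws=draws,
        logp=logps,
        step_size=eps,
        inv_metric=ham.inv_metric,
        n_divergent=n_div,
        mean_accept=accept_sum / max(accept_n, 1),
        tree_depths=depths,
    )
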