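"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained implementation of multinomial NUTS (tree doubling with
progressive multinomial state selection and the generalised U-turn criterion)
operating on a ``logp_grad(theta) -> (float, ndarray)`` callable.  Warmup
follows the usual three-phase schedule: an initial fast interval adapting only
the step size, doubling slow windows estimating the diagonal inverse mass
matrix from warmup draws, and a final fast interval re-tuning the step size
for the adapted metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NutsStats", "sample_nuts"]

# energy error beyond which a leapfrog trajectory is declared divergent
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsStats:
    """Per-chain sampler statistics."""

    divergences: int = 0
    n_draws: int = 0
    step_size: float = float("nan")
    mean_accept: float = float("nan")
    max_treedepth_hits: int = 0


class _DualAveraging:
    """Nesterov dual averaging of the log step size (Hoffman-Gelman schedule)."""

    def __init__(self, eps0: float, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    """Running mean/variance accumulator for mass-matrix estimation."""

    def __init__(self, n_dim: int):
        self.n = 0
        self.mean = np.zeros(n_dim)
        self.m2 = np.zeros(n_dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularise towards the unit metric, as Stan does
        return var * self.n / (self.n + 5.0) + 1e-3 * 5.0 / (self.n + 5.0)


def _find_reasonable_step(logp_grad, theta, inv_mass, rng):
    """Bracket a step size whose one-step accept probability is near 0.5."""
    eps = 1.0
    lp, grad = logp_grad(theta)
    r = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(inv_mass * r * r)

    def energy_after(e):
        with np.errstate(over="ignore", invalid="ignore"):
            r1 = r + 0.5 * e * grad
            th1 = theta + e * inv_mass * r1
            lp1, g1 = logp_grad(th1)
            r1 = r1 + 0.5 * e * g1
            return lp1 - 0.5 * np.sum(inv_mass * r1 * r1)

    h1 = energy_after(eps)
    while not np.isfinite(h1) and eps > 1e-10:
        eps /= 2.0
        h1 = energy_after(eps)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0**direction
        h1 = energy_after(eps)
        if not np.isfinite(h1):
            if direction > 0:
                eps /= 2.0
            break
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return float(max(eps, 1e-10))


def _adaptation_schedule(n_warmup: int):
    """Return (init_fast_end, [slow window (start, end)...], term_start)."""
    if n_warmup < 20:
        return n_warmup, [], n_warmup
    init = min(75, max(int(0.15 * n_warmup), 1))
    term = min(50, max(int(0.10 * n_warmup), 1))
    slow_total = n_warmup - init - term
    if slow_total <= 0:
        return n_warmup, [], n_warmup
    windows = []
    pos = init
    size = max(min(25, slow_total), 1)
    while pos < init + slow_total:
        end = pos + size
        # absorb a too-small final window into this one
        if init + slow_total - end < size * 2:
            end = init + slow_total
        windows.append((pos, end))
        pos = end
        size *= 2
    return init, windows, init + slow_total


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    lp, grad = logp_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, lp, grad


class _Subtree:
    __slots__ = (
        "theta", "lp", "grad", "log_w", "rho", "r_near", "r_far",
        "sum_alpha", "n_alpha", "divergent", "turning",
    )


def _build_tree(logp_grad, theta, r, grad, eps, depth, inv_mass, h0, rng):
    """Double a subtree in the direction of ``eps``.

    Returns ``(theta_end, r_end, grad_end, subtree)`` where the subtree record
    carries the multinomial proposal, total weight, momentum sum and the
    momenta at its two extreme leaves (for the U-turn criterion).
    """
    if depth == 0:
        theta1, r1, lp1, g1 = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * r1 * r1)
        delta_h = h1 - h0
        if not np.isfinite(delta_h):
            delta_h = -np.inf
        sub = _Subtree()
        sub.theta, sub.lp, sub.grad = theta1, lp1, g1
        sub.log_w = delta_h
        sub.rho = r1.copy()
        sub.r_near = sub.r_far = r1
        sub.sum_alpha = float(np.exp(min(delta_h, 0.0)))
        sub.n_alpha = 1
        sub.divergent = bool(delta_h < -DIVERGENCE_THRESHOLD)
        sub.turning = False
        return theta1, r1, g1, sub

    theta, r, grad, first = _build_tree(
        logp_grad, theta, r, grad, eps, depth - 1, inv_mass, h0, rng
    )
    if first.divergent or first.turning:
        return theta, r, grad, first
    theta, r, grad, second = _build_tree(
        logp_grad, theta, r, grad, eps, depth - 1, inv_mass, h0, rng
    )

    sub = _Subtree()
    sub.sum_alpha = first.sum_alpha + second.sum_alpha
    sub.n_alpha = first.n_alpha + second.n_alpha
    sub.divergent = second.divergent
    sub.turning = second.turning
    if second.divergent or second.turning:
        sub.theta, sub.lp, sub.grad = first.theta, first.lp, first.grad
        sub.log_w, sub.rho = first.log_w, first.rho
        sub.r_near, sub.r_far = first.r_near, first.r_far
        return theta, r, grad, sub

    log_w = np.logaddexp(first.log_w, second.log_w)
    chosen = second if np.log(rng.random()) < second.log_w - log_w else first
    rho = first.rho + second.rho
    sub.theta, sub.lp, sub.grad = chosen.theta, chosen.lp, chosen.grad
    sub.log_w = log_w
    sub.rho = rho
    sub.r_near, sub.r_far = first.r_near, second.r_far
    sub.turning = bool(
        np.sum(inv_mass * rho * sub.r_near) < 0 or np.sum(inv_mass * rho * sub.r_far) < 0
    )
    return theta, r, grad, sub


def sample_nuts(
    logp_grad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.95,
    max_treedepth: int = 10,
):
    """Run one NUTS chain; returns ``(draws [n_draws, dim], NutsStats)``.

    Divergent trajectories (energy error beyond 1000) are counted in the
    statistics and their subtrees discarded, never silently accepted.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    n_dim = theta.shape[0]
    inv_mass = np.ones(n_dim)
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_step(logp_grad, theta, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)
    _, slow_windows, _ = _adaptation_schedule(n_warmup)
    window_ends = {end for _, end in slow_windows}
    in_slow = lambda i: any(s <= i < e for s, e in slow_windows)
    welford = _Welford(n_dim)

    draws = np.empty((n_draws, n_dim))
    stats = NutsStats()
    accepts = []

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        r0 = rng.standard_normal(n_dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * r0 * r0)

        th_m = th_p = theta
        r_m = r_p = r0
        g_m = g_p = grad
        rho = r0.copy()
        prop_theta, prop_lp, prop_grad = theta, lp, grad
        log_w = 0.0  # weight of the initial point relative to h0
        sum_alpha, n_alpha = 0.0, 0
        divergent = False

        for depth in range(max_treedepth):
            if rng.random() < 0.5:
                th_p, r_p, g_p, sub = _build_tree(
                    logp_grad, th_p, r_p, g_p, +eps, depth, inv_mass, h0, rng
                )
            else:
                th_m, r_m, g_m, sub = _build_tree(
                    logp_grad, th_m, r_m, g_m, -eps, depth, inv_mass, h0, rng
                )
            sum_alpha += sub.sum_alpha
            n_alpha += sub.n_alpha
            if sub.divergent:
                divergent = True
                break
            if sub.turning:
                break
            log_w_new = np.logaddexp(log_w, sub.log_w)
            if np.log(rng.random()) < sub.log_w - log_w_new:
                prop_theta, prop_lp, prop_grad = sub.theta, sub.lp, sub.grad
            log_w = log_w_new
            rho = rho + sub.rho
            if np.sum(inv_mass * rho * r_m) < 0 or np.sum(inv_mass * rho * r_p) < 0:
                break
        else:
            stats.max_treedepth_hits += 1

        theta, lp, grad = prop_theta, prop_lp, prop_grad
        accept_prob = sum_alpha / max(n_alpha, 1)

        if warming:
            eps = da.update(accept_prob)
            if in_slow(it):
                welford.push(theta)
            if (it + 1) in window_ends and welford.n >= 10:
                inv_mass = welford.variance()
                welford = _Welford(n_dim)
                eps = _find_reasonable_step(logp_grad, theta, inv_mass, rng)
                da = _DualAveraging(eps, target_accept)
            if it + 1 == n_warmup:
                eps = da.adapted
        else:
            draws[it - n_warmup] = theta
            stats.n_draws += 1
            stats.divergences += int(divergent)
            accepts.append(accept_prob)

    stats.step_size = float(eps)
    stats.mean_accept = float(np.mean(accepts)) if accepts else float("nan")
    return draws, stats
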