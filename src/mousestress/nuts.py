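"""A No-U-Turn Sampler (NUTS) for differentiable log posteriors.

Adaptive Hamiltonian Monte Carlo: leapfrog integration of an auxiliary
momentum, with the trajectory length chosen dynamically by doubling the
simulated path until it starts to turn back on itself (the "no-U-turn"
criterion), and a slice variable selecting the returned state uniformly
from the valid points of the trajectory.

Warm-up adapts two things, Stan-style:

* the step size, by dual averaging toward a target acceptance statistic
  (default 0.9 — conservative for hierarchical geometries);
* a diagonal mass matrix, from the parameter variances of expanding
  adaptation windows (schedule: an initial step-size-only buffer, doubling
  variance windows, a terminal step-size-only buffer).

A transition whose energy error exceeds 1000 is recorded as a divergence.
The sampler is deterministic given its :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsResult", "sample_nuts"]

_DIVERGENCE_ENERGY = 1000.0


@dataclass
class NutsResult:
    """Post-warmup draws and per-draw diagnostics for one chain."""

    draws: np.ndarray  # (n_samples, dim)
    divergent: np.ndarray  # bool, (n_samples,)
    tree_depth: np.ndarray  # int, (n_samples,)
    accept_stat: np.ndarray  # float, (n_samples,)
    step_size: float
    inv_mass: np.ndarray  # diagonal of M^{-1}, (dim,)
    n_warmup_divergent: int


class _State:
    __slots__ = ("theta", "r", "grad", "logp")

    def __init__(self, theta, r, grad, logp):
        self.theta = theta
        self.r = r
        self.grad = grad
        self.logp = logp


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * (inv_mass * r1)
    logp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, grad1, logp1


def _joint(logp, r, inv_mass) -> float:
    return logp - 0.5 * float(np.dot(r, inv_mass * r))


def _no_uturn(theta_minus, r_minus, theta_plus, r_plus, inv_mass) -> bool:
    d = theta_plus - theta_minus
    return (
        float(np.dot(d, inv_mass * r_minus)) >= 0.0
        and float(np.dot(d, inv_mass * r_plus)) >= 0.0
    )


def _find_initial_step(logp_grad, theta, grad, logp, inv_mass, rng) -> float:
    """Heuristic: double/halve eps until the one-step accept prob crosses 1/2."""
    eps = 1.0
    r = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)
    joint0 = _joint(logp, r, inv_mass)
    _, r1, _, logp1 = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    delta = _joint(logp1, r1, inv_mass) - joint0
    if not np.isfinite(delta):
        delta = -np.inf
    direction = 1.0 if delta > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, r1, _, logp1 = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        delta = _joint(logp1, r1, inv_mass) - joint0
        if not np.isfinite(delta):
            delta = -np.inf
        if direction * delta <= direction * np.log(0.5):
            break
    return eps


def _build_tree(logp_grad, state, log_u, v, depth, eps, joint0, inv_mass, rng):
    """Recursively double the trajectory; progressive multinomial-by-count sampling.

    Returns (minus, plus, proposal, n_valid, keep_going, sum_accept,
    n_accept, divergent).
    """
    if depth == 0:
        theta1, r1, grad1, logp1 = _leapfrog(
            logp_grad, state.theta, state.r, state.grad, v * eps, inv_mass
        )
        st = _State(theta1, r1, grad1, logp1)
        joint = _joint(logp1, r1, inv_mass)
        if not np.isfinite(joint):
            joint = -np.inf
        n_valid = int(log_u <= joint)
        divergent = (log_u - joint) > _DIVERGENCE_ENERGY
        accept = min(1.0, float(np.exp(min(0.0, joint - joint0))))
        return st, st, st, n_valid, (not divergent), accept, 1, divergent

    minus, plus, prop, n1, keep, acc, nacc, div = _build_tree(
        logp_grad, state, log_u, v, depth - 1, eps, joint0, inv_mass, rng
    )
    if keep:
        if v == -1:
            minus, _, prop2, n2, keep2, acc2, nacc2, div2 = _build_tree(
                logp_grad, minus, log_u, v, depth - 1, eps, joint0, inv_mass, rng
            )
        else:
            _, plus, prop2, n2, keep2, acc2, nacc2, div2 = _build_tree(
                logp_grad, plus, log_u, v, depth - 1, eps, joint0, inv_mass, rng
            )
        if keep2 and n2 > 0 and rng.random() < n2 / max(n1 + n2, 1):
            prop = prop2
        n1 += n2
        acc += acc2
        nacc += nacc2
        keep = keep2 and _no_uturn(minus.theta, minus.r, plus.theta, plus.r, inv_mass)
        div = div or div2
    return minus, plus, prop, n1, keep, acc, nacc, div


def _nuts_step(logp_grad, state, eps, inv_mass, max_depth, rng):
    r0 = rng.standard_normal(state.theta.shape) / np.sqrt(inv_mass)
    cur = _State(state.theta, r0, state.grad, state.logp)
    joint0 = _joint(state.logp, r0, inv_mass)
    log_u = joint0 - rng.exponential()
    minus = plus = cur
    prop = cur
    n_valid, depth, keep = 1, 0, True
    divergent = False
    sum_acc, n_acc = 0.0, 0
    while keep and depth < max_depth:
        v = 1 if rng.random() < 0.5 else -1
        if v == -1:
            minus, _, prop1, n1, keep1, acc, nacc, div = _build_tree(
                logp_grad, minus, log_u, v, depth, eps, joint0, inv_mass, rng
            )
        else:
            _, plus, prop1, n1, keep1, acc, nacc, div = _build_tree(
                logp_grad, plus, log_u, v, depth, eps, joint0, inv_mass, rng
            )
        if keep1 and n1 > 0 and rng.random() < min(1.0, n1 / n_valid):
            prop = prop1
        n_valid += n1
        sum_acc += acc
        n_acc += nacc
        divergent = divergent or div
        keep = keep1 and _no_uturn(minus.theta, minus.r, plus.theta, plus.r, inv_mass)
        depth += 1
    accept_stat = sum_acc / max(n_acc, 1)
    return _State(prop.theta, r0, prop.grad, prop.logp), depth, accept_stat, divergent


def _adaptation_schedule(n_warmup: int) -> list[tuple[int, bool]]:
    """(window_end, update_mass_at_end) pairs partitioning the warm-up."""
    if n_warmup < 40:
        return [(n_warmup, False)]
    init = max(15, int(round(0.15 * n_warmup))) if n_warmup < 150 else 75
    term = max(10, int(round(0.10 * n_warmup))) if n_warmup < 150 else 50
    windows: list[tuple[int, bool]] = [(init, False)]
    size = 25
    pos = init
    while pos + size + term <= n_warmup:
        # last window absorbs the remainder before the terminal buffer
        if pos + 2 * size + term > n_warmup:
            size = n_warmup - term - pos
        windows.append((pos + size, True))
        pos += size
        size *= 2
    windows.append((n_warmup, False))
    return windows


def sample_nuts(
    logp_grad,
    init: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain and return post-warmup draws.

    Parameters
    ----------
    logp_grad
        Callable ``theta -> (log posterior, gradient)``; may return
        ``-inf`` (with arbitrary gradient) outside the support.
    init
        Starting point, shape ``(dim,)``.
    n_warmup, n_samples
        Adaptation and retained iteration counts.
    rng
        Seeded generator; the chain is deterministic given it.
    """
    theta = np.asarray(init, dtype=float).copy()
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log posterior")
    dim = theta.size
    inv_mass = np.ones(dim)
    state = _State(theta, np.zeros(dim), grad, logp)

    eps = _find_initial_step(logp_grad, theta, grad, logp, inv_mass, rng)
    # dual-averaging constants (Hoffman & Gelman)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0

    schedule = _adaptation_schedule(n_warmup)
    win_idx = 0
    win_start = 0
    win_buffer: list[np.ndarray] = []
    n_warm_div = 0

    for it in range(n_warmup):
        state, _, accept, div = _nuts_step(logp_grad, state, eps, inv_mass, max_treedepth, rng)
        n_warm_div += int(div)
        da_count += 1
        frac = 1.0 / (da_count + t0)
        h_bar = (1 - frac) * h_bar + frac * (target_accept - accept)
        log_eps = mu - np.sqrt(da_count) / gamma * h_bar
        w = da_count**-kappa
        log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
        eps = float(np.exp(log_eps))

        win_end, update_mass = schedule[win_idx]
        if update_mass:
            win_buffer.append(state.theta.copy())
        if it + 1 == win_end:
            if update_mass and len(win_buffer) >= 10:
                arr = np.asarray(win_buffer)
                n = arr.shape[0]
                var = arr.var(axis=0, ddof=1)
                # Stan-style shrinkage toward unit scale
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-10)
                # restart dual averaging around the current step size
                eps = _find_initial_step(
                    logp_grad, state.theta, state.grad, state.logp, inv_mass, rng
                )
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            win_buffer = []
            win_idx = min(win_idx + 1, len(schedule) - 1)
            win_start = it + 1
    _ = win_start

    if n_warmup > 0:
        eps = float(np.exp(log_eps_bar)) if da_count > 0 else eps

    draws = np.empty((n_samples, dim))
    divergent = np.zeros(n_samples, dtype=bool)
    depth_arr = np.zeros(n_samples, dtype=np.int64)
    accept_arr = np.zeros(n_samples)
    for it in range(n_samples):
        state, depth, accept, div = _nuts_step(
            logp_grad, state, eps, inv_mass, max_treedepth, rng
        )
        draws[it] = state.theta
        divergent[it] = div
        depth_arr[it] = depth
        accept_arr[it] = accept
    return NutsResult(
        draws=draws,
        divergent=divergent,
        tree_depth=depth_arr,
        accept_stat=accept_arr,
        step_size=eps,
        inv_mass=inv_mass,
        n_warmup_divergent=n_warm_div,
    )
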