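"""No-U-Turn sampler with diagonal mass-matrix and step-size adaptation.

Multinomial trajectory sampling, dual-averaging step size tuned to a
target acceptance statistic, and windowed estimation of a diagonal
metric during warmup. Written against a ``logp_grad(theta)`` callable;
fully deterministic given the supplied generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class _Leaf:
    theta: np.ndarray
    p: np.ndarray
    lp: float
    grad: np.ndarray


class _DualAveraging:
    def __init__(self, eps0: float, target: float):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_stat: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** -self.kappa
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return math.exp(self.log_eps)

    def restart(self, eps: float) -> None:
        self.mu = math.log(10.0 * eps)
        self.log_eps = math.log(eps)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        return self.m2 / max(self.n - 1, 1)


def _mass_windows(n_warmup: int) -> list[tuple[int, int]]:
    """(start, end) iteration ranges whose draws feed the metric."""
    init = min(75, max(10, int(0.15 * n_warmup)))
    term = min(50, max(10, int(0.10 * n_warmup)))
    windows = []
    start, size = init, 25
    while start + size < n_warmup - term:
        nxt = start + size
        if nxt + 2 * size >= n_warmup - term:
            nxt = n_warmup - term
        windows.append((start, nxt))
        start, size = nxt, 2 * size
    if not windows and n_warmup > init + term + 10:
        windows.append((init, n_warmup - term))
    return windows


class NutsSampler:
    def __init__(
        self,
        logp_grad,
        rng: np.random.Generator,
        target_accept: float = 0.85,
        max_treedepth: int = 10,
    ):
        self.f = logp_grad
        self.rng = rng
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.n_grad_evals = 0

    # ------------------------------------------------------------------ pieces
    def _eval(self, theta):
        self.n_grad_evals += 1
        lp, grad = self.f(theta)
        if not np.isfinite(lp):
            lp = -np.inf
            grad = np.zeros_like(theta)
        return lp, grad

    def _leapfrog(self, leaf: _Leaf, eps: float, direction: int) -> _Leaf:
        e = eps * direction
        p = leaf.p + 0.5 * e * leaf.grad
        theta = leaf.theta + e * self.inv_mass * p
        lp, grad = self._eval(theta)
        p = p + 0.5 * e * grad
        return _Leaf(theta, p, lp, grad)

    def _kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(np.dot(p, self.inv_mass * p))

    def _uturn(self, minus: _Leaf, plus: _Leaf) -> bool:
        dq = plus.theta - minus.theta
        return (
            float(np.dot(dq, self.inv_mass * minus.p)) < 0.0
            or float(np.dot(dq, self.inv_mass * plus.p)) < 0.0
        )

    def _build_tree(self, leaf: _Leaf, depth: int, eps: float, direction: int, h0: float):
        """Returns (inner, outer, proposal, log_sum_weight, sum_accept,
        n_leaves, diverged, turning). ``inner`` is the edge adjacent to the
        existing trajectory, ``outer`` the far edge."""
        if depth == 0:
            nxt = self._leapfrog(leaf, eps, direction)
            h = -nxt.lp + self._kinetic(nxt.p)
            diverged = (h - h0) > _DIVERGENCE_THRESHOLD or not math.isfinite(h)
            log_w = h0 - h if math.isfinite(h) else -np.inf
            accept = min(1.0, math.exp(min(0.0, h0 - h))) if math.isfinite(h) else 0.0
            return nxt, nxt, nxt, log_w, accept, 1, diverged, False

        inner1, outer1, prop1, lw1, acc1, n1, div1, turn1 = self._build_tree(
            leaf, depth - 1, eps, direction, h0
        )
        if div1 or turn1:
            return inner1, outer1, prop1, lw1, acc1, n1, div1, turn1
        inner2, outer2, prop2, lw2, acc2, n2, div2, turn2 = self._build_tree(
            outer1, depth - 1, eps, direction, h0
        )
        lw = np.logaddexp(lw1, lw2)
        prop = prop1
        if not (div2 or turn2) and math.isfinite(lw2):
            if math.log(self.rng.random() + 1e-300) < lw2 - lw:
                prop = prop2
        turning = turn2 or (
            not div2
            and (
                self._uturn(inner1, outer2)
                if direction > 0
                else self._uturn(outer2, inner1)
            )
        )
        return inner1, outer2, prop, lw, acc1 + acc2, n1 + n2, div2, turning

    # ---------------------------------------------------------------- sampling
    def _transition(self, current: _Leaf, eps: float):
        dim = current.theta.shape[0]
        p0 = self.rng.standard_normal(dim) / np.sqrt(self.inv_mass)
        start = _Leaf(current.theta, p0, current.lp, current.grad)
        h0 = -start.lp + self._kinetic(p0)
        minus = plus = start
        proposal = start
        log_sw = 0.0
        sum_accept, n_leaves = 0.0, 0
        diverged = False
        depth = 0
        while depth < self.max_treedepth:
            direction = 1 if self.rng.random() < 0.5 else -1
            edge = plus if direction > 0 else minus
            inner, outer, prop, lw, acc, n, div, turning = self._build_tree(
                edge, depth, eps, direction, h0
            )
            sum_accept += acc
            n_leaves += n
            if div:
                diverged = True
                break
            if not turning and math.isfinite(lw):
                new_total = np.logaddexp(log_sw, lw)
                if math.log(self.rng.random() + 1e-300) < lw - new_total:
                    proposal = prop
                log_sw = new_total
            if turning:
                break
            if direction > 0:
                plus = outer
            else:
                minus = outer
            if self._uturn(minus, plus):
                depth += 1
                break
            depth += 1
        accept_stat = sum_accept / max(n_leaves, 1)
        return proposal, accept_stat, depth, diverged

    def _find_initial_step(self, leaf: _Leaf) -> float:
        eps = 1.0
        dim = leaf.theta.shape[0]
        p0 = self.rng.standard_normal(dim) / np.sqrt(self.inv_mass)
        h0 = -leaf.lp + self._kinetic(p0)
        probe = _Leaf(leaf.theta, p0, leaf.lp, leaf.grad)
        nxt = self._leapfrog(probe, eps, 1)
        h1 = -nxt.lp + self._kinetic(nxt.p)
        delta = h0 - h1 if math.isfinite(h1) else -np.inf
        direction = 1 if delta > math.log(0.5) else -1
        for _ in range(50):
            eps *= 2.0 ** direction
            nxt = self._leapfrog(probe, eps, 1)
            h1 = -nxt.lp + self._kinetic(nxt.p)
            delta = h0 - h1 if math.isfinite(h1) else -np.inf
            if (direction == 1) != (delta > math.log(0.5)):
                break
        return eps

    def run(self, theta0: np.ndarray, n_warmup: int, n_samples: int):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._run(theta0, n_warmup, n_samples)

    def _run(self, theta0: np.ndarray, n_warmup: int, n_samples: int):
        dim = theta0.shape[0]
        self.inv_mass = np.ones(dim)
        lp, grad = self._eval(theta0)
        if not np.isfinite(lp):
            raise FloatingPointError("non-finite log density at the initial point")
        current = _Leaf(theta0.copy(), np.zeros(dim), lp, grad)

        eps = self._find_initial_step(current)
        da = _DualAveraging(eps, self.target_accept)
        windows = _mass_windows(n_warmup)
        welford = _Welford(dim)
        window_idx = 0

        draws = np.empty((n_samples, dim))
        divergent = np.zeros(n_samples, dtype=bool)
        depths = np.zeros(n_samples, dtype=np.int8)
        accept_stats = np.empty(n_samples)
        logps = np.empty(n_samples)
        n_div_warmup = 0

        for it in range(n_warmup + n_samples):
            warming = it < n_warmup
            proposal, accept_stat, depth, diverged = self._transition(current, eps)
            current = proposal
            if warming:
                eps = da.update(accept_stat)
                n_div_warmup += diverged
                if window_idx < len(windows):
                    w0, w1 = windows[window_idx]
                    if w0 <= it < w1:
                        welford.push(current.theta)
                    if it == w1 - 1:
                        n = welford.n
                        if n > 4:
                            var = welford.variance()
                            self.inv_mass = var * n / (n + 5.0) + 1e-3 * (5.0 / (n + 5.0))
                        welford = _Welford(dim)
                        window_idx += 1
                        eps = math.exp(da.log_eps_bar) if da.count else eps
                        da.restart(eps)
                if it == n_warmup - 1:
                    eps = math.exp(da.log_eps_bar) if da.count else eps
            else:
                k = it - n_warmup
                draws[k] = current.theta
                divergent[k] = diverged
                depths[k] = depth
                accept_stats[k] = accept_stat
                logps[k] = current.lp

        return {
            "draws": draws,
            "divergent": divergent,
            "treedepth": depths,
            "accept_stat": accept_stats,
            "logp": logps,
            "step_size": eps,
            "inv_mass": self.inv_mass,
            "n_divergent_warmup": n_div_warmup,
            "n_grad_evals": self.n_grad_evals,
        }
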