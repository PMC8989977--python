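"""No-U-Turn sampler with dual-averaging step-size and windowed metric
adaptation (diagonal or dense).

A compact implementation of the classic recursive formulation (slice
variable, doubling until the trajectory starts to retrace, Stan-style
expanding warmup windows).  It targets an arbitrary differentiable
log-density supplied as a ``value_and_grad`` callable and is driven
entirely by a ``numpy.random.Generator``, so runs are bit-reproducible for
a given seed.  The dense metric matters here: the collapsed structural
model couples the baseline hazard, the Weibull shape and the latent-scale
coefficients strongly enough that a diagonal metric roughly quadruples the
tree depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


class Metric:
    """Euclidean metric M (the momentum covariance); stores M^{-1} = Sigma,
    an estimate of the posterior covariance."""

    def __init__(self, sigma: np.ndarray):
        sigma = np.asarray(sigma, float)
        self.diag = sigma.ndim == 1
        self.sigma = sigma
        if self.diag:
            self._sqrt_inv = 1.0 / np.sqrt(sigma)
        else:
            self._chol = cholesky(sigma, lower=True)

    @classmethod
    def identity(cls, dim: int) -> "Metric":
        return cls(np.ones(dim))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.sigma.shape[0] if not self.diag else self.sigma.size)
        if self.diag:
            return z * self._sqrt_inv
        # p ~ N(0, Sigma^{-1}):  solve L^T p = z  with Sigma = L L^T
        return solve_triangular(self._chol, z, lower=True, trans="T")

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.sigma * p if self.diag else self.sigma @ p

    def kinetic(self, p: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            k = 0.5 * float(p @ self.velocity(p))
        return k if np.isfinite(k) else np.inf


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_samples, dim), unconstrained scale
    logposts: np.ndarray
    divergences: int
    n_leapfrogs: int
    step_size: float
    accept_rate: float


def _leapfrog(value_and_grad, x, p, g, eps, metric):
    with np.errstate(over="ignore", invalid="ignore"):
        p = p + 0.5 * eps * g
        x = x + eps * metric.velocity(p)
        lp, g = value_and_grad(x)
        p = p + 0.5 * eps * g
    return x, p, g, lp


def find_reasonable_step_size(value_and_grad, x, rng, metric):
    eps = 1.0
    lp, g = value_and_grad(x)
    p = metric.sample_momentum(rng)
    h0 = lp - metric.kinetic(p)
    _, p1, _, lp1 = _leapfrog(value_and_grad, x, p, g, eps, metric)
    h1 = lp1 - metric.kinetic(p1) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, _, lp1 = _leapfrog(value_and_grad, x, p, g, eps, metric)
        h1 = lp1 - metric.kinetic(p1) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    __slots__ = (
        "x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
        "x_prop", "g_prop", "lp_prop", "n", "cont", "alpha", "n_alpha",
    )


def _build_tree(value_and_grad, x, p, g, logu, v, j, eps, h0, metric, rng, counters):
    if j == 0:
        x1, p1, g1, lp1 = _leapfrog(value_and_grad, x, p, g, v * eps, metric)
        counters["leapfrogs"] += 1
        h1 = lp1 - metric.kinetic(p1) if np.isfinite(lp1) else -np.inf
        tree = _Tree()
        tree.x_minus = tree.x_plus = tree.x_prop = x1
        tree.p_minus = tree.p_plus = p1
        tree.g_minus = tree.g_plus = tree.g_prop = g1
        tree.lp_prop = lp1
        tree.n = 1 if logu <= h1 else 0
        divergent = logu - MAX_ENERGY_ERROR >= h1
        if divergent:
            counters["divergences"] += 1
        tree.cont = not divergent
        tree.alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0)))) if np.isfinite(h1) else 0.0
        tree.n_alpha = 1
        return tree

    tree = _build_tree(value_and_grad, x, p, g, logu, v, j - 1, eps, h0, metric, rng, counters)
    if tree.cont:
        if v == -1:
            sub = _build_tree(
                value_and_grad, tree.x_minus, tree.p_minus, tree.g_minus,
                logu, v, j - 1, eps, h0, metric, rng, counters,
            )
            tree.x_minus, tree.p_minus, tree.g_minus = sub.x_minus, sub.p_minus, sub.g_minus
        else:
            sub = _build_tree(
                value_and_grad, tree.x_plus, tree.p_plus, tree.g_plus,
                logu, v, j - 1, eps, h0, metric, rng, counters,
            )
            tree.x_plus, tree.p_plus, tree.g_plus = sub.x_plus, sub.p_plus, sub.g_plus
        total = tree.n + sub.n
        if total > 0 and rng.random() < sub.n / total:
            tree.x_prop, tree.g_prop, tree.lp_prop = sub.x_prop, sub.g_prop, sub.lp_prop
        tree.alpha += sub.alpha
        tree.n_alpha += sub.n_alpha
        tree.n = total
        dx = tree.x_plus - tree.x_minus
        tree.cont = (
            sub.cont
            and float(dx @ metric.velocity(tree.p_minus)) >= 0.0
            and float(dx @ metric.velocity(tree.p_plus)) >= 0.0
        )
    return tree


def _warmup_windows(n_warmup: int) -> list[tuple[int, int]]:
    """(start, end) of the expanding covariance-estimation windows."""
    if n_warmup < 40:
        return [(int(0.2 * n_warmup), int(0.9 * n_warmup))]
    init = max(20, int(0.15 * n_warmup))
    term = max(10, int(0.10 * n_warmup))
    windows = []
    start, size = init, 25
    while start < n_warmup - term:
        end = min(start + size, n_warmup - term)
        if (n_warmup - term) - end < size:  # absorb the remainder
            end = n_warmup - term
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def _regularized_cov(samples: np.ndarray, dense: bool):
    arr = np.asarray(samples)
    nw = arr.shape[0]
    shrink = nw / (nw + 5.0)
    if dense and nw > arr.shape[1] + 4:
        cov = np.cov(arr, rowvar=False)
        return shrink * cov + 1e-3 * (1.0 - shrink) * np.eye(arr.shape[1])
    var = arr.var(axis=0, ddof=1)
    return shrink * var + 1e-3 * (1.0 - shrink)


def nuts(
    value_and_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    dense_mass: bool = True,
) -> NutsResult:
    dim = x0.size
    metric = Metric.identity(dim)
    x = np.asarray(x0, float).copy()
    lp, g = value_and_grad(x)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log-density at the initial point")

    eps = find_reasonable_step_size(value_and_grad, x, rng, metric)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = _warmup_windows(n_warmup)
    window_idx = 0
    window_buf: list[np.ndarray] = []

    draws = np.empty((n_samples, dim))
    logposts = np.empty(n_samples)
    counters = {"divergences": 0, "leapfrogs": 0}
    accept_sum = 0.0
    m_adapt = 0

    for it in range(n_warmup + n_samples):
        p = metric.sample_momentum(rng)
        h0 = lp - metric.kinetic(p)
        logu = h0 + np.log(rng.random())
        x_minus = x_plus = x
        p_minus = p_plus = p
        g_minus = g_plus = g
        x_prop, g_prop, lp_prop = x, g, lp
        n, cont, j = 1, True, 0
        alpha, n_alpha = 1.0, 1
        while cont and j < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                tree = _build_tree(
                    value_and_grad, x_minus, p_minus, g_minus,
                    logu, v, j, eps, h0, metric, rng, counters,
                )
                x_minus, p_minus, g_minus = tree.x_minus, tree.p_minus, tree.g_minus
            else:
                tree = _build_tree(
                    value_and_grad, x_plus, p_plus, g_plus,
                    logu, v, j, eps, h0, metric, rng, counters,
                )
                x_plus, p_plus, g_plus = tree.x_plus, tree.p_plus, tree.g_plus
            if tree.cont and tree.n > 0 and rng.random() < min(1.0, tree.n / n):
                x_prop, g_prop, lp_prop = tree.x_prop, tree.g_prop, tree.lp_prop
            n += tree.n
            alpha, n_alpha = tree.alpha, tree.n_alpha
            dx = x_plus - x_minus
            cont = (
                tree.cont
                and float(dx @ metric.velocity(p_minus)) >= 0.0
                and float(dx @ metric.velocity(p_plus)) >= 0.0
            )
            j += 1
        x, g, lp = x_prop, g_prop, lp_prop
        accept_stat = alpha / max(n_alpha, 1)

        if it < n_warmup:
            m_adapt += 1
            frac = 1.0 / (m_adapt + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(m_adapt) / gamma * h_bar
            step = m_adapt**-kappa
            log_eps_bar = step * log_eps + (1.0 - step) * log_eps_bar
            eps = float(np.exp(log_eps))
            if window_idx < len(windows):
                start, end = windows[window_idx]
                if start <= it < end:
                    window_buf.append(x.copy())
                if it == end - 1 and len(window_buf) > 4:
                    metric = Metric(_regularized_cov(window_buf, dense_mass))
                    window_buf = []
                    window_idx += 1
                    eps = find_reasonable_step_size(value_and_grad, x, rng, metric)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, m_adapt = np.log(eps), 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
                counters["divergences"] = 0  # report sampling-phase divergences only
        else:
            draws[it - n_warmup] = x
            logposts[it - n_warmup] = lp
            accept_sum += accept_stat

    return NutsResult(
        draws=draws,
        logposts=logposts,
        divergences=counters["divergences"],
        n_leapfrogs=counters["leapfrogs"],
        step_size=eps,
        accept_rate=accept_sum / max(n_samples, 1),
    )
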