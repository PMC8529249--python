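"""Gradient-based MCMC: a No-U-Turn sampler with warmup adaptation.

Self-contained NUTS (multinomial variant) over an arbitrary target
exposing ``logp_grad(theta) -> (float, ndarray)``.  Warmup adapts the
step size by dual averaging toward a target acceptance statistic and a
diagonal inverse metric from the sample variance in expanding memory
windows; both are frozen after warmup.  Everything is driven by a
``numpy.random.Generator`` so runs are reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NutsConfig", "nuts_sample"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsConfig:
    warmup: int = 1000
    draws: int = 1000
    max_treedepth: int = 10
    target_accept: float = 0.8
    init_buffer: int = 75
    term_buffer: int = 50
    base_window: int = 25
    # trajectory cap while the metric is still adapting; full depth after warmup
    warmup_max_treedepth: int = 6
    # seed the diagonal metric from local curvature at the start point;
    # without it the first warmup window runs with a unit metric, which is
    # painfully slow when coordinate scales differ by orders of magnitude
    curvature_init_metric: bool = True


def _curvature_metric(target, th, g, floor: float = 1e-8, cap: float = 100.0):
    """Inverse-metric guess 1 / max(-H_ii, eps) from finite differences
    of the gradient; directions with flat or positive curvature fall
    back to unit scale."""
    dim = th.shape[0]
    minv = np.ones(dim)
    h = 1e-4
    for i in range(dim):
        tp = th.copy()
        tp[i] += h
        _, gp = target.logp_grad(tp)
        tm = th.copy()
        tm[i] -= h
        _, gm = target.logp_grad(tm)
        hii = (gp[i] - gm[i]) / (2 * h)
        if np.isfinite(hii) and hii < -floor:
            minv[i] = min(cap, -1.0 / hii)
    return minv


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman)."""

    mu: float
    delta: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    count: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.delta - accept_prob)
        log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return math.exp(log_eps)


@dataclass
class _Welford:
    dim: int
    n: int = 0
    mean: np.ndarray = field(default=None)
    m2: np.ndarray = field(default=None)

    def __post_init__(self):
        self.mean = np.zeros(self.dim)
        self.m2 = np.zeros(self.dim)

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones(self.dim)
        var = self.m2 / (self.n - 1)
        # shrink toward unit scale for stability in short windows
        w = self.n / (self.n + 5.0)
        return w * var + (1 - w) * 1e-3


class _Tree:
    __slots__ = (
        "th_minus", "r_minus", "g_minus", "th_plus", "r_plus", "g_plus",
        "th_prop", "g_prop", "lp_prop", "log_w", "sum_accept", "n_accept",
        "diverged", "turned", "n_leapfrog",
    )


def _leapfrog(target, th, r, g, eps, minv):
    r1 = r + 0.5 * eps * g
    th1 = th + eps * minv * r1
    lp1, g1 = target.logp_grad(th1)
    r1 = r1 + 0.5 * eps * g1
    return th1, r1, g1, lp1


def _hamiltonian(lp, r, minv):
    return lp - 0.5 * float(np.sum(r * r * minv))


def _uturn(th_minus, r_minus, th_plus, r_plus, minv):
    d = th_plus - th_minus
    return (d @ (minv * r_minus) < 0) or (d @ (minv * r_plus) < 0)


def _build_tree(target, depth, th, r, g, direction, eps, h0, minv, rng):
    if depth == 0:
        th1, r1, g1, lp1 = _leapfrog(target, th, r, g, direction * eps, minv)
        h1 = _hamiltonian(lp1, r1, minv)
        t = _Tree()
        t.th_minus = t.th_plus = t.th_prop = th1
        t.r_minus = t.r_plus = r1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.lp_prop = lp1
        delta = h1 - h0
        if not np.isfinite(delta):
            delta = -np.inf
        t.log_w = delta
        t.sum_accept = min(1.0, math.exp(min(0.0, delta)))
        t.n_accept = 1
        t.diverged = delta < -_DIVERGENCE_THRESHOLD
        t.turned = False
        t.n_leapfrog = 1
        return t

    first = _build_tree(target, depth - 1, th, r, g, direction, eps, h0, minv, rng)
    if first.diverged or first.turned:
        return first
    if direction == 1:
        second = _build_tree(
            target, depth - 1, first.th_plus, first.r_plus, first.g_plus,
            direction, eps, h0, minv, rng,
        )
        first.th_plus, first.r_plus, first.g_plus = (
            second.th_plus, second.r_plus, second.g_plus,
        )
    else:
        second = _build_tree(
            target, depth - 1, first.th_minus, first.r_minus, first.g_minus,
            direction, eps, h0, minv, rng,
        )
        first.th_minus, first.r_minus, first.g_minus = (
            second.th_minus, second.r_minus, second.g_minus,
        )
    first.n_leapfrog += second.n_leapfrog
    first.sum_accept += second.sum_accept
    first.n_accept += second.n_accept
    first.diverged = second.diverged
    total = np.logaddexp(first.log_w, second.log_w)
    # multinomial sampling within the subtree
    if math.log(rng.uniform()) < second.log_w - total:
        first.th_prop, first.g_prop, first.lp_prop = (
            second.th_prop, second.g_prop, second.lp_prop,
        )
    first.log_w = total
    first.turned = second.turned or _uturn(
        first.th_minus, first.r_minus, first.th_plus, first.r_plus, minv
    )
    return first


def _find_initial_step(target, th, lp, g, minv, rng):
    """Crude bisection to an acceptance ratio around 0.5."""
    eps = 1.0
    r = rng.standard_normal(th.shape) / np.sqrt(minv)
    h0 = _hamiltonian(lp, r, minv)
    _, r1, _, lp1 = _leapfrog(target, th, r, g, eps, minv)
    h1 = _hamiltonian(lp1, r1, minv)
    delta = h1 - h0 if np.isfinite(h1) else -np.inf
    direction = 1 if delta > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, r1, _, lp1 = _leapfrog(target, th, r, g, eps, minv)
        h1 = _hamiltonian(lp1, r1, minv)
        delta = h1 - h0 if np.isfinite(h1) else -np.inf
        if (direction == 1) != (delta > math.log(0.5)):
            break
    return eps


def _adaptation_schedule(warmup: int, cfg: NutsConfig) -> list[int]:
    """Iteration indices at which the metric window closes."""
    init, term, base = cfg.init_buffer, cfg.term_buffer, cfg.base_window
    if warmup < init + term + base:
        init = int(0.15 * warmup)
        term = int(0.10 * warmup)
        base = max(1, warmup - init - term)
    ends = []
    start, size = init, base
    while start + size < warmup - term:
        if start + 3 * size >= warmup - term:
            size = warmup - term - start  # absorb the slack
        ends.append(start + size)
        start += size
        size *= 2
    if not ends and warmup > init + term:
        ends.append(warmup - term)
    return ends


def nuts_sample(target, theta0, cfg: NutsConfig, rng: np.random.Generator, init_inv_metric=None):
    """Run one NUTS chain; returns (draws, stats).

    ``draws`` has shape (cfg.draws, dim); ``stats`` carries per-draw
    tree depth / leapfrog counts / divergence flags and the adapted
    step size and metric.  ``init_inv_metric`` lets chains of one fit
    share a precomputed starting metric.
    """
    th = np.asarray(theta0, dtype=float).copy()
    lp, g = target.logp_grad(th)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite density")
    dim = th.shape[0]
    if init_inv_metric is not None:
        minv = np.asarray(init_inv_metric, dtype=float).copy()
    elif cfg.curvature_init_metric:
        minv = _curvature_metric(target, th, g)
    else:
        minv = np.ones(dim)
    eps = _find_initial_step(target, th, lp, g, minv, rng)
    da = _DualAveraging(mu=math.log(10.0 * eps), delta=cfg.target_accept)
    welford = _Welford(dim)
    window_ends = _adaptation_schedule(cfg.warmup, cfg)

    n_total = cfg.warmup + cfg.draws
    draws = np.empty((cfg.draws, dim))
    depth_stat = np.zeros(cfg.draws, dtype=np.int64)
    leapfrog_stat = np.zeros(cfg.draws, dtype=np.int64)
    divergent_stat = np.zeros(cfg.draws, dtype=bool)
    energy_stat = np.zeros(cfg.draws)
    n_divergent_warmup = 0

    for it in range(n_total):
        r = rng.standard_normal(dim) / np.sqrt(minv)
        h0 = _hamiltonian(lp, r, minv)
        tree = _Tree()
        tree.th_minus = tree.th_plus = tree.th_prop = th
        tree.r_minus = tree.r_plus = r
        tree.g_minus = tree.g_plus = tree.g_prop = g
        tree.lp_prop = lp
        tree.log_w = 0.0
        tree.sum_accept = 0.0
        tree.n_accept = 0
        tree.diverged = False
        tree.turned = False
        tree.n_leapfrog = 0
        depth = 0
        depth_limit = (
            min(cfg.max_treedepth, cfg.warmup_max_treedepth)
            if it < cfg.warmup
            else cfg.max_treedepth
        )
        while depth < depth_limit:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == 1:
                sub = _build_tree(
                    target, depth, tree.th_plus, tree.r_plus, tree.g_plus,
                    1, eps, h0, minv, rng,
                )
            else:
                sub = _build_tree(
                    target, depth, tree.th_minus, tree.r_minus, tree.g_minus,
                    -1, eps, h0, minv, rng,
                )
            tree.n_leapfrog += sub.n_leapfrog
            tree.sum_accept += sub.sum_accept
            tree.n_accept += sub.n_accept
            if sub.diverged:
                tree.diverged = True
                break
            if sub.turned:
                break
            # biased progressive sampling favours the new subtree
            if math.log(rng.uniform()) < sub.log_w - tree.log_w:
                tree.th_prop, tree.g_prop, tree.lp_prop = (
                    sub.th_prop, sub.g_prop, sub.lp_prop,
                )
            tree.log_w = np.logaddexp(tree.log_w, sub.log_w)
            if direction == 1:
                tree.th_plus, tree.r_plus, tree.g_plus = (
                    sub.th_plus, sub.r_plus, sub.g_plus,
                )
            else:
                tree.th_minus, tree.r_minus, tree.g_minus = (
                    sub.th_minus, sub.r_minus, sub.g_minus,
                )
            if _uturn(tree.th_minus, tree.r_minus, tree.th_plus, tree.r_plus, minv):
                break
            depth += 1

        th, g, lp = tree.th_prop, tree.g_prop, tree.lp_prop
        accept_prob = tree.sum_accept / max(1, tree.n_accept)

        if it < cfg.warmup:
            eps = da.update(accept_prob)
            if tree.diverged:
                n_divergent_warmup += 1
            welford.add(th)
            if window_ends and it + 1 == window_ends[0]:
                minv = welford.variance()
                welford = _Welford(dim)
                window_ends.pop(0)
                eps = _find_initial_step(target, th, lp, g, minv, rng)
                da = _DualAveraging(mu=math.log(10.0 * eps), delta=cfg.target_accept)
            if it + 1 == cfg.warmup:
                eps = math.exp(da.log_eps_bar)
        else:
            k = it - cfg.warmup
            draws[k] = th
            depth_stat[k] = depth
            leapfrog_stat[k] = tree.n_leapfrog
            divergent_stat[k] = tree.diverged
            energy_stat[k] = -h0

    stats = {
        "step_size": eps,
        "inv_metric": minv,
        "tree_depth": depth_stat,
        "n_leapfrog": leapfrog_stat,
        "divergent": divergent_stat,
        "energy": energy_stat,
        "n_divergent_warmup": n_divergent_warmup,
    }
    return draws, stats
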