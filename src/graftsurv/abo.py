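"""African Buffalo Optimization: a population metaheuristic for box-bounded
continuous minimization, with a binary adaptation for feature-subset search.

Each of ``n_buffalo`` animals carries an exploitation position ``w`` and an
exploration move ``m``. One iteration updates, elementwise,

    m <- m + le1 * (bg - w) + le2 * (bp - w)        (democratic + intelligence)
    w <- clamp(w + m / lambda_star, bounds)

where ``bg`` is the herd-wide best position found so far and ``bp`` the
buffalo's own personal best; ``le1`` and ``le2`` are the learning factors
weighting attraction to the herd's consensus and to individual memory, and
``lambda_star`` acts as a unit of time scaling the move into a step. The
update itself is deterministic; stochasticity enters through the uniform
initialization of ``w`` and through stagnation restarts, which re-scatter
every buffalo except the incumbent best when the herd best has not improved
for ``restart_patience`` iterations.

For feature selection a real position is mapped to a boolean mask through a
sigmoid (or raw-threshold) transfer function; an all-false mask is repaired
by switching on the highest-scoring coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError

__all__ = [
    "ABOConfig",
    "Herd",
    "ABOResult",
    "init_herd",
    "update_exploration",
    "update_position",
    "minimize",
    "binarize_position",
]


@dataclass
class ABOConfig:
    """Herd size, learning factors, bounds and stopping settings.

    Defaults follow the conventions of the originating swarm literature:
    herd of 20, le1=0.6 (herd/democratic attraction), le2=0.5 (personal
    memory), lambda_star=1.
    """

    n_buffalo: int = 20
    le1: float = 0.6
    le2: float = 0.5
    lambda_star: float = 1.0
    bounds: tuple[float, float] = (-5.0, 5.0)
    max_iterations: int = 200
    restart_patience: int = 10
    restart_shrink: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_buffalo < 1:
            raise ConfigurationError("n_buffalo must be positive")
        if self.le1 < 0 or self.le2 < 0:
            raise ConfigurationError("learning factors must be non-negative")
        if self.lambda_star <= 0:
            raise ConfigurationError("lambda_star must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be positive")
        if self.restart_patience < 1:
            raise ConfigurationError("restart_patience must be positive")
        if not 0.0 < self.restart_shrink <= 1.0:
            raise ConfigurationError("restart_shrink must lie in (0, 1]")
        low, high = self.bounds
        if not low < high:
            raise ConfigurationError("bounds must satisfy low < high")


@dataclass
class Herd:
    """Optimizer state: positions, moves, personal bests, herd best."""

    w: np.ndarray  # (n_buffalo, dims) exploitation positions
    m: np.ndarray  # (n_buffalo, dims) exploration moves
    bp: np.ndarray  # (n_buffalo, dims) personal best positions
    bp_f: np.ndarray  # (n_buffalo,) personal best fitness
    bg: np.ndarray = field(repr=False)  # (dims,) herd best position
    bg_f: float = np.inf


@dataclass
class ABOResult:
    best_x: np.ndarray
    best_f: float
    history: np.ndarray  # best-so-far fitness after each iteration
    n_restarts: int = 0


def _evaluate(objective, W: np.ndarray) -> np.ndarray:
    f = np.array([float(objective(w)) for w in W])
    if not np.all(np.isfinite(f)):
        bad = W[int(np.flatnonzero(~np.isfinite(f))[0])]
        raise ConfigurationError(f"objective returned a non-finite value at {bad}")
    return f


def init_herd(
    objective,
    dims: int,
    config: ABOConfig,
    rng: np.random.Generator | None = None,
    x0: np.ndarray | None = None,
) -> Herd:
    """Scatter the herd uniformly within bounds and record initial bests.

    ``x0`` optionally seeds the first herd rows with caller-chosen
    positions (e.g. a known-good feature mask), clipped to bounds.
    """
    if dims < 1:
        raise ConfigurationError("dims must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    low, high = config.bounds
    w = rng.uniform(low, high, size=(config.n_buffalo, dims))
    if x0 is not None:
        x0 = np.atleast_2d(np.asarray(x0, dtype=float))
        k = min(len(x0), config.n_buffalo)
        w[:k] = np.clip(x0[:k], low, high)
    f = _evaluate(objective, w)
    best = int(np.argmin(f))
    return Herd(
        w=w,
        m=np.zeros_like(w),
        bp=w.copy(),
        bp_f=f,
        bg=w[best].copy(),
        bg_f=float(f[best]),
    )


def update_exploration(herd: Herd, config: ABOConfig) -> Herd:
    """m <- m + le1*(bg - w) + le2*(bp - w), elementwise (in place)."""
    herd.m += config.le1 * (herd.bg[None, :] - herd.w)
    herd.m += config.le2 * (herd.bp - herd.w)
    return herd


def update_position(herd: Herd, config: ABOConfig) -> Herd:
    """w <- w + m/lambda_star, clamped to bounds (in place)."""
    low, high = config.bounds
    herd.w += herd.m / config.lambda_star
    np.clip(herd.w, low, high, out=herd.w)
    return herd


def _update_bests(herd: Herd, f: np.ndarray) -> bool:
    """Refresh personal and herd bests; True iff the herd best improved."""
    improved = f < herd.bp_f
    herd.bp[improved] = herd.w[improved]
    herd.bp_f[improved] = f[improved]
    best = int(np.argmin(herd.bp_f))
    if herd.bp_f[best] < herd.bg_f:
        herd.bg = herd.bp[best].copy()
        herd.bg_f = float(herd.bp_f[best])
        return True
    return False


def minimize(
    objective,
    dims: int,
    config: ABOConfig,
    x0: np.ndarray | None = None,
) -> ABOResult:
    """Run the herd for ``max_iterations`` and return the best point found.

    The best-so-far history is non-increasing by construction. When the
    herd best stagnates for ``restart_patience`` consecutive iterations,
    every buffalo except the incumbent best is re-scattered uniformly in a
    box centred on the herd best (elitism), its move zeroed and its
    personal best reset to the fresh position. The scatter radius starts
    at half the bound width and shrinks by ``restart_shrink`` at each
    restart, so restarts progressively refine around the incumbent rather
    than resampling globally -- the elementwise update itself has no
    damping, so this schedule is what drives late-stage convergence.
    """
    rng = np.random.default_rng(config.seed)
    herd = init_herd(objective, dims, config, rng=rng, x0=x0)
    low, high = config.bounds
    history = np.empty(config.max_iterations)
    stall = 0
    n_restarts = 0
    radius = (high - low) / 2.0
    for t in range(config.max_iterations):
        update_exploration(herd, config)
        update_position(herd, config)
        f = _evaluate(objective, herd.w)
        if _update_bests(herd, f):
            stall = 0
        else:
            stall += 1
        if stall >= config.restart_patience:
            radius *= config.restart_shrink
            elite = int(np.argmin(herd.bp_f))
            others = np.arange(config.n_buffalo) != elite
            if others.any():
                fresh = herd.bg[None, :] + rng.uniform(
                    -radius, radius, size=(int(others.sum()), dims)
                )
                np.clip(fresh, low, high, out=fresh)
                herd.w[others] = fresh
                herd.m[others] = 0.0
                fr = _evaluate(objective, fresh)
                herd.bp[others] = fresh
                herd.bp_f[others] = fr
                if fr.min() < herd.bg_f:
                    herd.bg = fresh[int(np.argmin(fr))].copy()
                    herd.bg_f = float(fr.min())
            stall = 0
            n_restarts += 1
        history[t] = herd.bg_f
    return ABOResult(
        best_x=herd.bg.copy(),
        best_f=herd.bg_f,
        history=history,
        n_restarts=n_restarts,
    )


def binarize_position(
    w_row: np.ndarray, transfer: str = "sigmoid", cutoff: float = 0.5
) -> np.ndarray:
    """Map a real position to a boolean feature mask.

    ``sigmoid`` passes coordinates through the logistic function before
    comparing to ``cutoff``; ``threshold`` compares raw coordinates. An
    empty mask is repaired by switching on the single highest-scoring
    coordinate, so a mask is never all-false.
    """
    w_row = np.asarray(w_row, dtype=float)
    if transfer == "sigmoid":
        scores = expit(w_row)
    elif transfer == "threshold":
        scores = w_row
    else:
        raise ConfigurationError(f"unknown transfer function: {transfer!r}")
    mask = scores > cutoff
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(scores))] = True
    return mask
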