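"""Maximum-likelihood objective and optimizers for 3D structure inference.

Model
-----
Given target distances D_1..D_n (one per restrained bin pair) and a candidate
structure S with model distances D_i^s, the residuals are assumed i.i.d.
Gaussian with a single global standard deviation sigma.  Profiling sigma out
at its MLE, sigma = sqrt(SSE / n) with SSE = sum_i (D_i^s - D_i)^2, leaves the
log-likelihood

    L(S) = -n/2 - n * ln sigma

which depends on the coordinates only through SSE.  L is maximized by plain
gradient ascent, S <- S + lambda * grad L(S), with either a constant learning
rate or a step-decay schedule (halving every 70 epochs), or by AdaGrad, which
rescales each coordinate's step by the accumulated squared gradient.

Convergence is declared when the absolute change in L between successive
iterations drops below ``epsilon_conv``.  A perfect fit (SSE = 0) makes L
diverge to +infinity; it is reported via a large finite sentinel and treated
as converged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .restraints import RestraintSet

__all__ = [
    "Structure3D",
    "OptimConfig",
    "OptimTrace",
    "OptimizationDiverged",
    "PERFECT_FIT_LL",
    "init_structure",
    "log_likelihood",
    "gradient",
    "learning_rate",
    "optimize_gradient_ascent",
    "optimize_adagrad",
    "optimize",
]

# Sentinel log-likelihood reported when SSE = 0 (L is unbounded above there).
PERFECT_FIT_LL = 1e12
# sigma below this is treated as a perfect fit.
_SIGMA_FLOOR = 1e-12
# Guard added to model distances in the gradient denominator so exactly
# coincident beads cannot divide by zero.
_COINCIDENT_GUARD = 1e-9
# Maximum step halvings per gradient-ascent iteration.
_MAX_BACKTRACKS = 30


@dataclass
class Structure3D:
    """Ordered bead coordinates, one bead per active (modeled) bin.

    ``bin_map[k]`` is the original contact-matrix bin of bead k, so filtered
    gaps can be re-inserted when exporting.
    """

    coords: np.ndarray
    bin_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.bin_map is None:
            self.bin_map = np.arange(self.n_beads)
        else:
            self.bin_map = np.asarray(self.bin_map, dtype=int)
            if len(self.bin_map) != self.n_beads:
                raise ValueError("bin_map length must equal number of beads")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        """Condensed vector of all n*(n-1)/2 inter-bead distances."""
        from scipy.spatial.distance import pdist

        return pdist(self.coords)


@dataclass
class OptimConfig:
    """Optimizer hyperparameters.

    ``lr=None`` resolves to the defaults: 0.0001 for a constant schedule,
    initial 0.01 for step decay, and 0.01 for AdaGrad.
    """

    optimizer: str = "gradient_ascent"  # or "adagrad"
    schedule: str = "step_decay"  # or "constant"
    lr: float | None = None
    epsilon_conv: float = 0.0001
    adagrad_eps: float = 1e-6
    max_iters: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.optimizer not in ("gradient_ascent", "adagrad"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.schedule not in ("constant", "step_decay"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.lr is not None and self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epsilon_conv <= 0 or self.adagrad_eps <= 0:
            raise ValueError("epsilon_conv and adagrad_eps must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")

    @property
    def resolved_lr(self) -> float:
        if self.lr is not None:
            return self.lr
        if self.optimizer == "adagrad":
            return 0.01
        return 0.0001 if self.schedule == "constant" else 0.01


@dataclass
class OptimTrace:
    """Per-iteration record of one optimization run."""

    likelihoods: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    converged: bool = False
    diverged: bool = False
    sigma_final: float = float("nan")

    @property
    def iterations(self) -> int:
        return len(self.likelihoods)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            for t, ll in enumerate(self.likelihoods):
                fh.write(f"{t}\t{ll:.10g}\n")


class OptimizationDiverged(RuntimeError):
    """Log-likelihood became non-finite; try a smaller learning rate."""

    def __init__(self, message: str, trace: OptimTrace):
        super().__init__(message)
        self.trace = trace


def init_structure(
    n_bins: int, seed: int | None = None, bin_map: np.ndarray | None = None
) -> Structure3D:
    """Random structure with each coordinate uniform in [-0.5, 0.5]."""
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, got {n_bins}")
    rng = np.random.default_rng(seed)
    return Structure3D(rng.uniform(-0.5, 0.5, size=(n_bins, 3)), bin_map=bin_map)


def _model_distances(coords: np.ndarray, r: RestraintSet) -> np.ndarray:
    diff = coords[r.i] - coords[r.j]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def _sse(coords: np.ndarray, r: RestraintSet) -> float:
    res = _model_distances(coords, r) - r.d
    return float(res @ res)


def log_likelihood(s: Structure3D, r: RestraintSet) -> float:
    """Profile log-likelihood L = -n/2 - n ln sigma, sigma = sqrt(SSE/n)."""
    if r.n < 1:
        raise ValueError("empty restraint set")
    n = r.n
    sigma = math.sqrt(_sse(s.coords, r) / n)
    if sigma < _SIGMA_FLOOR:
        return PERFECT_FIT_LL
    return -n / 2.0 - n * math.log(sigma)


def gradient(s: Structure3D, r: RestraintSet) -> np.ndarray:
    """Analytic gradient of the log-likelihood w.r.t. bead coordinates.

    dL/dp_a = -(n/SSE) * sum_{(a,b)} (D_ab^s - D_ab) (p_a - p_b) / D_ab^s,
    with a small additive guard on D_ab^s against coincident beads.  Exactly
    zero at a perfect fit.
    """
    if r.n < 1:
        raise ValueError("empty restraint set")
    coords = s.coords
    diff = coords[r.i] - coords[r.j]
    ds = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    res = ds - r.d
    sse = float(res @ res)
    grad = np.zeros_like(coords)
    if sse == 0.0:
        return grad
    coef = -(r.n / sse) * res / (ds + _COINCIDENT_GUARD)
    contrib = coef[:, None] * diff
    for axis in range(3):
        grad[:, axis] += np.bincount(
            r.i, weights=contrib[:, axis], minlength=s.n_beads
        )
        grad[:, axis] -= np.bincount(
            r.j, weights=contrib[:, axis], minlength=s.n_beads
        )
    return grad


def learning_rate(schedule: str, initial_lr: float, epoch: int) -> float:
    """Learning rate at a given epoch.

    ``constant`` returns ``initial_lr``; ``step_decay`` halves it every 70
    epochs via the continuous form initial_lr * 0.5**((1 + epoch) / 70).
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if schedule == "constant":
        return initial_lr
    if schedule == "step_decay":
        return initial_lr * 0.5 ** ((1 + epoch) / 70.0)
    raise ValueError(f"unknown schedule {schedule!r}")


def _run(
    r: RestraintSet,
    cfg: OptimConfig,
    seed: int | None,
    adagrad: bool,
) -> tuple[Structure3D, OptimTrace]:
    if seed is None:
        seed = cfg.seed
    s = init_structure(r.n_beads, seed=seed)
    coords = s.coords
    trace = OptimTrace()
    lr0 = cfg.resolved_lr
    ll_old = log_likelihood(s, r)
    g_accum = np.zeros_like(coords) if adagrad else None
    shrink = 1.0  # persistent backtracking factor; deterministic
    for t in range(cfg.max_iters):
        g = gradient(s, r)
        if adagrad:
            g_accum += g * g
            lam = lr0
            coords += lam / np.sqrt(g_accum + cfg.adagrad_eps) * g
            ll = log_likelihood(s, r)
        else:
            # Guarded ascent: the scheduled step is halved (deterministically,
            # up to _MAX_BACKTRACKS times) while it would lower L, since large
            # rates oscillate around the optimum instead of climbing to it.
            # The shrink factor persists across iterations (and relaxes after
            # clean accepts) so the guard costs O(1) extra evaluations.
            lam = learning_rate(cfg.schedule, lr0, t) * shrink
            base = coords.copy()
            for halvings in range(_MAX_BACKTRACKS):
                coords[...] = base + lam * g
                ll = log_likelihood(s, r)
                if ll >= ll_old or not np.isfinite(ll):
                    break
                lam *= 0.5
                shrink *= 0.5
            if halvings == 0:
                shrink = min(1.0, shrink * 2.0)
        trace.likelihoods.append(ll)
        trace.lrs.append(lam)
        if not np.isfinite(ll):
            trace.diverged = True
            raise OptimizationDiverged(
                "log-likelihood became non-finite; try a smaller learning rate",
                trace,
            )
        if ll >= PERFECT_FIT_LL:
            trace.converged = True
            break
        if abs(ll - ll_old) < cfg.epsilon_conv:
            trace.converged = True
            break
        ll_old = ll
    res = _model_distances(coords, r) - r.d
    trace.sigma_final = math.sqrt(float(res @ res) / r.n)
    return s, trace


def optimize_gradient_ascent(
    r: RestraintSet, cfg: OptimConfig | None = None, seed: int | None = None
) -> tuple[Structure3D, OptimTrace]:
    """Maximize L(S) by gradient ascent from a random initial structure."""
    cfg = cfg or OptimConfig()
    if cfg.optimizer != "gradient_ascent":
        raise ValueError("config requests a different optimizer")
    return _run(r, cfg, seed, adagrad=False)


def optimize_adagrad(
    r: RestraintSet, cfg: OptimConfig | None = None, seed: int | None = None
) -> tuple[Structure3D, OptimTrace]:
    """Maximize L(S) with per-coordinate AdaGrad step sizes.

    Each coordinate's step is lambda / sqrt(G_t + eps) * g_t where G_t
    accumulates that coordinate's squared gradients from the first step.
    """
    cfg = cfg or OptimConfig(optimizer="adagrad")
    if cfg.optimizer != "adagrad":
        raise ValueError("config requests a different optimizer")
    return _run(r, cfg, seed, adagrad=True)


def optimize(
    r: RestraintSet, cfg: OptimConfig | None = None, seed: int | None = None
) -> tuple[Structure3D, OptimTrace]:
    """Dispatch on ``cfg.optimizer``."""
    cfg = cfg or OptimConfig()
    if cfg.optimizer == "adagrad":
        return optimize_adagrad(r, cfg, seed)
    return optimize_gradient_ascent(r, cfg, seed)
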