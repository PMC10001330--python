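"""Marine Predators Algorithm (MPA) for bounded continuous optimization.

MPA is a population metaheuristic inspired by foraging strategies of ocean
predators.  A Prey matrix of n candidate d-vectors is updated against an
Elite matrix (the best agent found so far, conceptually replicated n
times) through three phases tied to the predator/prey velocity ratio:

* phase 1 (first third of iterations, exploration): Brownian prey moves,
  ``Step = RB (x) (Elite - RB (x) Prey)``, ``Prey <- Prey + P * R (x) Step``;
* phase 2 (middle third, transition): the first half of the population
  takes Levy prey moves, the second half Brownian predator moves scaled by
  the adaptive factor ``CF = (1 - I/Imax)^(2 I/Imax)``;
* phase 3 (final third, exploitation): Levy predator moves around the
  elite, scaled by ``P * CF``.

After every move a fish-aggregating-devices (FADs) perturbation applies an
occasional long jump (probability ``FADs = 0.2``) to escape local optima.
Per-agent memory saving (an agent reverts to its previous position when
that position scored better) plus the elite update make the best-fitness
history non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "SearchSpace", "MPAConfig", "StepContext", "OptimizeResult",
    "init_population", "compute_cf", "levy_vector",
    "phase1_update", "phase2_update", "phase3_update", "fads_effect",
    "optimize", "error_rate", "hyperparameter_space", "decode_candidate",
    "classifier_error_fitness", "TrainBundle",
]


@dataclass
class SearchSpace:
    """Box-bounded search domain with per-coordinate decoding tags."""

    lb: np.ndarray
    ub: np.ndarray
    kinds: Optional[Sequence[str]] = None  # continuous | integer | log_scale

    def __post_init__(self) -> None:
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.lb.shape != self.ub.shape:
            raise ValueError("lb and ub must have the same shape")
        if not np.all(self.lb < self.ub):
            raise ValueError("lb must be strictly below ub elementwise")
        if self.kinds is None:
            self.kinds = ("continuous",) * self.d

    @property
    def d(self) -> int:
        return self.lb.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)


@dataclass
class MPAConfig:
    n: int = 25
    Imax: int = 100
    P: float = 0.5
    FADs: float = 0.2
    levy_alpha: float = 1.5
    levy_scale: float = 0.05
    seed: int = 0
    eq11_literal: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.Imax < 0:
            raise ValueError("Imax must be >= 0")
        if not 0.0 <= self.FADs <= 1.0:
            raise ValueError("FADs must lie in [0, 1]")
        if self.P <= 0:
            raise ValueError("P must be positive")


@dataclass
class StepContext:
    """Random draws for one iteration; pinnable for worked examples.

    RB are Brownian (standard normal) draws, RL Levy draws (already scaled
    by ``levy_scale``), R uniforms for the prey moves, CF the adaptive step
    factor.  The FADs fields hold the per-agent trigger uniforms ``r``, the
    binary mask ``U``, the jump uniforms and the two shuffled agent indices.
    """

    RB: np.ndarray
    RL: np.ndarray
    R: np.ndarray
    CF: float
    r: np.ndarray
    U: np.ndarray
    R_fads: np.ndarray
    r1: np.ndarray
    r2: np.ndarray

    @classmethod
    def draw(cls, n: int, d: int, cf: float, cfg: MPAConfig,
             rng: np.random.Generator) -> "StepContext":
        return cls(
            RB=rng.standard_normal((n, d)),
            RL=cfg.levy_scale * levy_vector((n, d), cfg.levy_alpha, rng),
            R=rng.uniform(size=(n, d)),
            CF=cf,
            r=rng.uniform(size=n),
            U=(rng.uniform(size=(n, d)) < cfg.FADs).astype(float),
            R_fads=rng.uniform(size=(n, d)),
            r1=rng.permutation(n),
            r2=rng.permutation(n),
        )


@dataclass
class OptimizeResult:
    best_x: np.ndarray
    best_f: float
    history: np.ndarray  # best-so-far fitness after each evaluation round
    evals: int


def init_population(space: SearchSpace, cfg: MPAConfig,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Uniform seeded initialization: ``X_j = lb_j + rand * (ub_j - lb_j)``."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return space.lb + rng.uniform(size=(cfg.n, space.d)) * (space.ub - space.lb)


def compute_cf(iteration: int, Imax: int) -> float:
    """Adaptive step factor ``(1 - I/Imax)^(2 I/Imax)``.

    Equals 1 at the first iteration and 0 at the last, shrinking predator
    moves as the search turns from exploration to exploitation.
    """
    if Imax < 1:
        raise ValueError("Imax must be >= 1")
    if not 0 <= iteration <= Imax:
        raise ValueError(f"iteration {iteration} outside [0, {Imax}]")
    frac = iteration / Imax
    return float((1.0 - frac) ** (2.0 * frac))


def levy_vector(shape, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed stable draws via the Mantegna algorithm.

    Returns ``u / |v|^(1/alpha)`` with ``u ~ N(0, sigma_u^2)``,
    ``v ~ N(0, 1)`` and ``sigma_u`` chosen so the ratio follows a symmetric
    alpha-stable law; the tail index of |draws| is ``alpha``.
    """
    if not 1.0 < alpha <= 2.0:
        raise ValueError("alpha must lie in (1, 2]")
    num = math.gamma(1.0 + alpha) * math.sin(math.pi * alpha / 2.0)
    den = math.gamma((1.0 + alpha) / 2.0) * alpha * 2.0 ** ((alpha - 1.0) / 2.0)
    sigma_u = (num / den) ** (1.0 / alpha)
    u = rng.normal(0.0, sigma_u, size=shape)
    v = rng.standard_normal(size=shape)
    return u / np.abs(v) ** (1.0 / alpha)


def _first_half(n: int) -> int:
    return -(-n // 2)  # ceil(n / 2): the middle agent of an odd population


def phase1_update(prey: np.ndarray, elite: np.ndarray, ctx: StepContext,
                  cfg: MPAConfig) -> np.ndarray:
    """High-velocity-ratio exploration: Brownian prey moves for all agents."""
    step = ctx.RB * (elite - ctx.RB * prey)
    return prey + cfg.P * ctx.R * step


def phase2_update(prey: np.ndarray, elite: np.ndarray, ctx: StepContext,
                  cfg: MPAConfig) -> np.ndarray:
    """Unit-velocity-ratio transition: Levy prey / Brownian predator halves."""
    n = prey.shape[0]
    h = _first_half(n)
    out = prey.copy()
    step1 = ctx.RL[:h] * (elite - ctx.RL[:h] * prey[:h])
    out[:h] = prey[:h] + cfg.P * ctx.R[:h] * step1
    step2 = ctx.RB[h:] * (elite - prey[h:])
    out[h:] = elite + cfg.P * ctx.CF * step2
    return out


def phase3_update(prey: np.ndarray, elite: np.ndarray, ctx: StepContext,
                  cfg: MPAConfig) -> np.ndarray:
    """Low-velocity-ratio exploitation: Levy predator moves for all agents.

    The default step is ``RL (x) (RL (x) Elite - Prey)``; setting
    ``eq11_literal`` drops the inner Levy factor, giving
    ``RL (x) (Elite - Prey)``.
    """
    if cfg.eq11_literal:
        step = ctx.RL * (elite - prey)
    else:
        step = ctx.RL * (ctx.RL * elite - prey)
    return elite + cfg.P * ctx.CF * step


def fads_effect(prey: np.ndarray, space: SearchSpace, ctx: StepContext,
                cfg: MPAConfig) -> np.ndarray:
    """Fish-aggregating-devices perturbation: occasional long jumps.

    Per agent: with probability FADs, jump toward a random in-bounds point
    through a sparse binary mask scaled by CF; otherwise drift along the
    difference of two randomly chosen agents.
    """
    jump = ctx.CF * (space.lb + ctx.R_fads * (space.ub - space.lb)) * ctx.U
    drift = ((cfg.FADs * (1.0 - ctx.r) + ctx.r)[:, None]
             * (prey[ctx.r1] - prey[ctx.r2]))
    take_jump = (ctx.r <= cfg.FADs)[:, None]
    return prey + np.where(take_jump, jump, drift)


def _phase_of(iteration: int, Imax: int) -> int:
    """1, 2 or 3 — which update rule iteration ``I`` (0-based) uses."""
    if iteration < Imax // 3:
        return 1
    if iteration < (2 * Imax) // 3:
        return 2
    return 3


def optimize(fitness: Callable[[np.ndarray], float], space: SearchSpace,
             cfg: MPAConfig) -> OptimizeResult:
    """Run the full MPA loop and return the best solution found.

    ``fitness`` maps any in-bounds d-vector to a finite scalar; lower is
    better.  Every candidate ever evaluated lies inside the bounds, and the
    returned history (best fitness after each evaluation round, including
    the initial population) is non-increasing.  Identical seed and config
    give identical results.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n, space.d

    def evaluate(pos: np.ndarray) -> np.ndarray:
        vals = np.empty(pos.shape[0])
        for i, x in enumerate(pos):
            v = float(fitness(x))
            if not np.isfinite(v):
                raise ValueError(f"fitness returned non-finite value {v} at {x}")
            vals[i] = v
        return vals

    prey = init_population(space, cfg, rng)
    fit = evaluate(prey)
    evals = n
    best_i = int(np.argmin(fit))
    elite_x, elite_f = prey[best_i].copy(), float(fit[best_i])
    history = [elite_f]

    for I in range(cfg.Imax):
        cf = compute_cf(I, cfg.Imax)
        ctx = StepContext.draw(n, d, cf, cfg, rng)
        phase = _phase_of(I, cfg.Imax)
        if phase == 1:
            moved = phase1_update(prey, elite_x, ctx, cfg)
        elif phase == 2:
            moved = phase2_update(prey, elite_x, ctx, cfg)
        else:
            moved = phase3_update(prey, elite_x, ctx, cfg)
        moved = fads_effect(moved, space, ctx, cfg)
        moved = space.clamp(moved)

        new_fit = evaluate(moved)
        evals += n
        better = new_fit < fit  # memory saving: revert agents that got worse
        prey = np.where(better[:, None], moved, prey)
        fit = np.where(better, new_fit, fit)

        best_i = int(np.argmin(fit))
        if fit[best_i] < elite_f:  # strict improvement only
            elite_x, elite_f = prey[best_i].copy(), float(fit[best_i])
        history.append(elite_f)

    return OptimizeResult(best_x=elite_x, best_f=elite_f,
                          history=np.asarray(history), evals=evals)


# ---------------------------------------------------------------------------
# classifier-error fitness for hyperparameter tuning

def error_rate(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Classifier error rate in percent: misclassified / total * 100."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    return float(np.mean(y_true != y_pred) * 100.0)


def hyperparameter_space() -> SearchSpace:
    """The 6-D box the tuner searches over.

    Coordinates: log10 RBM learning rate, log10 fine-tune learning rate,
    hidden layer 1 units, hidden layer 2 units, CD Gibbs steps k, fine-tune
    epochs.  Integer coordinates are decoded by rounding.
    """
    return SearchSpace(
        lb=np.array([-4.0, -4.0, 8.0, 8.0, 1.0, 5.0]),
        ub=np.array([-1.0, -1.0, 256.0, 256.0, 5.0, 60.0]),
        kinds=("log_scale", "log_scale", "integer", "integer",
               "integer", "integer"),
    )


def decode_candidate(x: np.ndarray) -> dict:
    """Decode a 6-vector from :func:`hyperparameter_space` into DBN settings."""
    x = np.asarray(x, dtype=float)
    return {
        "rbm_lr": float(10.0 ** x[0]),
        "finetune_lr": float(10.0 ** x[1]),
        "hidden": (int(round(x[2])), int(round(x[3]))),
        "cd_k": max(1, int(round(x[4]))),
        "finetune_epochs": int(round(x[5])),
    }


@dataclass
class TrainBundle:
    """Standardized training features + labels for the tuner's fitness.

    A stratified inner validation split (default 20% of the rows) is held
    out inside the fitness so the outer test split never influences the
    hyperparameter search.
    """

    X: np.ndarray
    y: np.ndarray
    n_classes: int
    val_fraction: float = 0.2
    seed: int = 0
    rbm_epochs: int = 15


def classifier_error_fitness(candidate: np.ndarray, space: SearchSpace,
                             bundle: TrainBundle) -> float:
    """Validation error rate (percent) of a DBN built from ``candidate``."""
    from sklearn.model_selection import train_test_split

    from .dbn import fit_dbn_classifier, predict

    hp = decode_candidate(candidate)
    idx = np.arange(bundle.y.size)
    tr, va = train_test_split(idx, test_size=bundle.val_fraction,
                              stratify=bundle.y, random_state=bundle.seed)
    model = fit_dbn_classifier(
        bundle.X[tr], bundle.y[tr], n_classes=bundle.n_classes,
        hidden=hp["hidden"], rbm_lr=hp["rbm_lr"], rbm_epochs=bundle.rbm_epochs,
        cd_k=hp["cd_k"], finetune_lr=hp["finetune_lr"],
        finetune_epochs=hp["finetune_epochs"], seed=bundle.seed,
    )
    _, pred = predict(model, bundle.X[va])
    return error_rate(bundle.y[va], pred)
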