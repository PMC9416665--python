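"""Amplitude fitting against observed contact-probability profiles.

The three class amplitudes (q_plus, q_minus, q_zero) are optimized by
minimizing the pooled per-residue squared error across all training
proteins; the per-protein scale ``c`` is profiled out in closed form
inside the objective.  Distance constants are held fixed.  A seeded
multi-start wraps a bounded local optimizer so results are deterministic
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import ModelParameters, ResidueClasses, relative_weights

DEFAULT_BOUNDS = ((0.01, 20.0),) * 3
N_STARTS = 10


@dataclass(frozen=True)
class TrainingProtein:
    """One training example: classified sequence + observed contact profile."""

    protein_id: str
    classes: ResidueClasses
    observed: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        if obs.size != len(self.classes):
            raise ValueError(
                f"{self.protein_id}: profile length {obs.size} != "
                f"sequence length {len(self.classes)}"
            )
        if np.any(obs < 0) or np.any(obs > 1):
            raise ValueError(f"{self.protein_id}: probabilities outside [0, 1]")
        object.__setattr__(self, "observed", obs)

    @property
    def effective_group(self) -> str:
        return self.group if self.group is not None else self.protein_id


@dataclass
class FitResult:
    params: ModelParameters
    scales: dict[str, float]
    rmses: dict[str, float]
    r0_squared: float
    objective: float
    n_iterations: int
    converged: bool
    seed: int | None
    non_identifiable: list[str] = field(default_factory=list)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.params.q_plus, self.params.q_minus, self.params.q_zero])

    def to_dict(self) -> dict:
        return {
            "q_plus": self.params.q_plus,
            "q_minus": self.params.q_minus,
            "q_zero": self.params.q_zero,
            "scales": self.scales,
            "rmses": self.rmses,
            "r0_squared": self.r0_squared,
            "objective": self.objective,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "seed": self.seed,
            "non_identifiable": self.non_identifiable,
        }


def optimal_scale(relative: np.ndarray, observed: np.ndarray) -> float:
    """Least-squares scale c for observed ~ c * relative, clipped to >= 0."""
    r = np.asarray(relative, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if r.shape != obs.shape:
        raise ValueError("relative weights and observations differ in length")
    denom = float(np.dot(r, r))
    if denom == 0.0:
        raise ValueError("all relative weights are zero")
    return max(0.0, float(np.dot(obs, r)) / denom)


def rmse(predicted, observed) -> float:
    """Root-mean-square residual between two equal-length profiles."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r0_squared(predicted, observed, about_zero: bool = False) -> float:
    """Pooled coefficient of determination, 1 - SSres/SStot.

    ``about_zero=True`` measures SStot about 0 instead of the observed
    mean (the alternative reading of the pooled metric).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    ss_res = float(np.sum((p - o) ** 2))
    ss_tot = float(np.sum(o**2) if about_zero else np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero variance in observations: R0^2 undefined")
    return 1.0 - ss_res / ss_tot


def _pooled_objective(q: np.ndarray, training: list[TrainingProtein]) -> float:
    """Pooled SSR with per-protein c solved in closed form."""
    params = ModelParameters(q_plus=q[0], q_minus=q[1], q_zero=q[2])
    ssr = 0.0
    for prot in training:
        rel = relative_weights(prot.classes, params)
        c = optimal_scale(rel, prot.observed)
        ssr += float(np.sum((c * rel - prot.observed) ** 2))
    return ssr


def _evaluate(
    q: np.ndarray, training: list[TrainingProtein]
) -> tuple[dict[str, float], dict[str, float], float]:
    params = ModelParameters(q_plus=q[0], q_minus=q[1], q_zero=q[2])
    scales, rmses = {}, {}
    pooled_pred, pooled_obs = [], []
    for prot in training:
        rel = relative_weights(prot.classes, params)
        c = optimal_scale(rel, prot.observed)
        pred = c * rel
        scales[prot.protein_id] = c
        rmses[prot.protein_id] = rmse(pred, prot.observed)
        pooled_pred.append(pred)
        pooled_obs.append(prot.observed)
    r0 = r0_squared(np.concatenate(pooled_pred), np.concatenate(pooled_obs))
    return scales, rmses, r0


def _flat_directions(
    q: np.ndarray, training: list[TrainingProtein], objective: float
) -> list[str]:
    """Amplitudes whose 1.5x rescaling leaves the objective unchanged."""
    names = ["q_plus", "q_minus", "q_zero"]
    flat = []
    scale = max(1.0, objective)
    for k, name in enumerate(names):
        probe = q.copy()
        probe[k] = min(probe[k] * 1.5, DEFAULT_BOUNDS[k][1])
        if abs(_pooled_objective(probe, training) - objective) < 1e-12 * scale:
            flat.append(name)
    return flat


def fit_amplitudes(
    training: list[TrainingProtein],
    init: tuple[float, float, float] = (2.0, 0.5, 0.8),
    bounds=DEFAULT_BOUNDS,
    seed: int | None = 0,
    n_starts: int = N_STARTS,
) -> FitResult:
    """Fit (q_plus, q_minus, q_zero) to the pooled training profiles.

    Runs L-BFGS-B from ``init`` plus ``n_starts - 1`` log-uniform random
    starting points drawn from ``bounds`` (seeded), and keeps the best.
    """
    if not training:
        raise ValueError("training set is empty")
    for lo, hi in bounds:
        if lo <= 0 or hi <= lo:
            raise ValueError("bounds must be positive with lo < hi")

    rng = np.random.default_rng(seed)
    lows = np.array([b[0] for b in bounds])
    highs = np.array([b[1] for b in bounds])
    starts = [np.asarray(init, dtype=float)]
    for _ in range(max(0, n_starts - 1)):
        u = rng.random(3)
        starts.append(np.exp(np.log(lows) + u * (np.log(highs) - np.log(lows))))

    best = None
    total_iter = 0
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            _pooled_objective,
            np.clip(x0, lows, highs),
            args=(training,),
            method="L-BFGS-B",
            bounds=bounds,
        )
        total_iter += int(res.nit)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    q = np.asarray(best.x, dtype=float)
    objective = float(best.fun)
    scales, rmses, r0 = _evaluate(q, training)
    return FitResult(
        params=ModelParameters(q_plus=q[0], q_minus=q[1], q_zero=q[2]),
        scales=scales,
        rmses=rmses,
        r0_squared=r0,
        objective=objective,
        n_iterations=total_iter,
        converged=any_converged,
        seed=seed,
        non_identifiable=_flat_directions(q, training, objective),
    )


@dataclass
class LeaveOneOutResult:
    folds: list[FitResult]
    held_out_groups: list[str]
    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "held_out_groups": self.held_out_groups,
            "mean": self.mean,
            "sd": self.sd,
            "folds": [f.to_dict() for f in self.folds],
        }


def leave_one_out(
    training: list[TrainingProtein],
    init: tuple[float, float, float] = (2.0, 0.5, 0.8),
    bounds=DEFAULT_BOUNDS,
    seed: int | None = 0,
    n_starts: int = N_STARTS,
) -> LeaveOneOutResult:
    """Refit with each group held out; proteins sharing a group leave together.

    Returns one fit per held-out group plus the mean and standard
    deviation of each amplitude across folds.
    """
    groups = sorted({p.effective_group for p in training})
    if len(groups) < 2:
        raise ValueError("leave-one-out requires at least 2 groups")
    folds = []
    for g in groups:
        subset = [p for p in training if p.effective_group != g]
        folds.append(
            fit_amplitudes(subset, init=init, bounds=bounds, seed=seed, n_starts=n_starts)
        )
    amps = np.array([f.amplitudes for f in folds])
    names = ["q_plus", "q_minus", "q_zero"]
    return LeaveOneOutResult(
        folds=folds,
        held_out_groups=groups,
        mean={n: float(m) for n, m in zip(names, amps.mean(axis=0))},
        sd={n: float(s) for n, s in zip(names, amps.std(axis=0, ddof=1))},
    )
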