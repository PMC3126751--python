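"""Hybrid genetic-algorithm / simulated-annealing parameter fitting.

A small population of candidate fraction vectors is evolved: each step
clones a randomly selected member, optionally crosses it block-wise
with a second member (at the crossover rate), perturbs a few randomly
chosen free variables with a magnitude that decays linearly over the
run (the annealing regime), projects the result back onto the
per-subunit simplexes, and accepts the child in place of its parent
when it does not worsen the objective.  Per-parent acceptance keeps the
population diverse (20 loosely coupled annealers mixed by crossover),
which avoids the premature basin takeover seen with worst-member
replacement.  Repeated independent runs provide replicate statistics
and a guard against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    IsotopologueProfile,
    MoietyStateSpace,
    ParameterSet,
    predict_profile,
)


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class OptimizerSettings:
    """Hyperparameters of the hybrid search.

    Defaults follow the published protocol: 10^6 steps, population 20,
    5% crossover, three mutated variables per step, linear annealing,
    50 repeats.  ``initial_scale``/``final_scale`` bound the linearly
    decaying mutation magnitude.
    """

    steps: int = 1_000_000
    population_size: int = 20
    crossover_rate: float = 0.05
    mutations_per_step: int = 3
    repeats: int = 50
    seed: int = 0
    initial_scale: float = 0.5
    final_scale: float = 1e-4
    multimodality_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.mutations_per_step < 1:
            raise ValueError("mutations_per_step must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class FitResult:
    """Outcome of repeated optimizations on one observed profile."""

    best_params: ParameterSet
    best_objective: float
    per_repeat_params: list[ParameterSet]
    per_repeat_objectives: list[float]
    mean_params: ParameterSet
    sd_params: dict[str, float]
    residuals: np.ndarray
    multimodal: bool


class _Evaluator:
    """Fast objective evaluation on raw concatenated block vectors."""

    def __init__(self, space: MoietyStateSpace, observed: np.ndarray):
        self.space = space
        self.observed = np.asarray(observed, dtype=float)
        if self.observed.size != space.max_mass_shift + 1:
            raise DataError(
                f"observed profile has {self.observed.size} components but the "
                f"model supports mass shifts 0..{space.max_mass_shift}"
            )
        self.slices: list[slice] = []
        self.positions: list[np.ndarray] = []
        self.sizes: list[int] = []
        start = 0
        for s in space.subunits:
            self.slices.append(slice(start, start + s.n_states))
            self.positions.append(np.array(s.allowed_labels))
            self.sizes.append(s.max_label + 1)
            start += s.n_states
        self.n_vars = start
        # indices of free variables (all but last state of each block)
        self.free_idx = np.array(
            [i for sl in self.slices for i in range(sl.start, sl.stop - 1)], dtype=int
        )

    def predict(self, vec: np.ndarray) -> np.ndarray:
        out = np.array([1.0])
        for sl, pos, size in zip(self.slices, self.positions, self.sizes):
            dist = np.zeros(size)
            dist[pos] = vec[sl]
            out = np.convolve(out, dist)
        return out

    def objective(self, vec: np.ndarray) -> float:
        r = self.predict(vec) - self.observed
        return float(r @ r)

    def project(self, vec: np.ndarray) -> np.ndarray:
        """Clamp to non-negative and renormalize each subunit block."""
        np.maximum(vec, 0.0, out=vec)
        for sl in self.slices:
            total = vec[sl].sum()
            if total <= 0.0:
                vec[sl] = 1.0 / (sl.stop - sl.start)
            else:
                vec[sl] /= total
        return vec

    def to_parameter_set(self, vec: np.ndarray) -> ParameterSet:
        return ParameterSet(
            dict(zip(self.space.parameter_names, (float(v) for v in vec)))
        ).validate(self.space)


def objective(
    params: ParameterSet, observed: IsotopologueProfile | np.ndarray, space: MoietyStateSpace
) -> float:
    """Sum of squared residuals between observed and predicted profiles."""
    obs = observed.fractions if isinstance(observed, IsotopologueProfile) else np.asarray(observed, float)
    ev = _Evaluator(space, obs)
    params = params.validate(space)
    vec = np.concatenate(params.block_arrays(space))
    return ev.objective(vec)


def _init_population(ev: _Evaluator, size: int, rng: np.random.Generator) -> np.ndarray:
    pop = np.empty((size, ev.n_vars))
    for sl in ev.slices:
        pop[:, sl] = rng.dirichlet(np.ones(sl.stop - sl.start), size=size)
    return pop


def fit_once(
    observed: IsotopologueProfile | np.ndarray,
    space: MoietyStateSpace,
    settings: OptimizerSettings,
    seed: int | np.random.SeedSequence | None = None,
    record_history: bool = False,
) -> tuple[ParameterSet, float, list[float]]:
    """One optimization run; deterministic for a fixed seed.

    Returns ``(best_params, best_objective, history)`` where history is
    the best-so-far objective sampled every 1000 steps (empty unless
    ``record_history``).
    """
    obs = observed.fractions if isinstance(observed, IsotopologueProfile) else np.asarray(observed, float)
    ev = _Evaluator(space, obs)
    rng = np.random.default_rng(settings.seed if seed is None else seed)

    pop = _init_population(ev, settings.population_size, rng)
    objs = np.array([ev.objective(p) for p in pop])
    best_i = int(np.argmin(objs))
    best_vec = pop[best_i].copy()
    best_obj = float(objs[best_i])

    n_mut = min(settings.mutations_per_step, ev.free_idx.size)
    if n_mut == 0:
        # no free variables: the model is fully determined
        return ev.to_parameter_set(best_vec), best_obj, []
    steps = settings.steps
    scale0, scale1 = settings.initial_scale, settings.final_scale
    history: list[float] = []

    for step in range(steps):
        scale = scale0 + (scale1 - scale0) * (step / max(steps - 1, 1))
        i = int(rng.integers(settings.population_size))
        child = pop[i].copy()
        if rng.random() < settings.crossover_rate:
            j = int(rng.integers(settings.population_size - 1))
            if j >= i:
                j += 1
            take = rng.random(len(ev.slices)) < 0.5
            for sl, t in zip(ev.slices, take):
                if t:
                    child[sl] = pop[j, sl]
        idx = rng.choice(ev.free_idx, size=n_mut, replace=False)
        child[idx] += rng.normal(0.0, scale, size=n_mut)
        ev.project(child)
        obj = ev.objective(child)
        if obj <= objs[i]:  # accept in place of the parent
            pop[i] = child
            objs[i] = obj
            if obj < best_obj:  # strict: earliest find wins ties
                best_obj = obj
                best_vec = child.copy()
        if record_history and step % 1000 == 0:
            history.append(best_obj)
    if record_history:
        history.append(best_obj)
    return ev.to_parameter_set(best_vec), best_obj, history


def fit(
    observed: IsotopologueProfile | np.ndarray,
    space: MoietyStateSpace,
    settings: OptimizerSettings,
) -> FitResult:
    """Repeat :func:`fit_once` and aggregate replicate statistics.

    Per-repeat seeds are spawned deterministically from the settings
    seed.  The fit is flagged multimodal when per-repeat best
    objectives spread by more than ``settings.multimodality_tol``.
    """
    obs = observed.fractions if isinstance(observed, IsotopologueProfile) else np.asarray(observed, float)
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.repeats)
    params_list: list[ParameterSet] = []
    obj_list: list[float] = []
    for ss in seeds:
        p, t, _ = fit_once(obs, space, settings, seed=ss)
        params_list.append(p)
        obj_list.append(t)

    best_i = int(np.argmin(obj_list))
    names = space.parameter_names
    mat = np.array([[p[nm] for nm in names] for p in params_list])
    mean_raw = ParameterSet(dict(zip(names, mat.mean(axis=0))))
    mean_params = mean_raw.validate(space, tol=1e-6)  # renormalize closure drift
    sd_params = dict(zip(names, (float(v) for v in mat.std(axis=0, ddof=1 if len(params_list) > 1 else 0))))
    residuals = obs - predict_profile(space, params_list[best_i]).fractions
    spread = max(obj_list) - min(obj_list)
    return FitResult(
        best_params=params_list[best_i],
        best_objective=float(obj_list[best_i]),
        per_repeat_params=params_list,
        per_repeat_objectives=[float(x) for x in obj_list],
        mean_params=mean_params,
        sd_params=sd_params,
        residuals=residuals,
        multimodal=spread > settings.multimodality_tol,
    )
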