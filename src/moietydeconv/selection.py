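"""Variant-model generation and AIC-based model selection.

Variant label models are produced from a small grammar (alternative
allowed-label sets per subunit, combined Cartesian-style).  Each
variant is fitted to every timepoint; the least-squares AIC — with the
small-sample correction by default, evaluated at the across-repeat
mean parameters — is summed over timepoints and variants are ranked.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import (
    ConfigurationError,
    IsotopologueProfile,
    MoietyStateSpace,
    SubunitStateSet,
    free_parameter_count,
)
from .optimize import OptimizerSettings, _Evaluator, fit


@dataclass(frozen=True)
class ModelVariant:
    space: MoietyStateSpace
    description: str
    k: int

    def __post_init__(self) -> None:
        if self.k != free_parameter_count(self.space):
            raise ConfigurationError("k must equal free_parameter_count(space)")


def _parameter_prefix(subunit: SubunitStateSet) -> str:
    names = subunit.parameter_names
    prefix = names[0].rstrip("0123456789")
    return prefix if prefix else subunit.name[0]


def _variant_subunit(base: SubunitStateSet, labels: Sequence[int]) -> SubunitStateSet:
    labels = tuple(sorted(set(int(x) for x in labels)))
    if not labels:
        raise ConfigurationError(f"{base.name}: variant label set is empty")
    if tuple(labels) == base.allowed_labels:
        return base
    prefix = _parameter_prefix(base)
    return SubunitStateSet(
        name=base.name,
        carbon_count=base.carbon_count,
        allowed_labels=labels,
        parameter_names=tuple(f"{prefix}{l}" for l in labels),
    )


def generate_variants(
    base: MoietyStateSpace, grammar: Mapping[str, Sequence[Sequence[int]]]
) -> list[ModelVariant]:
    """Expand a variant grammar into deduplicated model variants.

    ``grammar`` maps subunit names to lists of alternative allowed-label
    sets; the base label set is always included.  All combinations
    across subunits are produced, so the base model is always present
    (first in the returned list).
    """
    for name in grammar:
        base.subunit(name)  # raises KeyError for unknown subunits
    options: list[list[SubunitStateSet]] = []
    for s in base.subunits:
        alts = [s.allowed_labels] + [tuple(a) for a in grammar.get(s.name, [])]
        seen: list[tuple[int, ...]] = []
        subs = []
        for labels in alts:
            canon = tuple(sorted(set(int(x) for x in labels)))
            if canon in seen:
                continue
            seen.append(canon)
            subs.append(_variant_subunit(s, canon))
        options.append(subs)

    variants: list[ModelVariant] = []
    seen_keys: set[tuple] = set()
    for combo in itertools.product(*options):
        key = tuple(s.allowed_labels for s in combo)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        space = MoietyStateSpace(subunits=tuple(combo), name=base.name)
        desc = "|".join(
            f"{s.name}{{{','.join(map(str, s.allowed_labels))}}}" for s in combo
        )
        variants.append(ModelVariant(space=space, description=desc, k=free_parameter_count(space)))
    return variants


def aic(rss: float, n_obs: int, k: int, corrected: bool = True) -> float:
    """Least-squares Akaike information criterion.

    ``n_obs * ln(rss / n_obs) + 2k``, plus the small-sample correction
    ``2k(k+1)/(n_obs-k-1)`` when ``corrected`` (the default; per-
    timepoint profiles are short).  A perfect fit (rss == 0) returns
    ``-inf`` with a warning.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if corrected and n_obs <= k + 1:
        raise ValueError("small-sample correction needs n_obs > k + 1")
    if rss == 0.0:
        warnings.warn("rss is exactly 0; AIC is -inf (perfect fit)")
        return -math.inf
    value = n_obs * math.log(rss / n_obs) + 2 * k
    if corrected:
        value += 2 * k * (k + 1) / (n_obs - k - 1)
    return value


@dataclass
class VariantScore:
    description: str
    k: int
    aic: float
    delta_aic: float
    rss_at_mean: float
    rank: int
    error: str | None = None


@dataclass
class SelectionReport:
    scores: list[VariantScore]

    @property
    def best(self) -> VariantScore:
        return self.scores[0]


def _padded_rss(space: MoietyStateSpace, mean_vec: np.ndarray, observed: np.ndarray) -> float:
    """RSS with observed/predicted zero-padded to a common length."""
    ev = _Evaluator(space, np.zeros(space.max_mass_shift + 1))
    pred = ev.predict(mean_vec)
    n = max(pred.size, observed.size)
    p = np.zeros(n)
    o = np.zeros(n)
    p[: pred.size] = pred
    o[: observed.size] = observed
    r = p - o
    return float(r @ r)


def select(
    variants: Sequence[ModelVariant],
    timecourse: Sequence[IsotopologueProfile | np.ndarray],
    settings: OptimizerSettings,
    corrected: bool = True,
    use_mean: bool = True,
) -> SelectionReport:
    """Fit every variant at every timepoint and rank by summed AIC.

    ``n_obs`` is taken from the observed profile length so that all
    variants are penalized on the same measurement count.  Failing
    variants are ranked last with their error message recorded rather
    than aborting the selection.  Deterministic given the settings seed.
    """
    if not variants:
        raise ValueError("need at least one variant")
    obs_list = [
        o.fractions if isinstance(o, IsotopologueProfile) else np.asarray(o, float)
        for o in timecourse
    ]
    if not obs_list:
        raise ValueError("need at least one observed profile")

    records: list[tuple[float, float, ModelVariant, str | None]] = []
    for vi, var in enumerate(variants):
        try:
            total_aic = 0.0
            total_rss = 0.0
            var_settings = OptimizerSettings(
                steps=settings.steps,
                population_size=settings.population_size,
                crossover_rate=settings.crossover_rate,
                mutations_per_step=settings.mutations_per_step,
                repeats=settings.repeats,
                seed=settings.seed + 100_003 * vi,  # per-variant stream
                initial_scale=settings.initial_scale,
                final_scale=settings.final_scale,
            )
            for obs in obs_list:
                n_model = var.space.max_mass_shift + 1
                padded = np.zeros(max(n_model, obs.size))
                padded[: obs.size] = obs
                res = fit(padded[:n_model] if n_model >= obs.size else _refold(obs, n_model), var.space, var_settings)
                params = res.mean_params if use_mean else res.best_params
                vec = np.concatenate(params.block_arrays(var.space))
                rss = _padded_rss(var.space, vec, obs)
                total_aic += aic(rss, n_obs=obs.size, k=var.k, corrected=corrected)
                total_rss += rss
            records.append((total_aic, total_rss, var, None))
        except Exception as e:  # noqa: BLE001 - per-variant fault isolation
            records.append((math.inf, math.inf, var, f"{type(e).__name__}: {e}"))

    records.sort(key=lambda r: r[0])
    best_aic = records[0][0]
    scores = [
        VariantScore(
            description=var.description,
            k=var.k,
            aic=a,
            delta_aic=a - best_aic if math.isfinite(a) else math.inf,
            rss_at_mean=rss,
            rank=i + 1,
            error=err,
        )
        for i, (a, rss, var, err) in enumerate(records)
    ]
    return SelectionReport(scores=scores)


def _refold(obs: np.ndarray, n_model: int) -> np.ndarray:
    """Truncate an observed profile to a narrower model support.

    Out-of-support mass is dropped from the fit input; it still counts
    against the variant through the padded RSS.
    """
    out = obs[:n_model].copy()
    total = out.sum()
    if total <= 0:
        raise ValueError("observed profile has no mass inside model support")
    return out / total
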