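"""Moiety labeling state spaces and the forward isotopologue model.

A composite metabolite is described as an ordered list of biochemical
subunits, each with a small set of allowed 13C label counts.  Given the
mole fraction of each allowed label state per subunit, the predicted
mass-isotopologue distribution of the intact metabolite is the
convolution of the per-subunit label distributions.

The shipped default model (``default_space``) describes UDP-GlcNAc as
glucose (C6, labels {0,6}), ribose (C5, {0,5}), acetyl (C2, {0,2}) and
uracil (C4, {0,1,2,3}); it has 32 joint label states, 17 reachable mass
shifts (m0..m16) and 6 free parameters.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

#: tolerance for per-subunit closure (fractions summing to 1)
CLOSURE_TOL = 1e-9


class ConfigurationError(ValueError):
    """An invalid model/state-space definition."""


class ValidationError(ValueError):
    """Data or parameters violating a model contract."""


@dataclass(frozen=True)
class SubunitStateSet:
    """One biochemical subunit and its allowed 13C label counts.

    Parameters
    ----------
    name:
        Subunit identifier, e.g. ``"glucose"``.
    carbon_count:
        Number of carbon atoms in the subunit (>= 1).
    allowed_labels:
        Distinct label counts, sorted ascending, each in
        ``[0, carbon_count]``.
    parameter_names:
        One mole-fraction parameter name per allowed label state.
    """

    name: str
    carbon_count: int
    allowed_labels: tuple[int, ...]
    parameter_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed_labels", tuple(int(x) for x in self.allowed_labels))
        object.__setattr__(self, "parameter_names", tuple(str(x) for x in self.parameter_names))
        if not self.name:
            raise ConfigurationError("subunit name must be non-empty")
        if self.carbon_count < 1:
            raise ConfigurationError(f"{self.name}: carbon_count must be >= 1")
        if not self.allowed_labels:
            raise ConfigurationError(f"{self.name}: allowed_labels must be non-empty")
        if list(self.allowed_labels) != sorted(set(self.allowed_labels)):
            raise ConfigurationError(
                f"{self.name}: allowed_labels must be distinct and sorted ascending"
            )
        if self.allowed_labels[0] < 0 or self.allowed_labels[-1] > self.carbon_count:
            raise ConfigurationError(
                f"{self.name}: allowed labels must lie in [0, {self.carbon_count}]"
            )
        if len(self.parameter_names) != len(self.allowed_labels):
            raise ConfigurationError(
                f"{self.name}: need one parameter name per allowed label state"
            )
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ConfigurationError(f"{self.name}: parameter names must be distinct")

    @property
    def n_states(self) -> int:
        return len(self.allowed_labels)

    @property
    def max_label(self) -> int:
        return self.allowed_labels[-1]


@dataclass(frozen=True)
class MoietyStateSpace:
    """An ordered collection of subunits defining the metabolite model."""

    subunits: tuple[SubunitStateSet, ...]
    name: str = "metabolite"

    def __post_init__(self) -> None:
        object.__setattr__(self, "subunits", tuple(self.subunits))
        if not self.subunits:
            raise ConfigurationError("state space needs at least one subunit")
        names = [s.name for s in self.subunits]
        if len(set(names)) != len(names):
            raise ConfigurationError("subunit names must be distinct")
        all_params = [p for s in self.subunits for p in s.parameter_names]
        if len(set(all_params)) != len(all_params):
            raise ConfigurationError("parameter names must be globally distinct")

    @property
    def metabolite_carbons(self) -> int:
        return sum(s.carbon_count for s in self.subunits)

    @property
    def max_mass_shift(self) -> int:
        """Largest achievable total label count."""
        return sum(s.max_label for s in self.subunits)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """All state parameters, in subunit order."""
        return tuple(p for s in self.subunits for p in s.parameter_names)

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        """Free parameters: all but the last state of each subunit."""
        return tuple(p for s in self.subunits for p in s.parameter_names[:-1])

    def subunit(self, name: str) -> SubunitStateSet:
        for s in self.subunits:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "subunits": [
                {
                    "name": s.name,
                    "carbon_count": s.carbon_count,
                    "allowed_labels": list(s.allowed_labels),
                    "parameter_names": list(s.parameter_names),
                }
                for s in self.subunits
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MoietyStateSpace":
        try:
            subunits = tuple(
                SubunitStateSet(
                    name=su["name"],
                    carbon_count=int(su["carbon_count"]),
                    allowed_labels=tuple(su["allowed_labels"]),
                    parameter_names=tuple(su["parameter_names"]),
                )
                for su in d["subunits"]
            )
        except KeyError as e:  # pragma: no cover - defensive
            raise ConfigurationError(f"model definition missing field {e}") from e
        return cls(subunits=subunits, name=str(d.get("name", "metabolite")))

    @classmethod
    def from_json(cls, path) -> "MoietyStateSpace":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_space() -> MoietyStateSpace:
    """The shipped UDP-GlcNAc six-free-parameter model."""
    ref = resources.files("moietydeconv").joinpath("data/udp_glcnac.json")
    return MoietyStateSpace.from_dict(json.loads(ref.read_text()))


@dataclass(frozen=True)
class Isotopomer:
    """One joint label state: a label choice for every subunit."""

    labels: tuple[int, ...]
    mass_shift: int
    parameter_names: tuple[str, ...]


def enumerate_isotopomers(space: MoietyStateSpace) -> list[Isotopomer]:
    """All joint label states (Cartesian product over subunits).

    Each state carries its total mass shift and the parameter names
    whose product gives its mole fraction.
    """
    states = []
    per_subunit = [list(zip(s.allowed_labels, s.parameter_names)) for s in space.subunits]
    for combo in itertools.product(*per_subunit):
        labels = tuple(l for l, _ in combo)
        names = tuple(p for _, p in combo)
        states.append(Isotopomer(labels=labels, mass_shift=sum(labels), parameter_names=names))
    return states


def mass_support(space: MoietyStateSpace) -> tuple[int, ...]:
    """Sorted distinct achievable total mass shifts."""
    return tuple(sorted({iso.mass_shift for iso in enumerate_isotopomers(space)}))


def free_parameter_count(space: MoietyStateSpace) -> int:
    """Number of independent fractions after per-subunit closure."""
    return sum(s.n_states - 1 for s in space.subunits)


@dataclass
class ParameterSet:
    """Mole fractions of every allowed label state, keyed by parameter name."""

    fractions: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.fractions[key]

    def validate(self, space: MoietyStateSpace, tol: float = CLOSURE_TOL) -> "ParameterSet":
        """Check bounds and per-subunit closure; renormalize within ``tol``.

        Raises :class:`ValidationError` for missing parameters, values
        outside [0, 1] or closure violations beyond ``tol``.
        """
        out: dict[str, float] = {}
        for s in space.subunits:
            block = []
            for p in s.parameter_names:
                if p not in self.fractions:
                    raise ValidationError(f"missing parameter {p!r}")
                v = float(self.fractions[p])
                if not (-tol <= v <= 1 + tol):
                    raise ValidationError(f"{p} = {v} outside [0, 1]")
                block.append(min(max(v, 0.0), 1.0))
            total = sum(block)
            if abs(total - 1.0) > tol:
                raise ValidationError(
                    f"subunit {s.name}: fractions sum to {total}, not 1 (tol {tol})"
                )
            out.update({p: v / total for p, v in zip(s.parameter_names, block)})
        return ParameterSet(out)

    @classmethod
    def from_free(
        cls, space: MoietyStateSpace, free: Mapping[str, float]
    ) -> "ParameterSet":
        """Build a full parameter set from free parameters only.

        The last state of each subunit is implied by closure.
        """
        out: dict[str, float] = {}
        for s in space.subunits:
            acc = 0.0
            for p in s.parameter_names[:-1]:
                if p not in free:
                    raise ValidationError(f"missing free parameter {p!r}")
                v = float(free[p])
                out[p] = v
                acc += v
            implied = 1.0 - acc
            if implied < -CLOSURE_TOL:
                raise ValidationError(
                    f"subunit {s.name}: free fractions sum to {acc} > 1"
                )
            out[s.parameter_names[-1]] = max(implied, 0.0)
        return cls(out).validate(space)

    def block_arrays(self, space: MoietyStateSpace) -> list[np.ndarray]:
        """Per-subunit fraction vectors, in allowed-label order."""
        return [
            np.array([self.fractions[p] for p in s.parameter_names], dtype=float)
            for s in space.subunits
        ]


@dataclass
class IsotopologueProfile:
    """Mole-fraction vector over mass shifts 0..N."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)

    @property
    def mass_shifts(self) -> np.ndarray:
        return np.arange(self.fractions.size)

    @property
    def mean_mass_shift(self) -> float:
        return float(np.dot(self.mass_shifts, self.fractions))

    def __len__(self) -> int:
        return self.fractions.size


def _subunit_shift_dist(subunit: SubunitStateSet, block: np.ndarray) -> np.ndarray:
    dist = np.zeros(subunit.max_label + 1)
    dist[list(subunit.allowed_labels)] = block
    return dist


def predict_profile(space: MoietyStateSpace, params: ParameterSet) -> IsotopologueProfile:
    """Forward model: subunit fractions -> isotopologue distribution.

    The metabolite's mass-shift distribution is the convolution of the
    per-subunit label distributions.  Mass shifts without model support
    are reported as exact zeros.  The output sums to 1.
    """
    params = params.validate(space)
    out = np.array([1.0])
    for s, block in zip(space.subunits, params.block_arrays(space)):
        out = np.convolve(out, _subunit_shift_dist(s, block))
    return IsotopologueProfile(out)
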