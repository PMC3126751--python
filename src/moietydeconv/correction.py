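"""Natural-abundance stripping and mole-fraction normalization.

Only 13C is corrected: at the resolution assumed here, isotopologues of
other elements (2H, 15N, 18O) are resolved away upstream.  A component
with ``e`` enriched carbons carries a binomial natural-abundance
envelope over its remaining ``carbon_count - e`` positions; stripping
inverts that (lower-triangular) mixing from the lowest mass upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .model import ConfigurationError, IsotopologueProfile

log = logging.getLogger(__name__)

#: natural 13C abundance
DEFAULT_P13 = 0.011


class DataError(ValueError):
    """Input intensity data violating a precondition."""


@dataclass(frozen=True)
class CorrectionSettings:
    """Settings for natural-abundance stripping.

    ``carbon_count`` is the carbon count of the intact metabolite (17
    for UDP-GlcNAc); ``p13`` the natural 13C abundance; negative
    post-correction values are clamped to zero when ``clamp_negative``.
    """

    carbon_count: int
    p13: float = DEFAULT_P13
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.carbon_count < 1:
            raise ConfigurationError("carbon_count must be >= 1")
        if not (0.0 <= self.p13 < 0.5):
            raise ConfigurationError(f"p13 = {self.p13} outside [0, 0.5)")


def natural_abundance_envelope(
    enriched: int, carbon_count: int, p13: float
) -> np.ndarray:
    """Binomial mass envelope of a species with ``enriched`` 13C atoms.

    Entry ``j`` is the probability of ``j`` additional 13C atoms among
    the ``carbon_count - enriched`` unenriched positions.
    """
    if not (0 <= enriched <= carbon_count):
        raise ConfigurationError("enriched count outside [0, carbon_count]")
    free = carbon_count - enriched
    if p13 < 1e-12:  # binom.pmf misbehaves for subnormal p
        out = np.zeros(free + 1)
        out[0] = 1.0
        return out
    return binom.pmf(np.arange(free + 1), free, p13)


def convolve_natural_abundance(
    corrected: np.ndarray, settings: CorrectionSettings, length: int | None = None
) -> np.ndarray:
    """Forward mixing: spread each enriched component over its envelope.

    ``length`` sets the output vector size (default: input size); mass
    falling beyond it is truncated, mirroring a detector that reports a
    fixed mass window.
    """
    corrected = np.asarray(corrected, dtype=float)
    n = corrected.size if length is None else int(length)
    out = np.zeros(n)
    for e, x in enumerate(corrected):
        if x == 0.0:
            continue
        env = natural_abundance_envelope(min(e, settings.carbon_count), settings.carbon_count, settings.p13)
        hi = min(n, e + env.size)
        if e < n:
            out[e:hi] += x * env[: hi - e]
    return out


def strip_natural_abundance(
    raw: np.ndarray, settings: CorrectionSettings
) -> tuple[np.ndarray, float]:
    """Remove natural-abundance 13C contributions from ``raw``.

    Proceeds from the lowest mass upward: the component at mass ``e``
    is rescaled by its monoisotopic envelope weight and its envelope is
    subtracted from all higher masses.  Returns ``(corrected,
    clamped_mass)`` where ``clamped_mass`` is the total magnitude of
    negative values clamped to zero (0.0 when clamping is disabled).

    With clamping disabled this exactly inverts
    :func:`convolve_natural_abundance`.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 1:
        raise DataError("empty intensity vector")
    residual = raw.astype(float).copy()
    corrected = np.zeros_like(residual)
    clamped = 0.0
    p = settings.p13
    for e in range(residual.size):
        free = settings.carbon_count - min(e, settings.carbon_count)
        mono_weight = (1.0 - p) ** free
        x = residual[e] / mono_weight
        if x < 0.0 and settings.clamp_negative:
            clamped += -x
            x = 0.0
        corrected[e] = x
        if x != 0.0 and free > 0:
            env = natural_abundance_envelope(min(e, settings.carbon_count), settings.carbon_count, p)
            hi = min(residual.size, e + env.size)
            residual[e:hi] -= x * env[: hi - e]
    if clamped > 0.0:
        log.warning("natural-abundance stripping clamped %.3g total negative mass", clamped)
    return corrected, clamped


def normalize(raw: np.ndarray) -> IsotopologueProfile:
    """Divide by the summed intensity, giving mole fractions."""
    raw = np.asarray(raw, dtype=float)
    total = raw.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise DataError(f"cannot normalize: total intensity {total} is not positive")
    return IsotopologueProfile(raw / total)
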