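"""Single-unit response metrics.

Vector strength (VS) measures how tightly spiking is locked to one phase of
a periodic stimulus: 1 if every spike falls at the same phase, 0 for firing
uniform over phase.  Significance uses Rayleigh's statistic,
``p = exp(-n r^2)``, with p < 0.001 as the phase-locking criterion.

The modulation index ``MI = (X1 - X2) / (X1 + X2)`` compares a quantity
between two conditions; throughout the pipeline the argument order is
(engaged, passive), so positive MI means larger in the engaged state.

The behavioral discrimination ratio is ``DR = HR * (1 - FA)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VectorStrengthResult",
    "ModulationIndexResult",
    "vector_strength",
    "rayleigh_p",
    "modulation_index",
    "discrimination_ratio",
    "VS_SIGNIFICANCE_LEVEL",
    "VS_RATE_FLOOR_HZ",
]

VS_SIGNIFICANCE_LEVEL = 1e-3
#: units firing below this rate are excluded from VS summaries by callers
VS_RATE_FLOOR_HZ = 1.0


@dataclass(frozen=True)
class VectorStrengthResult:
    r: float
    n: int
    rayleigh_p: float
    significant: bool
    defined: bool = True


@dataclass(frozen=True)
class ModulationIndexResult:
    mi: float
    x1: float
    x2: float
    defined: bool = True


def vector_strength(
    spike_times: np.ndarray,
    period: float,
    onset: float = 0.0,
) -> VectorStrengthResult:
    """Resultant length of spike phases relative to a periodic stimulus.

    Phases are ``theta_j = 2*pi*((t_j - onset) mod P) / P`` and
    ``r = |sum_j exp(i*theta_j)| / n``.  With no spikes the result is
    flagged undefined (``defined=False``) rather than reported as 0.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    t = np.asarray(spike_times, dtype=float)
    n = t.size
    if n == 0:
        return VectorStrengthResult(r=np.nan, n=0, rayleigh_p=np.nan, significant=False, defined=False)
    theta = 2.0 * np.pi * np.mod(t - onset, period) / period
    r = float(np.abs(np.exp(1j * theta).mean()))
    r = min(r, 1.0)
    p = rayleigh_p(r, n)
    return VectorStrengthResult(
        r=r, n=int(n), rayleigh_p=p, significant=bool(p < VS_SIGNIFICANCE_LEVEL)
    )


def rayleigh_p(r: float, n: int) -> float:
    """Rayleigh significance ``p = exp(-n r^2)``, clipped to (0, 1]."""
    if not (0.0 <= r <= 1.0):
        raise ValueError("r must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    p = float(np.exp(-n * r * r))
    return min(max(p, np.finfo(float).tiny), 1.0)


def modulation_index(x1: float, x2: float) -> ModulationIndexResult:
    """``MI = (x1 - x2) / (x1 + x2)`` for non-negative inputs.

    A zero denominator yields an undefined-flagged result rather than NaN
    propagation.  Pipeline convention: ``x1`` = engaged, ``x2`` = passive.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("modulation index inputs must be >= 0")
    s = x1 + x2
    if s == 0:
        return ModulationIndexResult(mi=np.nan, x1=x1, x2=x2, defined=False)
    return ModulationIndexResult(mi=(x1 - x2) / s, x1=x1, x2=x2)


def discrimination_ratio(hit_rate: float, false_alarm: float) -> float:
    """Behavioral discrimination ratio ``DR = HR * (1 - FA)``."""
    if not (0.0 <= hit_rate <= 1.0):
        raise ValueError("hit_rate must be in [0, 1]")
    if not (0.0 <= false_alarm <= 1.0):
        raise ValueError("false_alarm must be in [0, 1]")
    return hit_rate * (1.0 - false_alarm)
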