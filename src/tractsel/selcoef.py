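"""Post-admixture selection-coefficient estimation.

Given an allele that entered a population by admixture at initial frequency
``p0 = admixture_fraction x source_frequency`` and is observed ``t``
generations later at frequency ``pt``, the module finds the per-generation
selection coefficient ``s`` that carries the deterministic one-locus
recursion from ``p0`` to ``pt``.

Genotype fitnesses (allele A = selected):

* ``dominant``: w(AA) = w(Aa) = 1 + s, w(aa) = 1, giving
  ``p' = p (1 + s) / (1 + s (2p - p^2))``;
* ``additive``: w(AA) = 1 + 2s, w(Aa) = 1 + s, w(aa) = 1.

``p(t; s)`` is strictly increasing in ``s`` for ``p0 in (0,1)`` and
``t >= 1``, so the inverse problem has a unique root, found by bracketed
root-finding on ``s in [0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .genome_model import ComputeError, ValidationError

__all__ = [
    "SelCoefResult",
    "forward_frequency",
    "solve_s",
    "admixture_initial_frequency",
]

_FITNESS = {
    "dominant": lambda s: (1.0 + s, 1.0 + s, 1.0),
    "additive": lambda s: (1.0 + 2.0 * s, 1.0 + s, 1.0),
}


@dataclass
class SelCoefResult:
    p0: float
    pt: float
    generations: int
    model: str
    s: float
    residual: float  # |p(t; s) - pt| at the fitted s


def forward_frequency(p0: float, s: float, t: int, model: str = "dominant") -> np.ndarray:
    """Deterministic allele-frequency trajectory of length ``t + 1``.

    Monotone non-decreasing for ``s >= 0``; constant at ``p0`` for ``s = 0``.
    """
    if model not in _FITNESS:
        raise ValidationError(f"unknown dominance model {model!r}")
    if not (0.0 <= p0 <= 1.0):
        raise ValidationError("p0 must be in [0,1]")
    if s < 0 or t < 0:
        raise ValidationError("require s >= 0 and t >= 0")
    w_aa, w_het, w_bb = _FITNESS[model](s)
    traj = np.empty(t + 1)
    p = float(p0)
    traj[0] = p
    for i in range(1, t + 1):
        q = 1.0 - p
        wbar = p * p * w_aa + 2 * p * q * w_het + q * q * w_bb
        p = (p * p * w_aa + p * q * w_het) / wbar
        traj[i] = p
    return traj


def solve_s(
    p0: float,
    pt: float,
    t: int,
    model: str = "dominant",
    tol: float = 1e-8,
    s_max: float = 1.0,
) -> SelCoefResult:
    """Selection coefficient carrying ``p0`` to ``pt`` in ``t`` generations.

    Raises :class:`ComputeError` if ``pt`` is unreachable with ``s <= s_max``.
    """
    if not (0.0 < p0 <= pt < 1.0):
        raise ValidationError("require 0 < p0 <= pt < 1")
    if t < 1:
        raise ValidationError("require t >= 1")

    def gap(s: float) -> float:
        return forward_frequency(p0, s, t, model)[-1] - pt

    if gap(0.0) >= 0.0:  # pt == p0 (within the recursion's exactness)
        return SelCoefResult(p0, pt, t, model, 0.0, abs(gap(0.0)))
    if gap(s_max) < 0.0:
        raise ComputeError(
            f"pt={pt} unreachable from p0={p0} in {t} generations with s <= {s_max}"
        )
    s = float(brentq(gap, 0.0, s_max, xtol=tol))
    return SelCoefResult(p0, pt, t, model, s, abs(gap(s)))


def admixture_initial_frequency(alpha: float, f_source: float) -> float:
    """Initial post-admixture frequency: admixture fraction times source
    frequency (the recipient population is assumed to lack the allele)."""
    if not (0.0 <= alpha <= 1.0 and 0.0 <= f_source <= 1.0):
        raise ValidationError("alpha and f_source must be in [0,1]")
    return alpha * f_source
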