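"""Hill regulatory-function primitives.

Every rate law in the signaling and transcription-factor networks is built
from three dimensionless regulatory functions of reduced inputs
``u = (level / K)^n``, where ``K`` is the Hill constant (the input level at
half-maximal effect; inversely related to interaction strength) and ``n``
the Hill exponent (2 throughout, since the relevant effectors act as
dimers):

* activation        ``u / (1 + u)``            — inductive input
* repression        ``1 / (1 + u)``            — repressive input
* shared-promoter   ``(b + Σu_act) / (1 + Σu_act + Σu_rep)``
  competition between any number of activators and repressors, with an
  optional basal term ``b = 1`` for promoters with signal-independent
  activity.

All three are bounded in [0, 1] and accept scalar or ndarray levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "RegulatoryTerm",
    "hill_activation",
    "hill_repression",
    "competitive_regulation",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class RegulatoryTerm:
    """One regulatory input: a concentration, its Hill constant and exponent.

    Parameters
    ----------
    level
        Concentration of the regulator (arbitrary units, >= 0). May be an
        ndarray for vectorised evaluation over a spatial grid.
    hill_constant
        Concentration at half-maximal effect (arbitrary units, > 0).
    exponent
        Hill coefficient (positive integer; default 2, dimer binding).
    """

    level: ArrayLike
    hill_constant: float
    exponent: int = 2

    def __post_init__(self) -> None:
        level = np.asarray(self.level, dtype=float)
        if not np.all(np.isfinite(level)):
            raise ValueError("regulator level must be finite")
        if np.any(level < 0):
            raise ValueError("regulator level must be >= 0")
        if not np.isfinite(self.hill_constant) or self.hill_constant <= 0:
            raise ValueError("hill_constant must be finite and > 0")
        if int(self.exponent) != self.exponent or self.exponent < 1:
            raise ValueError("exponent must be a positive integer")

    @property
    def reduced(self) -> ArrayLike:
        """The reduced variable u = (level / K)^n (finite, >= 0)."""
        return (np.asarray(self.level, dtype=float) / self.hill_constant) ** self.exponent


def hill_activation(term: RegulatoryTerm) -> ArrayLike:
    """Fractional activation u/(1+u); 0 at level 0, 1/2 at level K."""
    u = term.reduced
    return u / (1.0 + u)


def hill_repression(term: RegulatoryTerm) -> ArrayLike:
    """Fractional activity 1/(1+u) under repression; 1 at level 0, 1/2 at K."""
    u = term.reduced
    return 1.0 / (1.0 + u)


def competitive_regulation(
    activators: Sequence[RegulatoryTerm] = (),
    repressors: Sequence[RegulatoryTerm] = (),
    basal: bool = False,
) -> ArrayLike:
    """Shared-promoter competition between activators and repressors.

    Returns ``(b + Σu_act) / (1 + Σu_act + Σu_rep)`` with ``b = 1`` when
    ``basal`` else 0. Monotone increasing in every activator level and
    decreasing in every repressor level; reduces to :func:`hill_activation`
    for a single activator and to :func:`hill_repression` for a single
    repressor with ``basal=True``.
    """
    if not activators and not repressors and not basal:
        raise ValueError(
            "competitive_regulation with no inputs and basal=False is a "
            "degenerate constant; supply at least one regulatory term"
        )
    u_act = sum((t.reduced for t in activators), 0.0)
    u_rep = sum((t.reduced for t in repressors), 0.0)
    b = 1.0 if basal else 0.0
    return (b + u_act) / (1.0 + u_act + u_rep)
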