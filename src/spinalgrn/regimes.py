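"""Classification of signaling-network outcomes.

A simulated :class:`~spinalgrn.signaling.SignalField` falls into one of four
qualitative regimes, depending on the interaction-strength Hill constants:

* ``FGF_DOMINANT`` — RA never accumulates appreciably; the whole domain
  stays under caudal-type FGF8 signaling (no differentiation).
* ``FGF_RA_BALANCE`` — opposing caudal-FGF8 / rostral-RA gradients settle
  into a stationary standoff (steady axial elongation).
* ``FGF_RA_SWITCH`` — RA progressively takes over the whole domain, the
  RA-vs-FGF8 front sweeping caudally (differentiation terminating axial
  elongation); quantified by a completion time.
* ``RA_ABERRANT_OSCILLATORY`` — RA production is non-monotone in a way not
  seen in vivo: sustained oscillations of total RA, a transient burst that
  collapses back toward FGF8 production, or a final RA profile peaking in
  the domain interior instead of rising toward the somites.

The in-vivo outcome labels were qualitative; the thresholds here are
explicit operational reconstructions and all live on
:class:`ClassifierConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .signaling import SignalField

__all__ = [
    "Regime",
    "RegimeLabel",
    "ClassifierConfig",
    "UnclassifiableFieldError",
    "ra_front_position",
    "front_trajectory",
    "switch_completion_time",
    "detect_oscillation",
    "classify_regime",
]


class Regime(str, Enum):
    FGF_DOMINANT = "FGF_DOMINANT"
    FGF_RA_BALANCE = "FGF_RA_BALANCE"
    FGF_RA_SWITCH = "FGF_RA_SWITCH"
    RA_ABERRANT_OSCILLATORY = "RA_ABERRANT_OSCILLATORY"


class UnclassifiableFieldError(RuntimeError):
    """The field matches none of the four regime signatures."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Operational thresholds of the regime decision cascade.

    ``dominance_ratio``: RA is "not appreciable" when max R < this fraction
    of max F at the final time. ``osc_min_extrema`` / ``osc_amplitude``:
    an oscillation needs at least this many alternating local extrema of
    spatially integrated RA over the final half of the run, with
    peak-to-trough range above this fraction of the mean (separates solver
    ripple from real oscillations). ``burst_ratio`` flags a transient RA
    burst (peak integrated RA / final integrated RA); ``interior_peak_drop``
    flags an aberrant final profile whose rostral endpoint falls below this
    fraction of the profile maximum. ``balance_drift`` is the allowed
    RA-front drift over the final third of the run, as a fraction of domain
    length, for the stationary balance regime.
    """

    dominance_ratio: float = 0.01
    osc_min_extrema: int = 3
    osc_amplitude: float = 0.2
    burst_ratio: float = 1.5
    interior_peak_drop: float = 0.5
    balance_drift: float = 0.05


@dataclass
class RegimeLabel:
    """Outcome of :func:`classify_regime`."""

    label: Regime
    switch_time: Optional[float] = None          # min; only for FGF_RA_SWITCH
    period: Optional[float] = None               # min; only when oscillating
    front_trajectory: Optional[np.ndarray] = None  # (n_times,) um, NaN = no front

    def __post_init__(self) -> None:
        if (self.switch_time is not None) != (self.label is Regime.FGF_RA_SWITCH):
            raise ValueError("switch_time must be present iff label is FGF_RA_SWITCH")


def ra_front_position(field: SignalField, time_index: int) -> Optional[float]:
    """Caudal-most x (um) at which RA has overtaken FGF8, or None.

    The front is where R >= F (signaling-molecule levels, not mRNAs) with R
    strictly positive; None when FGF8 leads everywhere or RA is absent.
    """
    R = field.R[time_index]
    F = field.F[time_index]
    ahead = (R >= F) & (R > 0.0)
    if not ahead.any():
        return None
    return float(field.x[int(np.argmax(ahead))])


def front_trajectory(field: SignalField) -> np.ndarray:
    """RA front position at every sampled time; NaN where no front exists."""
    out = np.full(len(field.t), np.nan)
    for i in range(len(field.t)):
        pos = ra_front_position(field, i)
        if pos is not None:
            out[i] = pos
    return out


def switch_completion_time(field: SignalField) -> Optional[float]:
    """First sampled time from which RA leads FGF8 at every grid point,
    sustained to the end of the run; None if the switch never completes."""
    ahead = (field.R >= field.F) & (field.R > 0.0)
    everywhere = ahead.all(axis=1)
    if not everywhere[-1]:
        return None
    # last index where the condition fails, +1 = onset of the sustained run
    failing = np.nonzero(~everywhere)[0]
    onset = 0 if len(failing) == 0 else failing[-1] + 1
    if onset >= len(field.t):
        return None
    return float(field.t[onset])


def integrated_ra(field: SignalField) -> np.ndarray:
    """Spatially integrated RA level over time (trapezoidal, AU*um)."""
    return np.trapezoid(field.R, field.x, axis=1)


def detect_oscillation(
    field: SignalField, config: ClassifierConfig = ClassifierConfig()
) -> Tuple[bool, Optional[float]]:
    """Detect sustained RA oscillation over the final half of the run.

    Operates on spatially integrated RA. Returns (flag, period) where the
    period is the mean inter-peak spacing in minutes.
    """
    if len(field.t) < 50:
        raise ValueError("oscillation detection needs >= 50 time samples")
    s = integrated_ra(field)
    s = s[len(s) // 2:]
    t = field.t[len(field.t) - len(s):]
    mean = float(np.mean(s))
    if mean <= 0:
        return False, None
    if (np.max(s) - np.min(s)) <= config.osc_amplitude * mean:
        return False, None
    prom = 0.05 * mean  # ignore solver ripple
    peaks, _ = find_peaks(s, prominence=prom)
    troughs, _ = find_peaks(-s, prominence=prom)
    if len(peaks) + len(troughs) < config.osc_min_extrema:
        return False, None
    period = float(np.mean(np.diff(t[peaks]))) if len(peaks) >= 2 else None
    return True, period


def _aberrant_ra(field: SignalField, config: ClassifierConfig) -> bool:
    """Transient RA burst or interior-peaked final RA profile."""
    s = integrated_ra(field)
    final = s[-1]
    if final <= 0:
        return bool(np.max(s) > 0)
    if np.max(s) / final > config.burst_ratio:
        return True
    prof = field.R[-1]
    peak = prof.max()
    return peak > 0 and prof[-1] < config.interior_peak_drop * peak


def classify_regime(
    field: SignalField, config: ClassifierConfig = ClassifierConfig()
) -> RegimeLabel:
    """Label a simulated field with one of the four signaling regimes.

    Decision cascade: FGF dominance (no appreciable RA at the final time);
    then aberrant/oscillatory RA (sustained oscillation, transient burst or
    interior-peaked profile); then a completed FGF-RA switch; then the
    stationary balance of opposing gradients. A field matching none raises
    :class:`UnclassifiableFieldError` rather than guessing.
    """
    traj = front_trajectory(field)
    R_end, F_end = field.R[-1], field.F[-1]
    if R_end.max() < config.dominance_ratio * F_end.max():
        return RegimeLabel(Regime.FGF_DOMINANT, front_trajectory=traj)

    oscillating, period = detect_oscillation(field, config)
    if oscillating or _aberrant_ra(field, config):
        return RegimeLabel(Regime.RA_ABERRANT_OSCILLATORY, period=period,
                           front_trajectory=traj)

    completion = switch_completion_time(field)
    if completion is not None:
        return RegimeLabel(Regime.FGF_RA_SWITCH, switch_time=completion,
                           front_trajectory=traj)

    # balance: a front exists and drifts little over the final third
    last_third = traj[2 * len(traj) // 3:]
    if np.isfinite(last_third).all():
        drift = np.max(last_third) - np.min(last_third)
        if drift < config.balance_drift * (field.x[-1] - field.x[0]):
            return RegimeLabel(Regime.FGF_RA_BALANCE, front_trajectory=traj)

    raise UnclassifiableFieldError(
        "field matches none of the four regime signatures "
        f"(R/F ratio {R_end.max() / max(F_end.max(), 1e-300):.3g}, "
        f"front drift over final third {np.nanmax(last_third) - np.nanmin(last_third) if np.isfinite(last_third).any() else float('nan'):.1f} um)"
    )
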