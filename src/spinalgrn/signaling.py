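"""FGF8-WNT8C-RA reaction-diffusion network on the maturation domain.

The caudal end of the elongating chick embryo maintains a ~2500 um strip of
tissue — the maturation domain — running from the neuro-mesodermal
progenitor (NMP) zone (x = 0, caudal) to the anterior boundary of the last
formed somite (x = 2500 um, rostral). The domain comoves with axial
elongation, so in domain coordinates the NMP zone is stationary and cells
age as they are displaced rostrally.

Six species are tracked on that strip: *Fgf8*, *Wnt8c* and *Raldh2* mRNAs
(no diffusion) and the FGF8 and WNT8C proteins plus retinoic acid (RA,
proxied by RALDH2 translation), which diffuse. The wiring is an extended
FGF-RA negative feedback loop: caudal FGF8 induces *Wnt8c* and represses RA
(blocking *Raldh2* transcription and boosting RA degradation through
CYP26A, folded into an FGF-dependent decay multiplier), while WNT8C and RA
autoregulation drive rostral RA production and RA in turn shuts down *Fgf8*
transcription. *Fgf8* transcription itself is confined caudally by an
exponentially decaying input ``F0(x) = 0.06 exp(-0.002 x)`` whose length
scale is the mRNA decay rate (ln 2 / 120 min ~ 0.006 / min) divided by the
elongation velocity (3 um/min); the comoving-frame advection is absorbed
into that constant, so no explicit advection term appears.

Integration is by the method of lines: central second differences with
zero-flux (Neumann) boundaries for the three diffusing species, and a
stiff-capable adaptive integrator (LSODA with a banded Jacobian) in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .hill import RegulatoryTerm, competitive_regulation, hill_activation, hill_repression

__all__ = [
    "SignalingParams",
    "DomainGrid",
    "SignalField",
    "SPECIES",
    "mrna_decay_rate",
    "spatial_decay_constant",
    "constant_input_profile",
    "laplacian",
    "signaling_rhs",
    "simulate_signaling",
    "signaling_preset",
    "PRESET_COLUMNS",
]

#: State-vector species order: mRNAs then the diffusing products, pairwise.
SPECIES = ("Fm", "F", "Wm", "W", "Rm", "R")


def mrna_decay_rate(half_life_min: float) -> float:
    """First-order decay rate ln 2 / t_half (per minute).

    The 2 h *Fgf8* mRNA half-life gives the canonical 0.006 / min.
    """
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / half_life_min


def spatial_decay_constant(decay_rate_per_min: float, velocity_um_per_min: float) -> float:
    """Spatial decay constant (per um) of a temporally decaying species in a
    frame comoving at the given axial-elongation velocity.

    A transcript decaying at rate beta in cells receding from the source at
    velocity v is graded in space as exp(-(beta/v) x); 0.006 / 3 = 0.002 /um.
    """
    if velocity_um_per_min <= 0:
        raise ValueError("velocity must be positive")
    return decay_rate_per_min / velocity_um_per_min


@dataclass(frozen=True)
class SignalingParams:
    """Rate, diffusion and Hill constants of the signaling network.

    Rates are per minute, diffusivities um^2/min, Hill constants and the
    input amplitude arbitrary concentration units (AU), ``f0_lambda`` per
    um. Defaults are the reference constants; the six interaction-strength
    Hill constants (``F_FW`` ... ``R_RR``) default to the balance preset
    (column II) and are what :func:`signaling_preset` varies.
    """

    # Fgf8 mRNA / FGF8 protein
    alpha_Fm: float = 1.0
    beta_Fm: float = 0.006
    alpha_Fp: float = 0.3
    beta_Fp: float = 0.005
    D_F: float = 120.0
    # Wnt8c mRNA / WNT8C protein
    alpha_Wm: float = 0.1
    beta_Wm: float = 0.03
    alpha_Wp: float = 0.3
    beta_Wp: float = 0.01
    D_W: float = 10.0
    # Raldh2 mRNA / RA
    alpha_Rm: float = 1.0
    beta_Rm: float = 0.03
    alpha_Rp: float = 0.3
    beta_Rp: float = 0.025
    D_R: float = 1200.0
    #: fold-increase of RA decay at saturating FGF8 (CYP26A action);
    #: dimensionless multiplier inside the decay bracket.
    beta_FR: float = 6.0
    # interaction-strength Hill constants (varied across presets)
    F_FW: float = 10.0   # FGF8 -> Wnt8c transcription (activation)
    F_FR1: float = 1.0   # FGF8 -| Raldh2 transcription (repression)
    F_FR2: float = 10.0  # FGF8 -> RA degradation via CYP26A (activation)
    W_WR: float = 1.0    # WNT8C -> Raldh2 transcription (activation)
    R_RF: float = 1.0    # RA -| Fgf8 transcription (repression)
    R_RR: float = 50.0   # RA -> Raldh2 transcription (autoregulation)
    # caudal Fgf8 transcription input F0(x) = f0_amp * exp(-f0_lambda x)
    f0_amp: float = 0.06
    f0_lambda: float = 0.002
    # Hill exponents (dimer binding)
    a: int = 2
    r: int = 2

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"signaling parameter {f.name} must be finite")
            if f.name in ("D_F", "D_W", "D_R"):
                if v < 0:
                    raise ValueError(f"signaling parameter {f.name} must be >= 0")
            elif v <= 0:
                raise ValueError(f"signaling parameter {f.name} must be finite and > 0")


#: Table of tested Hill-constant combinations, columns I-VIII, as
#: (F_FW, F_FR1, F_FR2, W_WR, R_RF, R_RR).
PRESET_COLUMNS = {
    "I":    (10.0, 1.0, 2.0, 1.0, 10.0, 50.0),
    "II":   (10.0, 1.0, 10.0, 1.0, 1.0, 50.0),
    "III":  (10.0, 5.0, 15.0, 0.2, 0.2, 50.0),
    "IV":   (10.0, 10.0, 10.0, 0.5, 0.1, 50.0),
    "V":    (10.0, 10.0, 10.0, 0.2, 0.3, 50.0),
    "VI":   (10.0, 10.0, 10.0, 0.5, 0.45, 50.0),
    "VII":  (10.0, 2.0, 20.0, 1.0, 1.0, 300.0),
    "VIII": (10.0, 20.0, 20.0, 1.0, 20.0, 300.0),
}


def signaling_preset(column: str, **overrides) -> SignalingParams:
    """Signaling parameters for one of the eight tested Hill-constant
    combinations (columns "I" ... "VIII").

    Columns I, II give FGF dominance and FGF-RA balance, III-VI FGF-RA
    switches of decreasing speed, VII-VIII aberrant/oscillatory RA.
    """
    key = column.strip().upper()
    if key not in PRESET_COLUMNS:
        raise KeyError(f"unknown preset column {column!r}; expected one of {list(PRESET_COLUMNS)}")
    F_FW, F_FR1, F_FR2, W_WR, R_RF, R_RR = PRESET_COLUMNS[key]
    base = SignalingParams(F_FW=F_FW, F_FR1=F_FR1, F_FR2=F_FR2,
                           W_WR=W_WR, R_RF=R_RF, R_RR=R_RR)
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class DomainGrid:
    """Spatial grid and time-sampling of the maturation domain.

    x = 0 is the caudal end (NMP zone), x = ``length`` the rostral end
    (anterior boundary of the last formed somite). ``velocity`` is the
    axial-elongation velocity used downstream to map cell age to position.
    """

    length: float = 2500.0     # um
    n_points: int = 251
    t_end: float = 6000.0      # min
    output_dt: float = 10.0    # min
    velocity: float = 3.0      # um/min

    def __post_init__(self) -> None:
        if self.n_points < 51:
            raise ValueError("n_points must be >= 51 to resolve the gradients")
        if self.length <= 0 or self.t_end <= 0 or self.output_dt <= 0 or self.velocity <= 0:
            raise ValueError("length, t_end, output_dt and velocity must be positive")

    @property
    def dx(self) -> float:
        return self.length / (self.n_points - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_points)

    @property
    def t_samples(self) -> np.ndarray:
        n = int(round(self.t_end / self.output_dt))
        return np.linspace(0.0, n * self.output_dt, n + 1)


@dataclass
class SignalField:
    """Sampled space-time solution of the signaling network.

    Arrays are indexed ``[time, space]``; ``x`` in um, ``t`` in minutes,
    levels in AU. ``Fm``/``Wm``/``Rm`` are mRNAs, ``F``/``W``/``R`` the
    corresponding diffusing signaling molecules (RA for ``R``).
    """

    x: np.ndarray
    t: np.ndarray
    Fm: np.ndarray
    F: np.ndarray
    Wm: np.ndarray
    W: np.ndarray
    Rm: np.ndarray
    R: np.ndarray
    velocity: float = 3.0

    def __post_init__(self) -> None:
        shape = (len(self.t), len(self.x))
        for name in SPECIES:
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"species {name} has shape {arr.shape}, expected {shape}")

    def species(self, name: str) -> np.ndarray:
        if name not in SPECIES:
            raise KeyError(f"unknown species {name!r}")
        return getattr(self, name)

    def copy(self) -> "SignalField":
        return SignalField(
            x=self.x.copy(), t=self.t.copy(), velocity=self.velocity,
            **{s: self.species(s).copy() for s in SPECIES},
        )


def constant_input_profile(grid: DomainGrid, params: SignalingParams) -> np.ndarray:
    """Caudal *Fgf8* transcription input F0(x) = f0_amp * exp(-f0_lambda x)."""
    return params.f0_amp * np.exp(-params.f0_lambda * grid.x)


def laplacian(values: np.ndarray, dx: float) -> np.ndarray:
    """Second spatial derivative, central differences, zero-flux boundaries.

    Boundaries use ghost-point mirroring (reflecting), so with zero reaction
    terms the spatial integral of the field is conserved.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < 3:
        raise ValueError("laplacian needs at least 3 grid points")
    lap = np.empty_like(values)
    lap[..., 1:-1] = values[..., 2:] - 2.0 * values[..., 1:-1] + values[..., :-2]
    lap[..., 0] = 2.0 * (values[..., 1] - values[..., 0])
    lap[..., -1] = 2.0 * (values[..., -2] - values[..., -1])
    return lap / dx**2


def _check_finite(state: np.ndarray, t: Optional[float] = None) -> None:
    if np.all(np.isfinite(state)):
        return
    bad = np.argwhere(~np.isfinite(state))
    i, s = bad[0][0], bad[0][1]
    when = "" if t is None else f" at t={t:.1f} min"
    raise FloatingPointError(
        f"non-finite level in species {SPECIES[s]} at grid index {i}{when}"
    )


def signaling_rhs(
    state: np.ndarray,
    grid: DomainGrid,
    params: SignalingParams,
    f0: Optional[np.ndarray] = None,
    t: Optional[float] = None,
) -> np.ndarray:
    """Time-derivatives of all six species at one instant.

    ``state`` has shape ``(n_points, 6)`` in :data:`SPECIES` order. The
    mRNAs follow pointwise transcription/decay kinetics; F, W, R add
    Fickian diffusion. Small negative excursions from the adaptive solver
    are clamped to zero before entering the Hill terms.
    """
    _check_finite(state, t)
    if f0 is None:
        f0 = constant_input_profile(grid, params)
    s = np.maximum(state, 0.0)
    Fm, F, Wm, W, Rm, R = (s[:, k] for k in range(6))
    a, r = params.a, params.r

    # Fgf8 mRNA: caudal input, repressed by RA
    dFm = params.alpha_Fm * f0 * hill_repression(RegulatoryTerm(R, params.R_RF, r)) \
        - params.beta_Fm * Fm
    # FGF8 protein: translation, decay, diffusion
    dF = params.alpha_Fp * Fm - params.beta_Fp * F + params.D_F * laplacian(F, grid.dx)
    # Wnt8c mRNA: activated by FGF8
    dWm = params.alpha_Wm * hill_activation(RegulatoryTerm(F, params.F_FW, a)) \
        - params.beta_Wm * Wm
    dW = params.alpha_Wp * Wm - params.beta_Wp * W + params.D_W * laplacian(W, grid.dx)
    # Raldh2 mRNA: WNT8C + RA autoactivation on a shared promoter, gated by
    # FGF8 repression
    act = competitive_regulation(
        activators=[RegulatoryTerm(W, params.W_WR, a), RegulatoryTerm(R, params.R_RR, a)],
    )
    dRm = params.alpha_Rm * act * hill_repression(RegulatoryTerm(F, params.F_FR1, r)) \
        - params.beta_Rm * Rm
    # RA: translation proxy, FGF8-enhanced decay (CYP26A), diffusion
    decay = params.beta_Rp * R * (
        1.0 + params.beta_FR * hill_activation(RegulatoryTerm(F, params.F_FR2, a))
    )
    dR = params.alpha_Rp * Rm - decay + params.D_R * laplacian(R, grid.dx)

    return np.column_stack([dFm, dF, dWm, dW, dRm, dR])


def fgf8_mrna_initial_state(params: SignalingParams, grid: DomainGrid) -> np.ndarray:
    """Default initial state: the established *Fgf8* mRNA gradient.

    The tissue enters the modeled window already transcribing *Fgf8*
    caudally, so the simulation starts from the RA-free steady state of the
    mRNA equation, ``Fm(x) = alpha_Fm F0(x) / beta_Fm``, with every other
    species at zero; proteins and RA then emerge dynamically.
    """
    state = np.zeros((grid.n_points, 6))
    state[:, 0] = params.alpha_Fm * constant_input_profile(grid, params) / params.beta_Fm
    return state


def simulate_signaling(
    params: Optional[SignalingParams] = None,
    grid: Optional[DomainGrid] = None,
    initial: Optional[np.ndarray] = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> SignalField:
    """Integrate the signaling network from t = 0 to ``grid.t_end``.

    Method of lines with point-major state ordering (bandwidth 6), LSODA
    with a banded Jacobian. ``initial`` is an optional ``(n_points, 6)``
    state in :data:`SPECIES` order; the default is the established *Fgf8*
    mRNA gradient of :func:`fgf8_mrna_initial_state`. Deterministic for
    fixed inputs and tolerances.
    """
    params = params or SignalingParams()
    grid = grid or DomainGrid()
    nx = grid.n_points
    if initial is None:
        y0 = fgf8_mrna_initial_state(params, grid).ravel()
    else:
        initial = np.asarray(initial, dtype=float)
        if initial.shape != (nx, 6):
            raise ValueError(f"initial state must have shape ({nx}, 6)")
        y0 = initial.ravel()

    f0 = constant_input_profile(grid, params)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return signaling_rhs(y.reshape(nx, 6), grid, params, f0=f0, t=t).ravel()

    sol = solve_ivp(
        rhs, (0.0, grid.t_end), y0, method="LSODA",
        t_eval=grid.t_samples, rtol=rtol, atol=atol,
        lband=6, uband=6,
    )
    if not sol.success:
        raise RuntimeError(
            f"signaling integration failed at t={sol.t[-1] if len(sol.t) else 0.0:.1f} min: "
            f"{sol.message}"
        )
    y = sol.y.T.reshape(len(sol.t), nx, 6)
    if y.min() < -1e-6:
        raise RuntimeError(
            f"negative-state blow-up: min level {y.min():.3e} during integration"
        )
    # tiny solver-noise negatives -> exact zero
    y[(y < 0.0)] = 0.0
    arrays = {name: np.ascontiguousarray(y[:, :, k]) for k, name in enumerate(SPECIES)}
    return SignalField(x=grid.x, t=sol.t, velocity=grid.velocity, **arrays)
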