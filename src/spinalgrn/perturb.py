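"""Perturbation experiments: signal noise, input-shape replacement, Cdx4
manipulations, Hill-constant robustness sweeps and boundary-shift metrics.

The experiments probe canalization: the staggered expression pattern should
survive moderate periodic or random noise on the signaling inputs and
transcriptional noise on *Cdx4*, should collapse when the graded spatial
information is destroyed (Boolean step or linear ramp inputs), and responds
to *Cdx4* loss/overexpression with characteristic domain rearrangements
(rostral Nkx1.2 expansion + caudal Ngn2 expansion, or Ngn2 loss).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .signaling import SignalField
from .tfnet import Cdx4Drive, TFParams, TFProfile

__all__ = [
    "PerturbationKind",
    "PerturbationSpec",
    "perturb_signals",
    "replace_input_shape",
    "perturb_cdx4",
    "scale_hill_constants",
    "boundary_shift",
    "max_abs_shift",
]


class PerturbationKind(str, Enum):
    PERIODIC_NOISE = "PERIODIC_NOISE"
    RANDOM_NOISE = "RANDOM_NOISE"
    BOOLEAN_INPUT = "BOOLEAN_INPUT"
    LINEAR_INPUT = "LINEAR_INPUT"
    CDX4_NULL = "CDX4_NULL"
    CDX4_OVEREXPRESS = "CDX4_OVEREXPRESS"
    CDX4_NOISE = "CDX4_NOISE"
    HILL_SCALE = "HILL_SCALE"


_STOCHASTIC = {PerturbationKind.RANDOM_NOISE, PerturbationKind.CDX4_NOISE}


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation experiment.

    ``amplitude`` is the relative noise amplitude (multiplicative, so
    amplitude < 1 preserves nonnegativity), ``period`` the period of the
    periodic disturbance in minutes, ``factor`` the fold-change for
    overexpression / Hill scaling, ``seed`` the RNG seed (required for the
    stochastic kinds), ``redraw_dt`` the correlation time of transcriptional
    noise in minutes.
    """

    kind: PerturbationKind
    amplitude: float = 0.0
    period: float = 200.0
    factor: float = 1.0
    seed: Optional[int] = None
    redraw_dt: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must be in [0, 1)")
        if self.factor <= 0 or self.period <= 0 or self.redraw_dt <= 0:
            raise ValueError("factor, period and redraw_dt must be positive")
        if self.kind in _STOCHASTIC and self.seed is None:
            raise ValueError(f"{self.kind.value} requires a seed")


def perturb_signals(field: SignalField, spec: PerturbationSpec) -> SignalField:
    """Multiplicative noise on the signaling-molecule fields F, W, R.

    PERIODIC: every signal scaled by ``1 + amplitude*sin(2*pi*t/period)``
    (coherent across species and space). RANDOM: scaled by
    ``1 + amplitude*u`` with u ~ U[-1, 1] drawn independently per sampled
    time and species, seeded. mRNA fields are untouched; outputs floored
    at 0.
    """
    if spec.kind not in (PerturbationKind.PERIODIC_NOISE, PerturbationKind.RANDOM_NOISE):
        raise ValueError(f"perturb_signals cannot apply {spec.kind.value}")
    out = field.copy()
    nt = len(field.t)
    if spec.kind is PerturbationKind.PERIODIC_NOISE:
        factors = {name: 1.0 + spec.amplitude * np.sin(2.0 * np.pi * field.t / spec.period)
                   for name in ("F", "W", "R")}
    else:
        rng = np.random.default_rng(spec.seed)
        factors = {name: 1.0 + spec.amplitude * rng.uniform(-1.0, 1.0, size=nt)
                   for name in ("F", "W", "R")}
    for name, fac in factors.items():
        arr = out.species(name)
        arr *= fac[:, None]
        np.maximum(arr, 0.0, out=arr)
    return out


def _handover_index(field: SignalField, time_index: int) -> int:
    """Grid index of the caudal-most point where RA leads FGF8 at one time;
    one past the end when FGF8 leads everywhere (whole domain caudal-state)."""
    R, F = field.R[time_index], field.F[time_index]
    ahead = (R >= F) & (R > 0.0)
    if not ahead.any():
        return len(field.x)
    return int(np.argmax(ahead))


def replace_input_shape(field: SignalField, spec: PerturbationSpec) -> SignalField:
    """Destroy the graded spatial information of the signals.

    LINEAR_INPUT replaces each signal's spatial profile by the straight line
    through its two endpoint values. BOOLEAN_INPUT reduces the tissue to two
    signaling states: every signal takes its caudal-end value caudal to the
    FGF8-to-RA handover position (the caudal-most point where RA leads
    FGF8) and its rostral-end value rostral of it — on/off signals switching
    at one common boundary. Both act at every sampled time and preserve the
    endpoint levels.
    """
    if spec.kind not in (PerturbationKind.BOOLEAN_INPUT, PerturbationKind.LINEAR_INPUT):
        raise ValueError(f"replace_input_shape cannot apply {spec.kind.value}")
    out = field.copy()
    x = field.x
    w = (x - x[0]) / (x[-1] - x[0])
    for i in range(len(field.t)):
        if spec.kind is PerturbationKind.LINEAR_INPUT:
            for name in ("F", "W", "R"):
                arr = out.species(name)
                arr[i] = arr[i, 0] * (1.0 - w) + arr[i, -1] * w
        else:
            # clamp the step into the interior so both endpoints keep their
            # original values even before a handover exists
            k = int(np.clip(_handover_index(field, i), 1, len(x) - 1))
            for name in ("F", "W", "R"):
                arr = out.species(name)
                caudal, rostral = arr[i, 0], arr[i, -1]
                arr[i, :k] = caudal
                arr[i, k:] = rostral
    return out


class Cdx4TranscriptionalNoise:
    """Cell-intrinsic multiplicative noise on *Cdx4* transcription.

    Each cell carries an independent noise stream: a factor
    ``1 + amplitude*u``, u ~ U[-1, 1], redrawn every ``redraw_dt`` minutes.
    Called with a 2-D (time, cell) array it resolves one seeded stream per
    cell column; with scalars/1-D input it uses the first stream. Fully
    deterministic given the seed.
    """

    def __init__(self, amplitude: float, redraw_dt: float, seed: int):
        self.amplitude = amplitude
        self.redraw_dt = redraw_dt
        self.seed = seed

    def _column(self, cell: int, bins: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng([self.seed, cell])
        draws = 1.0 + self.amplitude * rng.uniform(-1.0, 1.0, size=int(bins.max()) + 1)
        return draws[bins]

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        bins = np.maximum(np.floor(t / self.redraw_dt).astype(int), 0)
        if bins.ndim == 1:
            return self._column(0, bins)
        out = np.empty_like(t)
        for j in range(t.shape[1]):
            out[:, j] = self._column(j, bins[:, j])
        return out


def perturb_cdx4(spec: PerturbationSpec) -> Cdx4Drive:
    """*Cdx4* transcription manipulation as a :class:`~spinalgrn.tfnet.Cdx4Drive`.

    CDX4_NULL zeroes transcription. CDX4_OVEREXPRESS scales the endogenous
    regulated rate by ``factor`` and adds a constitutive component at
    ``factor - 1`` times the maximal rate: a misexpression transgene
    transcribes independently of the endogenous promoter's signal inputs,
    so the boost reaches rostral cells where endogenous *Cdx4*
    transcription has ceased. CDX4_NOISE attaches cell-intrinsic
    multiplicative noise (amplitude, redrawn every ``redraw_dt`` min,
    seeded).
    """
    if spec.kind is PerturbationKind.CDX4_NULL:
        return Cdx4Drive(scale=0.0)
    if spec.kind is PerturbationKind.CDX4_OVEREXPRESS:
        return Cdx4Drive(scale=spec.factor, const=spec.factor - 1.0)
    if spec.kind is PerturbationKind.CDX4_NOISE:
        return Cdx4Drive(
            scale=Cdx4TranscriptionalNoise(spec.amplitude, spec.redraw_dt, spec.seed)
        )
    raise ValueError(f"perturb_cdx4 cannot apply {spec.kind.value}")


def scale_hill_constants(params: TFParams, factor: float) -> TFParams:
    """All 20 TF-network Hill constants scaled by ``factor``; rates untouched."""
    return params.scale_hill_constants(factor)


@dataclass(frozen=True)
class GeneShift:
    """Boundary displacement of one gene between control and perturbed
    profiles; ``edge_shifts`` pairs (caudal-edge, rostral-edge) per matched
    interval, signed, rostral-positive, in um."""

    gene: str
    edge_shifts: Tuple[Tuple[float, float], ...]
    domains_lost: int = 0
    domains_gained: int = 0

    @property
    def max_abs(self) -> float:
        if not self.edge_shifts:
            return 0.0
        return max(max(abs(a), abs(b)) for a, b in self.edge_shifts)


def _match_intervals(
    c: List[Tuple[float, float]], p: List[Tuple[float, float]]
) -> List[Tuple[int, int]]:
    """Pair control/perturbed intervals by greatest overlap (greedy)."""
    pairs: List[Tuple[int, int]] = []
    used_p: set = set()
    for i, (cs, ce) in enumerate(c):
        best, best_ov = None, 0.0
        for j, (ps, pe) in enumerate(p):
            if j in used_p:
                continue
            ov = min(ce, pe) - max(cs, ps)
            if ov > best_ov:
                best, best_ov = j, ov
        if best is not None:
            pairs.append((i, best))
            used_p.add(best)
    return pairs


def boundary_shift(
    control: Dict[str, List[Tuple[float, float]]],
    perturbed: Dict[str, List[Tuple[float, float]]],
) -> Dict[str, GeneShift]:
    """Per-gene, per-edge signed displacement between two extracted domain
    sets sharing a grid and threshold rule. Intervals are matched by
    overlap; whole domains appearing or disappearing are flagged
    categorically instead of numerically."""
    if set(control) != set(perturbed):
        raise ValueError("control and perturbed domain sets cover different genes")
    out: Dict[str, GeneShift] = {}
    for gene in control:
        c, p = control[gene], perturbed[gene]
        pairs = _match_intervals(c, p)
        shifts = tuple(
            (p[j][0] - c[i][0], p[j][1] - c[i][1]) for i, j in pairs
        )
        out[gene] = GeneShift(
            gene=gene, edge_shifts=shifts,
            domains_lost=len(c) - len(pairs),
            domains_gained=len(p) - len(pairs),
        )
    return out


def max_abs_shift(shifts: Dict[str, GeneShift]) -> float:
    """Largest absolute boundary displacement across all genes (um)."""
    return max((s.max_abs for s in shifts.values()), default=0.0)
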