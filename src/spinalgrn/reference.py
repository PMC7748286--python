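"""The reference experiment suite under the study conditions.

One place that runs, with the shipped defaults, every headline computation:
the eight-preset regime table, switch kinetics, TF patterning under the
balance input (curated vs uniform Hill constants), the ±30% robustness
sweep, and the perturbation experiments. Used by the ``reproduce`` CLI
subcommand and the reproduction script.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, Optional, Sequence

from .perturb import (
    PerturbationKind,
    PerturbationSpec,
    boundary_shift,
    max_abs_shift,
    perturb_cdx4,
    perturb_signals,
    replace_input_shape,
)
from .regimes import ClassifierConfig, classify_regime
from .signaling import DomainGrid, SignalField, simulate_signaling, signaling_preset, PRESET_COLUMNS
from .tfnet import (
    OBSERVABLE_GENES,
    TFParams,
    TFProfile,
    assemble_spatial_profile,
    check_pattern,
    extract_domains,
)

__all__ = [
    "regime_table",
    "balance_field",
    "patterning_suite",
    "max_symmetric_hill_scaling",
    "perturbation_suite",
    "reference_suite",
]

DEFAULT_THRESHOLD = 0.1


def regime_table(
    grid: Optional[DomainGrid] = None,
    classifier: ClassifierConfig = ClassifierConfig(),
    columns: Iterable[str] = tuple(PRESET_COLUMNS),
) -> Dict[str, Dict]:
    """Classify every requested preset column; returns
    {column: {label, switch_time, period}}."""
    grid = grid or DomainGrid()
    out = {}
    for col in columns:
        label = classify_regime(simulate_signaling(signaling_preset(col), grid), classifier)
        out[col] = {"label": label.label.value,
                    "switch_time": label.switch_time,
                    "period": label.period}
    return out


def balance_field(grid: Optional[DomainGrid] = None) -> SignalField:
    """The FGF-RA balance signaling field (preset II) used as TF input."""
    return simulate_signaling(signaling_preset("II"), grid or DomainGrid())


def _verdict(field: SignalField, params: TFParams,
             threshold: float = DEFAULT_THRESHOLD, **kwargs) -> str:
    profile = assemble_spatial_profile(field, params, **kwargs)
    domains = extract_domains(profile, threshold_fraction=threshold)
    return check_pattern(domains, domain_length=float(field.x[-1])).verdict


def patterning_suite(
    field: Optional[SignalField] = None, threshold: float = DEFAULT_THRESHOLD
) -> Dict[str, str]:
    """Pattern verdicts for the curated Hill constants and the two uniform
    (all-20, all-2) control networks."""
    field = field if field is not None else balance_field()
    return {
        "curated": _verdict(field, TFParams(), threshold),
        "uniform_20": _verdict(field, TFParams().with_uniform_hill_constants(20.0), threshold),
        "uniform_2": _verdict(field, TFParams().with_uniform_hill_constants(2.0), threshold),
    }


def max_symmetric_hill_scaling(
    field: Optional[SignalField] = None,
    percents: Sequence[int] = (10, 20, 30),
    threshold: float = DEFAULT_THRESHOLD,
) -> Dict:
    """Largest tested symmetric percentage by which all TF Hill constants
    can be scaled up and down while the staggered pattern survives.

    Tests each percentage in ``percents`` in both directions (x(1-p/100)
    and x(1+p/100)); returns the outcome per percentage and the largest
    passing one.
    """
    field = field if field is not None else balance_field()
    control = _verdict(field, TFParams(), threshold)
    results = {}
    largest = 0
    for p in percents:
        verdicts = {
            "down": _verdict(field, TFParams().scale_hill_constants(1.0 - p / 100.0), threshold),
            "up": _verdict(field, TFParams().scale_hill_constants(1.0 + p / 100.0), threshold),
        }
        ok = (verdicts["down"] == control == verdicts["up"] == "CORRECT_STAGGERED")
        results[p] = {**verdicts, "preserved": ok}
        if ok and p > largest:
            largest = p
    return {"control": control, "per_percent": results,
            "max_preserved_percent": largest}


def perturbation_suite(
    field: Optional[SignalField] = None,
    n_noise_seeds: int = 10,
    threshold: float = DEFAULT_THRESHOLD,
) -> Dict:
    """The signal-noise, input-shape and Cdx4 manipulation experiments."""
    field = field if field is not None else balance_field()
    control = assemble_spatial_profile(field, TFParams())
    control_domains = extract_domains(control, threshold_fraction=threshold)
    obs_control = {g: control_domains[g] for g in OBSERVABLE_GENES}
    L = float(field.x[-1])

    def verdict_of(profile: TFProfile, reference=None) -> Dict:
        domains = extract_domains(profile, threshold_fraction=threshold,
                                  reference=reference)
        shifts = boundary_shift(obs_control, {g: domains[g] for g in OBSERVABLE_GENES})
        return {
            "verdict": check_pattern(domains, domain_length=L).verdict,
            "max_shift_um": max_abs_shift(shifts),
            "domains": domains,
            "shifts": shifts,
        }

    report: Dict = {"control": check_pattern(control_domains, domain_length=L).verdict}
    periodic = perturb_signals(field, PerturbationSpec(
        PerturbationKind.PERIODIC_NOISE, amplitude=0.2, period=200.0))
    report["periodic_noise"] = verdict_of(assemble_spatial_profile(periodic, TFParams()))
    random_ = perturb_signals(field, PerturbationSpec(
        PerturbationKind.RANDOM_NOISE, amplitude=0.25, seed=0))
    report["random_noise"] = verdict_of(assemble_spatial_profile(random_, TFParams()))
    boolean = replace_input_shape(field, PerturbationSpec(PerturbationKind.BOOLEAN_INPUT))
    report["boolean_input"] = verdict_of(assemble_spatial_profile(boolean, TFParams()))
    linear = replace_input_shape(field, PerturbationSpec(PerturbationKind.LINEAR_INPUT))
    report["linear_input"] = verdict_of(assemble_spatial_profile(linear, TFParams()))
    null = assemble_spatial_profile(
        field, TFParams(),
        cdx4_rate=perturb_cdx4(PerturbationSpec(PerturbationKind.CDX4_NULL)))
    report["cdx4_null"] = verdict_of(null, reference=control)
    over = assemble_spatial_profile(
        field, TFParams(),
        cdx4_rate=perturb_cdx4(PerturbationSpec(PerturbationKind.CDX4_OVEREXPRESS,
                                                factor=5.0)))
    report["cdx4_overexpress"] = verdict_of(over, reference=control)
    noise_runs = {}
    for seed in range(n_noise_seeds):
        prof = assemble_spatial_profile(
            field, TFParams(),
            cdx4_rate=perturb_cdx4(PerturbationSpec(PerturbationKind.CDX4_NOISE,
                                                    amplitude=0.25, seed=seed)))
        noise_runs[seed] = verdict_of(prof, reference=control)
    report["cdx4_noise"] = {
        "per_seed": noise_runs,
        "max_shift_um": max((r["max_shift_um"] for r in noise_runs.values()),
                            default=0.0),
    }
    return report


def _strip(obj):
    """Drop bulky domain/shift payloads for the JSON summary report."""
    if isinstance(obj, dict):
        return {k: _strip(v) for k, v in obj.items() if k not in ("domains", "shifts")}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    return obj


def reference_suite(n_noise_seeds: int = 10) -> Dict:
    """Run everything with the shipped defaults; JSON-serialisable summary."""
    grid = DomainGrid()
    field = balance_field(grid)
    return {
        "regimes": regime_table(grid),
        "patterning": patterning_suite(field),
        "hill_scaling": max_symmetric_hill_scaling(field),
        "perturbations": _strip(perturbation_suite(field, n_noise_seeds=n_noise_seeds)),
    }
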