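"""Result serialisation: long-format CSV for fields and profiles, JSON for
verdicts, optional space-time heatmaps, run manifests, and the parameter
sweep driver."""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from pathlib import Path
from typing import Any, Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .regimes import ClassifierConfig, RegimeLabel, classify_regime
from .signaling import SPECIES, DomainGrid, SignalField, SignalingParams, simulate_signaling
from .tfnet import GENES, TFProfile

logger = logging.getLogger("spinalgrn")

__all__ = [
    "field_to_frame",
    "frame_to_field",
    "write_field_csv",
    "read_field_csv",
    "profile_to_frame",
    "write_profile_csv",
    "domains_to_frame",
    "label_to_dict",
    "write_verdict_json",
    "write_manifest",
    "plot_field_heatmaps",
    "sweep",
]

_FIELD_HEADER = (
    "# signaling field, long format; time in minutes, x in um (0 = caudal "
    "NMP end), level in AU; species Fm/Wm/Rm are mRNAs, F/W = FGF8/WNT8C "
    "proteins, R = retinoic acid\n"
)


def field_to_frame(field: SignalField) -> pd.DataFrame:
    """Long-format (time, x, species, level) view of a signal field."""
    nt, nx = len(field.t), len(field.x)
    frames = []
    for name in SPECIES:
        frames.append(pd.DataFrame({
            "time": np.repeat(field.t, nx),
            "x": np.tile(field.x, nt),
            "species": name,
            "level": field.species(name).ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def frame_to_field(frame: pd.DataFrame, velocity: float = 3.0) -> SignalField:
    """Rebuild a :class:`SignalField` from its long-format frame."""
    t = np.sort(frame["time"].unique())
    x = np.sort(frame["x"].unique())
    arrays = {}
    for name in SPECIES:
        sub = frame[frame["species"] == name].sort_values(["time", "x"])
        arrays[name] = sub["level"].to_numpy().reshape(len(t), len(x))
    return SignalField(x=x, t=t, velocity=velocity, **arrays)


def write_field_csv(field: SignalField, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_FIELD_HEADER)
        field_to_frame(field).to_csv(fh, index=False)
    return path


def read_field_csv(path: Union[str, Path], velocity: float = 3.0) -> SignalField:
    return frame_to_field(pd.read_csv(path, comment="#"), velocity=velocity)


def profile_to_frame(profile: TFProfile) -> pd.DataFrame:
    """Long-format (x, gene, mrna, protein) view of a TF profile."""
    rows = []
    for gene in GENES:
        prot = profile.protein.get(gene)
        rows.append(pd.DataFrame({
            "x": profile.x,
            "gene": gene,
            "mrna": profile.mrna[gene],
            "protein": prot if prot is not None else np.nan,
        }))
    return pd.concat(rows, ignore_index=True)


def write_profile_csv(profile: TFProfile, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# TF spatial profile at eval_time="
                 f"{profile.eval_time} min; x in um, levels in AU\n")
        profile_to_frame(profile).to_csv(fh, index=False)
    return path


def domains_to_frame(domains: Dict[str, List[tuple]]) -> pd.DataFrame:
    rows = [
        {"gene": gene, "start_um": s, "end_um": e}
        for gene, intervals in domains.items()
        for s, e in intervals
    ]
    return pd.DataFrame(rows, columns=["gene", "start_um", "end_um"])


def label_to_dict(label: RegimeLabel) -> Dict[str, Any]:
    return {
        "label": label.label.value,
        "switch_time": label.switch_time,
        "period": label.period,
    }


def write_verdict_json(record: Dict[str, Any], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path


def write_manifest(
    path: Union[str, Path],
    config: Any,
    seeds: Sequence[int] = (),
    tolerances: Optional[Dict[str, float]] = None,
) -> Path:
    """Reproducibility manifest: config hash + content, seeds, tolerances,
    package/library versions."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    else:
        payload = json.dumps(config, default=str, sort_keys=True)
    import scipy

    manifest = {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": json.loads(payload),
        "seeds": list(seeds),
        "tolerances": tolerances or {"rtol": 1e-6, "atol": 1e-9},
        "versions": {
            "spinalgrn": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    return write_verdict_json(manifest, path)


def plot_field_heatmaps(field: SignalField, prefix: Union[str, Path]) -> List[Path]:
    """Space-time heatmaps (one PNG per signaling molecule). Requires
    matplotlib; the core pipeline never imports it."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    cmaps = {"F": "Reds", "W": "RdPu", "R": "Blues"}
    for name, cmap in cmaps.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.pcolormesh(field.x, field.t, field.species(name),
                           cmap=cmap, shading="auto")
        ax.set_xlabel("x (um, caudal -> rostral)")
        ax.set_ylabel("t (min)")
        ax.set_title(name)
        fig.colorbar(im, ax=ax, label="level (AU)")
        out = prefix.with_name(prefix.name + f"_{name}.png")
        fig.savefig(out, dpi=120)
        plt.close(fig)
        paths.append(out)
    return paths


def sweep(
    param_grid: Dict[str, Iterable[float]],
    base_params: Optional[SignalingParams] = None,
    grid: Optional[DomainGrid] = None,
    classifier: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Classify one signaling run per combination of the given parameter
    values. Returns a tidy table (parameters..., label, switch_time,
    period); per-run failures are recorded in an ``error`` column and the
    sweep continues."""
    base_params = base_params or SignalingParams()
    grid = grid or DomainGrid()
    names = list(param_grid)
    rows = []
    for combo in itertools.product(*(list(param_grid[n]) for n in names)):
        overrides = dict(zip(names, combo))
        row: Dict[str, Any] = dict(overrides)
        try:
            params = dataclasses.replace(base_params, **overrides)
            label = classify_regime(simulate_signaling(params, grid), classifier)
            row.update(label_to_dict(label))
            row["error"] = None
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad corners
            logger.warning("sweep point %s failed: %s", overrides, exc)
            row.update({"label": None, "switch_time": None, "period": None,
                        "error": str(exc)})
        rows.append(row)
        logger.info("sweep point %s -> %s", overrides, row.get("label"))
    return pd.DataFrame(rows)
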