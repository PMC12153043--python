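"""Readers and writers for the pipeline's on-disk formats.

Plain-text first: curves, tracks, vectors, strain maps, event and colony
tables are CSV with a header row; indentation metadata and simulation/growth
parameters are YAML sidecars; image stacks are multi-page 16-bit TIFF.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .growth import GrowthParams
from .indentation import IndentationCurve
from .simulate import SimConfig

__all__ = [
    "write_curve", "read_curve",
    "write_stack", "read_stack",
    "write_table", "read_table",
    "write_params", "read_params",
    "write_config", "read_config",
    "write_json",
]

_CURVE_COLUMNS = ["t_s", "d_mm", "F_N"]


def write_curve(curve: IndentationCurve, path: str | Path) -> None:
    """Write a curve as CSV (t_s,d_mm,F_N) plus a YAML metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"t_s": curve.t, "d_mm": curve.d, "F_N": curve.F}).to_csv(
        path, index=False)
    meta = {"R_mm": float(curve.R), "rate_mm_s": float(curve.rate),
            "d_max_mm": float(curve.d_max)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def read_curve(path: str | Path) -> IndentationCurve:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return IndentationCurve(t=df["t_s"].to_numpy(), d=df["d_mm"].to_numpy(),
                            F=df["F_N"].to_numpy(), R=meta["R_mm"],
                            rate=meta["rate_mm_s"], d_max=meta["d_max_mm"])


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write an image stack as multi-page 16-bit grayscale TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _to_plain(obj):
    """Recursively convert dataclass values to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _from_lists(obj):
    """YAML round trip: restore tuples where the dataclasses expect them."""
    if isinstance(obj, list):
        return tuple(_from_lists(v) for v in obj)
    if isinstance(obj, dict):
        return {k: _from_lists(v) for k, v in obj.items()}
    return obj


def write_params(params: GrowthParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(dataclasses.asdict(params))))


def read_params(path: str | Path) -> GrowthParams:
    raw = yaml.safe_load(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(GrowthParams)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown growth parameters: {sorted(unknown)}")
    kwargs = {k: _from_lists(v) if k != "viability_table" else
              {float(p): tuple(v) for p, v in raw[k].items()}
              for k, v in raw.items()}
    return GrowthParams(**kwargs)


def write_config(cfg: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(dataclasses.asdict(cfg))))


def read_config(path: str | Path) -> SimConfig:
    return SimConfig(**yaml.safe_load(Path(path).read_text()))


def write_json(obj, path: str | Path) -> None:
    import json

    Path(path).write_text(json.dumps(_to_plain(obj), indent=2) + "\n")
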