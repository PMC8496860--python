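"""File formats: parameter sets, strain tables, profiles, chains, configs.

Parameter sets are flat JSON mappings (canonical) keyed by the 45 symbol
names, with an optional ``"knockouts"`` list; YAML is accepted on read and
written when the path ends in .yaml/.yml.  Unknown keys are an error;
missing keys fall back to the packaged defaults with a logged warning.
Floats are serialized with 9 significant digits; grid concentrations are
stored exact.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .params import (
    PARAM_NAMES,
    InvalidParameterError,
    ModelParameters,
    reference_parameters,
)
from .steady_state import DecisionFront, InductionProfile, SugarGrid, default_grid
from .tables import StrainTable

__all__ = [
    "read_params",
    "write_params",
    "read_strain_table",
    "write_strain_table",
    "write_profile",
    "write_front",
    "RunConfig",
]

logger = logging.getLogger(__name__)


def _sig9(x: float) -> float:
    return float(f"{float(x):.9g}")


def read_params(path: str | Path) -> ModelParameters:
    """Read a parameter set from JSON (canonical) or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"{path}: expected a flat mapping")
    knockouts = tuple(raw.pop("knockouts", ()))
    unknown = set(raw) - set(PARAM_NAMES)
    if unknown:
        raise InvalidParameterError(
            f"{path}: unknown parameter keys: {sorted(unknown)}"
        )
    defaults = reference_parameters()
    values = {}
    for name in PARAM_NAMES:
        if name in raw:
            values[name] = float(raw[name])
        else:
            values[name] = defaults[name]
            logger.warning(
                "%s: missing key %r; using packaged default %g",
                path, name, defaults[name],
            )
    from .params import apply_knockout

    params = ModelParameters(values, frozenset(knockouts))
    for gene in knockouts:       # re-zero in case the file kept old values
        params = apply_knockout(params, gene)
    return params


def write_params(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set (JSON canonical; YAML by extension)."""
    path = Path(path)
    out: dict = {n: _sig9(params[n]) for n in PARAM_NAMES}
    if params.knockouts:
        out["knockouts"] = sorted(params.knockouts)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(out, sort_keys=False))
    else:
        path.write_text(json.dumps(out, indent=2) + "\n")


def read_strain_table(
    path: str | Path,
    grid: SugarGrid | None = None,
    strain_id: str | None = None,
    knockouts: tuple[str, ...] = (),
) -> StrainTable:
    """Read a strain table CSV (glucose,galactose,on_peak,off_peak,valid).

    Conditions are matched to the grid within relative 1e-6; off-grid
    conditions raise, naming the nearest grid value.
    """
    path = Path(path)
    df = pd.read_csv(path)
    table = StrainTable(strain_id or path.stem, df, knockouts)
    return table.align_to_grid(grid or default_grid())


def write_strain_table(table: StrainTable, path: str | Path) -> None:
    df = table.data.copy()
    for col in ("glucose", "galactose"):
        df[col] = df[col].astype(float)          # exact ladder values
    for col in ("on_peak", "off_peak"):
        df[col] = df[col].map(_sig9)
    df.to_csv(path, index=False)


def write_profile(profile: InductionProfile, path: str | Path) -> None:
    """Long-format profile CSV (one row per grid condition)."""
    df = profile.to_frame()
    for col in ("g1_high", "g1_low", "normalized_high", "normalized_low"):
        df[col] = df[col].map(_sig9)
    df.to_csv(path, index=False)


def write_front(front: DecisionFront, path: str | Path) -> None:
    df = front.to_frame()
    df["galactose_crossing"] = df["galactose_crossing"].map(_sig9)
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Resolved run settings, written beside every output for provenance."""

    command: str = ""
    seed: int | None = None
    grid_glucose: tuple[float, ...] = field(
        default_factory=lambda: default_grid().glucose_levels
    )
    grid_galactose: tuple[float, ...] = field(
        default_factory=lambda: default_grid().galactose_levels
    )
    solver: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def grid(self) -> SugarGrid:
        return SugarGrid(tuple(self.grid_glucose), tuple(self.grid_galactose))

    def write(self, path: str | Path) -> None:
        from . import __version__

        payload = asdict(self)
        payload["galvar_version"] = __version__
        Path(path).write_text(json.dumps(payload, indent=2, default=list) + "\n")
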