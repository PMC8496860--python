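"""Single-parameter phenotype switching and the fitting-improvement matrix.

For each query strain and each model parameter, the parameter is scanned
across six orders of magnitude centered on its starting value (48 points
evenly spaced in log10 on [1e-3, 1e+3], endpoints inclusive, plus the x1
default as an extra candidate) while everything else is held fixed.  The
improvement

    dObj = (Obj_start - Obj_best) / Obj_start

quantifies how far single-parameter tuning can move the simulated
phenotype toward the strain's table; because the x1 candidate is always
scanned, dObj lies in [0, 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import objective
from .params import PARAM_NAMES, ModelParameters, make_variant
from .solvers import SolverConfig
from .steady_state import SugarGrid, default_grid
from .tables import StrainTable

__all__ = [
    "ScanConfig",
    "ScanResult",
    "ImprovementMatrix",
    "scan_multipliers",
    "scan_parameter",
    "improvement",
    "improvement_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """Scan geometry and simulation settings for parameter scans."""

    points: int = 48
    decades: float = 3.0          # half-width: 10^-decades .. 10^+decades
    grid: SugarGrid | None = None
    solver: SolverConfig = field(default_factory=SolverConfig)


def scan_multipliers(cfg: ScanConfig | None = None) -> np.ndarray:
    """The scan's multiplier ladder plus the x1 default, sorted ascending."""
    cfg = cfg or ScanConfig()
    base = np.logspace(-cfg.decades, cfg.decades, cfg.points)
    if not np.any(np.isclose(base, 1.0)):
        base = np.sort(np.append(base, 1.0))
    return base


@dataclass
class ScanResult:
    """Objective landscape of one parameter against one strain table."""

    parameter: str
    multipliers: np.ndarray
    objectives: np.ndarray          # np.nan where evaluation failed
    best_multiplier: float
    best_objective: float
    start_objective: float          # objective at the x1 candidate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "multiplier": self.multipliers,
            "objective": self.objectives,
        })


def scan_parameter(
    base_params: ModelParameters,
    table: StrainTable,
    name: str,
    cfg: ScanConfig | None = None,
) -> ScanResult:
    """Scan one parameter's multiplier ladder against one strain table.

    Ties on the objective are broken toward the multiplier closest to x1;
    failures at individual multipliers are logged and skipped.
    """
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown model parameter {name!r}")
    cfg = cfg or ScanConfig()
    grid = cfg.grid or default_grid()
    mults = scan_multipliers(cfg)
    objs = np.full(len(mults), np.nan)
    for k, m in enumerate(mults):
        try:
            p = make_variant(base_params, {name: float(m)}, table.knockouts)
            objs[k] = objective(p, table, grid, cfg.solver)
        except Exception as exc:
            logger.warning("scan point %s x %g failed: %s", name, m, exc)
    if np.all(np.isnan(objs)):
        raise RuntimeError(f"every scan point failed for {name}")
    # tie-break toward multiplier nearest 1 (log distance)
    order = sorted(
        (k for k in range(len(mults)) if not np.isnan(objs[k])),
        key=lambda k: (objs[k], abs(np.log10(mults[k]))),
    )
    kbest = order[0]
    k1 = int(np.argmin(np.abs(np.log10(mults))))
    return ScanResult(
        parameter=name,
        multipliers=mults,
        objectives=objs,
        best_multiplier=float(mults[kbest]),
        best_objective=float(objs[kbest]),
        start_objective=float(objs[k1]),
    )


def improvement(obj_start: float, obj_best: float) -> float:
    """(Obj_start - Obj_best) / Obj_start, in [0, 1).

    A perfect starting fit (Obj_start = 0) improves by 0 by convention.
    """
    if obj_start < 0 or obj_best < 0:
        raise ValueError("objectives must be non-negative")
    if obj_best > obj_start:
        raise ValueError("obj_best must be <= obj_start (x1 is a candidate)")
    if obj_start == 0:
        return 0.0
    return (obj_start - obj_best) / obj_start


@dataclass
class ImprovementMatrix:
    """Strain x parameter fitting-improvement matrix (Fig-4 style)."""

    delta_obj: pd.DataFrame          # rows strains, columns parameters
    best_multiplier: pd.DataFrame
    start_objective: pd.Series

    @property
    def shape(self) -> tuple[int, int]:
        return self.delta_obj.shape

    def row_argmax(self, strain_id: str) -> str:
        return str(self.delta_obj.loc[strain_id].astype(float).idxmax())


def improvement_matrix(
    base_params: ModelParameters,
    panel: list[StrainTable],
    param_names: tuple[str, ...] | None = None,
    cfg: ScanConfig | None = None,
    cache: dict | None = None,
) -> ImprovementMatrix:
    """Scan every (strain, parameter) pair and collect improvements.

    ``param_names`` defaults to all 45 model parameters.  ``cache`` (an
    optional mutable mapping) memoizes completed ScanResults keyed by
    (strain_id, parameter) so an interrupted sweep can be resumed; failed
    cells are recorded as missing (NaN) and do not abort the sweep.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    param_names = tuple(param_names or PARAM_NAMES)
    cfg = cfg or ScanConfig()
    strains = [t.strain_id for t in panel]
    dobj = pd.DataFrame(np.nan, index=strains, columns=list(param_names))
    bmult = pd.DataFrame(np.nan, index=strains, columns=list(param_names))
    starts = {}
    for table in panel:
        for name in param_names:
            key = (table.strain_id, name)
            if cache is not None and key in cache:
                res = cache[key]
            else:
                try:
                    res = scan_parameter(base_params, table, name, cfg)
                except Exception as exc:
                    logger.warning(
                        "improvement cell (%s, %s) failed: %s",
                        table.strain_id, name, exc,
                    )
                    continue
                if cache is not None:
                    cache[key] = res
            dobj.loc[table.strain_id, name] = improvement(
                res.start_objective, res.best_objective
            )
            bmult.loc[table.strain_id, name] = res.best_multiplier
            starts[table.strain_id] = res.start_objective
    return ImprovementMatrix(dobj, bmult, pd.Series(starts))
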