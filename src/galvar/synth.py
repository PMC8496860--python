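"""Synthetic strain tables with the statistical structure of FACS summaries.

Real induction data arrive as per-condition ON/OFF peak positions (means
of the GAL-induced and GAL-repressed subpopulations), normalized to each
strain's maximum, over a 96-condition sugar grid.  This module generates
such tables from ground-truth parameter sets: a variant strain is a
multiplicative modification (and/or knockout) of the base parameters, its
grid is simulated, Gaussian measurement noise is added on the normalized
scale (truncated at zero), and the table is re-normalized so the maximum
valid ON peak is 1.  Everything is deterministic under the spec's seed, so
any table can be regenerated bit-exactly from its spec.

Not modelled on purpose: full FACS histograms, cell-to-cell noise
mechanisms, and growth-rate differences between conditions (the
poor-growth cells are simply marked invalid).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters, make_variant, reference_parameters
from .solvers import SolverConfig
from .steady_state import SugarGrid, default_grid, simulate_grid
from .tables import StrainTable

__all__ = [
    "SyntheticStrainSpec",
    "generate_strain_table",
    "generate_panel",
    "default_panel_specs",
]


@dataclass(frozen=True)
class SyntheticStrainSpec:
    """Recipe for one synthetic strain table (fully reproducible)."""

    strain_id: str
    modifications: Mapping[str, float] = field(default_factory=dict)
    knockouts: tuple[str, ...] = ()
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(m <= 0 for m in self.modifications.values()):
            raise ValueError("modification multipliers must be > 0")
        object.__setattr__(self, "modifications", dict(self.modifications))

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "modifications": dict(self.modifications),
            "knockouts": list(self.knockouts),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticStrainSpec":
        return cls(
            strain_id=d["strain_id"],
            modifications=dict(d.get("modifications", {})),
            knockouts=tuple(d.get("knockouts", ())),
            noise_sd=float(d.get("noise_sd", 0.05)),
            seed=int(d["seed"]),
        )


def generate_strain_table(
    spec: SyntheticStrainSpec,
    base: ModelParameters | None = None,
    grid: SugarGrid | None = None,
    cfg: SolverConfig | None = None,
) -> StrainTable:
    """Simulate the variant strain and emit a noisy ON/OFF peak table.

    ON peaks get noise on ``normalized_high``, OFF peaks on
    ``normalized_low``; both are truncated at zero, ordered (ON >= OFF)
    and the table is re-normalized so the maximum valid ON peak is 1.
    Masked or non-convergent grid cells are emitted with ``valid=False``,
    mimicking missing-data cells in measured profiles.
    """
    base = base or reference_parameters()
    grid = grid or default_grid()
    cfg = cfg or SolverConfig()
    params = make_variant(base, spec.modifications, spec.knockouts)
    profile = simulate_grid(params, grid, cfg)
    if float(np.where(profile.mask, 0.0, profile.high_levels).max()) <= 0.0:
        raise ValueError(
            f"strain {spec.strain_id!r} has an all-zero induction profile; "
            "check its parameter modifications/knockouts"
        )
    rng = np.random.default_rng(spec.seed)
    shape = profile.normalized_high.shape
    on = profile.normalized_high + rng.normal(0.0, spec.noise_sd, shape)
    off = profile.normalized_low + rng.normal(0.0, spec.noise_sd, shape)
    on = np.maximum(on, 0.0)
    off = np.maximum(off, 0.0)
    off = np.minimum(off, on)          # peak ordering survives the noise
    valid = ~profile.mask
    peak = float(np.where(valid, on, 0.0).max())
    if peak > 0:
        on = on / peak
        off = off / peak
    rows = []
    for i, g in enumerate(grid.glucose_levels):
        for j, ga in enumerate(grid.galactose_levels):
            rows.append({
                "glucose": g, "galactose": ga,
                "on_peak": on[i, j], "off_peak": off[i, j],
                "valid": bool(valid[i, j]),
            })
    return StrainTable(spec.strain_id, pd.DataFrame(rows), spec.knockouts)


def default_panel_specs(
    noise_sd: float = 0.05, seed: int = 1000
) -> list[SyntheticStrainSpec]:
    """The packaged six-strain panel.

    Base strain, the two deletion mutants used to constrain the fit
    (mig1, gal80), and three variants tuning the mechanisms that dominate
    natural bimodal-range variation: the hexose-transporter sugar
    preference (rHXT / 10), the Gal3*-Gal80 binding rate (kf83 x 10) and
    the Gal3p-galactose binding rate (kf3 x 10).
    """
    mk = SyntheticStrainSpec
    return [
        mk("base", {}, (), noise_sd, seed + 1),
        mk("mig1_del", {}, ("MIG1",), noise_sd, seed + 2),
        mk("gal80_del", {}, ("GAL80",), noise_sd, seed + 3),
        mk("rHXT_down", {"rHXT": 0.1}, (), noise_sd, seed + 4),
        mk("kf83_up", {"kf83": 10.0}, (), noise_sd, seed + 5),
        mk("kf3_up", {"kf3": 10.0}, (), noise_sd, seed + 6),
    ]


def generate_panel(
    base: ModelParameters | None = None,
    menu: Sequence[SyntheticStrainSpec] | None = None,
    grid: SugarGrid | None = None,
    cfg: SolverConfig | None = None,
) -> list[StrainTable]:
    """Generate one table per spec (default: the packaged 6-strain panel)."""
    menu = list(menu) if menu is not None else default_panel_specs()
    if not menu:
        raise ValueError("menu must be non-empty")
    return [generate_strain_table(s, base, grid, cfg) for s in menu]
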