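"""Induction profiles over sugar grids: steady states, modality, fronts.

For every (glucose, galactose) condition the network is relaxed to steady
state twice, from a shared pair of pre-equilibrated initial states:

* OFF init: steady state at zero glucose, zero galactose;
* ON init: steady state at zero glucose and saturating galactose
  (``on_init_gal``, default 2% w/v).

Where the two relaxations settle on different attractors the condition is
bistable, modelling the coexisting GAL-induced and GAL-repressed
subpopulations seen in flow-cytometry histograms (bimodality).  A
condition is called bimodal when the high steady-state Gal1p level is at
least ``fold_threshold`` (default 5) times the low level; otherwise it is
unimodal ON or OFF according to whether the high level clears half the
profile maximum.

An alternative titration mode seeds each galactose step of a row with the
previous step's steady state (both sweep directions), tracing the two
branches by continuation; on the reference parameters it yields the same
bimodal set as the dual-init protocol.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParameters, SugarCondition
from .network import N_STATE
from .solvers import SolverConfig, equilibrate

__all__ = [
    "SugarGrid",
    "default_grid",
    "SteadyStatePair",
    "InductionProfile",
    "DecisionFront",
    "on_off_inits",
    "classify_modality",
    "simulate_grid",
    "decision_front",
    "induction_ratio",
    "UndefinedRatioError",
]

logger = logging.getLogger(__name__)

UNIMODAL_OFF = "unimodal_OFF"
UNIMODAL_ON = "unimodal_ON"
BIMODAL = "bimodal"


class UndefinedRatioError(ValueError):
    """Decision front has too few crossings to define an induction ratio."""


@dataclass(frozen=True)
class SugarGrid:
    """Ordered glucose x galactose concentration levels (% w/v).

    Levels are stored strictly decreasing with any zero level moved to the
    end, matching the display convention of putting the no-sugar row/column
    at the axis origin.
    """

    glucose_levels: tuple[float, ...]
    galactose_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        for levels in (self.glucose_levels, self.galactose_levels):
            nz = [x for x in levels if x > 0]
            if any(x < 0 for x in levels):
                raise ValueError("negative concentration in grid")
            if list(levels) != sorted(nz, reverse=True) + [0.0] * (
                len(levels) - len(nz)
            ):
                raise ValueError(
                    "grid levels must be strictly decreasing, zero last"
                )
            if len(set(levels)) != len(levels):
                raise ValueError("duplicate grid levels")

    @property
    def n_conditions(self) -> int:
        return len(self.glucose_levels) * len(self.galactose_levels)

    def conditions(self):
        for g in self.glucose_levels:
            for ga in self.galactose_levels:
                yield SugarCondition(g, ga)

    def galactose_ladder(self) -> tuple[float, ...]:
        """Nonzero galactose levels, ascending (titration order)."""
        return tuple(sorted(x for x in self.galactose_levels if x > 0))


def default_grid() -> SugarGrid:
    """The experimental 96-condition grid.

    Glucose: twofold ladder 1% -> 0.015625% (7 levels) plus zero; galactose:
    twofold ladder 4% -> 0.00390625% (11 levels) plus zero.  Exact unrounded
    ladder values are stored; display labels round them (0.031, 0.004, ...).
    """
    glucose = tuple(1.0 * 2.0 ** -k for k in range(7)) + (0.0,)
    galactose = tuple(4.0 * 2.0 ** -k for k in range(11)) + (0.0,)
    return SugarGrid(glucose, galactose)


@dataclass(frozen=True)
class SteadyStatePair:
    """High/low Gal1p steady states of one condition and their modality."""

    g1_high: float
    g1_low: float
    converged_high: bool
    converged_low: bool
    modality: str


@dataclass
class InductionProfile:
    """Per-condition steady-state Gal1p levels over a grid.

    Arrays are indexed ``[i_glucose, j_galactose]`` following the grid's
    level order.  ``normalized_*`` are levels divided by the maximum
    unmasked high level (the strain's own maximum, mirroring per-strain
    normalization of measured profiles).
    """

    grid: SugarGrid
    high_levels: np.ndarray
    low_levels: np.ndarray
    normalized_high: np.ndarray
    normalized_low: np.ndarray
    modality: np.ndarray          # dtype=object, strings
    mask: np.ndarray              # True = excluded (poor growth / no convergence)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.grid.glucose_levels):
            for j, ga in enumerate(self.grid.galactose_levels):
                rows.append({
                    "glucose": g, "galactose": ga,
                    "g1_high": self.high_levels[i, j],
                    "g1_low": self.low_levels[i, j],
                    "normalized_high": self.normalized_high[i, j],
                    "normalized_low": self.normalized_low[i, j],
                    "modality": self.modality[i, j],
                    "masked": bool(self.mask[i, j]),
                })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DecisionFront:
    """Half-maximum induction crossings, one per glucose row where defined."""

    crossings: tuple[tuple[float, float], ...]   # (glucose, galactose)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.crossings), columns=["glucose", "galactose_crossing"]
        )


def on_off_inits(
    params: ModelParameters, cfg: SolverConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Shared (ON, OFF) initial states for grid simulation.

    OFF: equilibrated at zero sugar from the zero state.  ON: equilibrated
    at zero glucose, ``cfg.on_init_gal`` galactose (saturating by default).
    """
    cfg = cfg or SolverConfig()
    off_state, conv_off = equilibrate(
        params, SugarCondition(0.0, 0.0), np.zeros(N_STATE), cfg
    )
    on_state, conv_on = equilibrate(
        params, SugarCondition(0.0, cfg.on_init_gal), np.zeros(N_STATE), cfg
    )
    if not (conv_off and conv_on):
        raise RuntimeError("pre-equilibration of ON/OFF inits did not converge")
    return on_state, off_state


def classify_modality(
    g1_high: float,
    g1_low: float,
    profile_half_max: float,
    fold_threshold: float = 5.0,
    low_floor: float = 1e-9,
) -> str:
    """Classify one condition as bimodal / unimodal ON / unimodal OFF.

    Bimodal iff ``g1_high >= fold_threshold * max(g1_low, low_floor)`` (the
    fold rule is inclusive; the floor makes a true-zero OFF state with any
    induced ON state count as bimodal).  Otherwise unimodal ON when the
    high level clears the profile half-maximum, else unimodal OFF.
    """
    if g1_high < g1_low:
        raise ValueError("g1_high must be >= g1_low")
    if profile_half_max <= 0:
        raise ValueError("profile_half_max must be > 0")
    if g1_high >= fold_threshold * max(g1_low, low_floor):
        return BIMODAL
    return UNIMODAL_ON if g1_high >= profile_half_max else UNIMODAL_OFF


def _default_mask(grid: SugarGrid, n_cells: int) -> np.ndarray:
    """Poor-growth mask: the n lowest-galactose cells of the zero-glucose row."""
    mask = np.zeros((len(grid.glucose_levels), len(grid.galactose_levels)), bool)
    if n_cells <= 0:
        return mask
    zero_rows = [i for i, g in enumerate(grid.glucose_levels) if g == 0.0]
    if not zero_rows:
        return mask
    i0 = zero_rows[0]
    order = np.argsort(grid.galactose_levels)  # ascending galactose
    for j in order[:n_cells]:
        mask[i0, j] = True
    return mask


def simulate_grid(
    params: ModelParameters,
    grid: SugarGrid | None = None,
    cfg: SolverConfig | None = None,
    mode: str = "dual_init",
    mask: np.ndarray | None = None,
) -> InductionProfile:
    """Compute the induction profile of ``params`` over ``grid``.

    ``mode="dual_init"`` relaxes every condition from the shared ON/OFF
    initial states; ``mode="titration"`` sweeps each glucose row along the
    galactose ladder in both directions, seeding each step with the
    previous steady state (continuation).  Non-convergent conditions are
    masked and logged, never fatal.
    """
    grid = grid or default_grid()
    cfg = cfg or SolverConfig()
    ng, na = len(grid.glucose_levels), len(grid.galactose_levels)
    high = np.zeros((ng, na))
    low = np.zeros((ng, na))
    conv = np.ones((ng, na), bool)

    if mode == "dual_init":
        on0, off0 = on_off_inits(params, cfg)
        for i, g in enumerate(grid.glucose_levels):
            for j, ga in enumerate(grid.galactose_levels):
                c = SugarCondition(g, ga)
                yh, ch = equilibrate(params, c, on0, cfg)
                yl, cl = equilibrate(params, c, off0, cfg)
                hi, lo = yh[0], yl[0]
                if hi < lo:
                    hi, lo = lo, hi
                high[i, j], low[i, j] = hi, lo
                conv[i, j] = ch and cl
    elif mode == "titration":
        jorder_up = list(np.argsort(grid.galactose_levels))      # ascending
        for i, g in enumerate(grid.glucose_levels):
            # upward sweep from the zero-galactose steady state (low branch)
            y, c0 = equilibrate(params, SugarCondition(g, 0.0),
                                np.zeros(N_STATE), cfg)
            up = {}
            for j in jorder_up:
                y, cj = equilibrate(
                    params, SugarCondition(g, grid.galactose_levels[j]), y, cfg
                )
                up[j] = (y.copy(), cj)
            # downward sweep from saturating galactose (high branch)
            top = max(grid.galactose_levels)
            y, c1 = equilibrate(params, SugarCondition(g, top),
                                np.zeros(N_STATE), cfg)
            for j in reversed(jorder_up):
                y, cj = equilibrate(
                    params, SugarCondition(g, grid.galactose_levels[j]), y, cfg
                )
                yu, cu = up[j]
                hi, lo = y[0], yu[0]
                if hi < lo:
                    hi, lo = lo, hi
                high[i, j], low[i, j] = hi, lo
                conv[i, j] = cj and cu
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if mask is None:
        mask = _default_mask(grid, cfg.mask_zero_glucose_cells)
    mask = mask | ~conv
    n_fail = int((~conv).sum())
    if n_fail:
        logger.warning("%d conditions did not converge; masked", n_fail)

    unmasked_high = np.where(mask, 0.0, high)
    hmax = float(unmasked_high.max())
    if hmax <= 0.0:
        logger.warning(
            "all-zero induction profile; returning unnormalized zeros "
            "(check parameters, e.g. GAL1 knockout)"
        )
        norm_high = np.zeros_like(high)
        norm_low = np.zeros_like(low)
        half = 1.0   # degenerate; everything classifies unimodal OFF
    else:
        norm_high = high / hmax
        norm_low = low / hmax
        half = 0.5 * hmax

    modality = np.empty((ng, na), dtype=object)
    for i in range(ng):
        for j in range(na):
            modality[i, j] = classify_modality(
                high[i, j], low[i, j], half,
                cfg.fold_threshold, cfg.low_floor,
            )

    return InductionProfile(
        grid=grid, high_levels=high, low_levels=low,
        normalized_high=norm_high, normalized_low=norm_low,
        modality=modality, mask=mask,
    )


def decision_front(profile: InductionProfile) -> DecisionFront:
    """Half-maximum contour of the normalized high level.

    For each glucose row, the crossing ``normalized_high = 0.5`` is located
    between adjacent galactose ladder points and interpolated linearly in
    log concentration.  Rows that never span 0.5 contribute no crossing.
    """
    crossings = []
    gal = np.asarray(profile.grid.galactose_levels)
    order = np.argsort(gal)          # ascending galactose
    for i, g in enumerate(profile.grid.glucose_levels):
        vals = profile.normalized_high[i, :]
        msk = profile.mask[i, :]
        js = [j for j in order if gal[j] > 0 and not msk[j]]
        found = None
        for a, b in zip(js[:-1], js[1:]):
            v0, v1 = vals[a], vals[b]
            if v0 < 0.5 <= v1:
                t = (0.5 - v0) / (v1 - v0)
                found = float(np.exp(
                    np.log(gal[a]) + t * (np.log(gal[b]) - np.log(gal[a]))
                ))
                break
        if found is not None:
            crossings.append((float(g), found))
    return DecisionFront(tuple(crossings))


def induction_ratio(front: DecisionFront) -> tuple[float, float]:
    """Glucose/galactose concentration ratio along the decision front.

    Returns ``(snapped, raw)`` where ``raw`` is the median over rows of
    glucose / interpolated galactose crossing and ``snapped`` is the
    nearest power of two (the reporting convention for strain induction
    ratios).  Requires at least two crossings.
    """
    if len(front.crossings) < 2:
        raise UndefinedRatioError(
            "need >= 2 decision-front crossings to define an induction ratio"
        )
    ratios = [g / ga for g, ga in front.crossings if g > 0]
    if len(ratios) < 2:
        raise UndefinedRatioError("not enough nonzero-glucose crossings")
    raw = float(np.median(ratios))
    snapped = float(2.0 ** round(np.log2(raw)))
    return snapped, raw
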