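"""Calibration of model parameters against strain induction tables.

The score is the summed squared deviation, over valid conditions, between
the measured ON/OFF peak positions and the simulated normalized high/low
steady-state Gal1p levels:

    Obj(beta) = sum_i (y_i_high - f(x_i_high, beta))^2
              + sum_i (y_i_low  - f(x_i_low,  beta))^2

Fitting maximizes the posterior log P(beta | data) = -Obj/sigma^2 +
log P(beta) by Metropolis-Hastings random walk in log10-parameter space
(Gaussian likelihood on the stacked residuals, log-normal priors).
Sampling in log space keeps every parameter positive and treats
order-of-magnitude moves symmetrically.

Several strains can be fitted simultaneously with one shared parameter
vector; per-strain knockouts (structural zeros) and overrides are applied
on top of the shared vector before each strain is scored, mirroring the
use of identical parameters for wild type and deletion mutants apart from
the deleted synthesis rates.

The statsmodels-style front end is :class:`GalPathwayModel`, whose
``fit()`` returns a :class:`GalPathwayResults` with the chain, the best
parameters and a ``summary()`` table.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import (
    FREE_PARAMETERS,
    ModelParameters,
    apply_knockout,
    make_variant,
    reference_parameters,
)
from .solvers import SolverConfig
from .steady_state import SugarGrid, default_grid, simulate_grid
from .tables import StrainTable

__all__ = [
    "FitConfig",
    "Chain",
    "objective",
    "multi_strain_objective",
    "log_prior",
    "log_posterior",
    "mh_sample",
    "fit_strains",
    "GalPathwayModel",
    "GalPathwayResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Settings for posterior evaluation and Metropolis-Hastings sampling.

    ``priors`` maps parameter names to (center, sd_decades) of a log-normal
    prior; unspecified free parameters default to a prior centered on the
    packaged reference value with a 1-decade spread.  ``sigma`` is the
    Gaussian likelihood scale on the normalized induction axis (residuals
    live in [0, 1]).
    """

    free: tuple[str, ...] = FREE_PARAMETERS
    priors: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    sigma: float = 0.1
    step_decades: float = 0.05
    n_steps: int = 2000
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        extra = set(self.free) - set(FREE_PARAMETERS)
        if extra:
            logger.warning(
                "free list includes non-default parameters: %s", sorted(extra)
            )

    def prior_for(self, name: str) -> tuple[float, float]:
        if name in self.priors:
            return self.priors[name]
        return (reference_parameters()[name], 1.0)


@dataclass
class Chain:
    """A Metropolis-Hastings trace in log10-parameter space."""

    free: tuple[str, ...]
    samples: np.ndarray            # (n_steps + 1, n_free), log10 values
    log_posterior: np.ndarray      # (n_steps + 1,)
    accepted: np.ndarray           # (n_steps,), bool
    objective_trace: np.ndarray    # (n_steps + 1,)
    best_params: ModelParameters
    best_objective: float

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean()) if len(self.accepted) else 0.0

    def best_so_far(self) -> np.ndarray:
        return np.minimum.accumulate(self.objective_trace)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=[f"log10_{n}" for n in self.free])
        df.insert(0, "log_posterior", self.log_posterior)
        df.insert(1, "objective", self.objective_trace)
        acc = np.concatenate([[True], self.accepted])
        df.insert(2, "accepted", acc)
        df.insert(0, "step", np.arange(len(df)))
        return df


# ----------------------------------------------------------- objectives --

def objective(
    params: ModelParameters,
    table: StrainTable,
    grid: SugarGrid | None = None,
    cfg: SolverConfig | None = None,
) -> float:
    """Eq-1-style summed squared residual of one strain table."""
    grid = grid or default_grid()
    cfg = cfg or SolverConfig()
    table = table.align_to_grid(grid)
    profile = simulate_grid(params, grid, cfg)
    gi = {g: i for i, g in enumerate(grid.glucose_levels)}
    gj = {g: j for j, g in enumerate(grid.galactose_levels)}
    total = 0.0
    n_used = 0
    for row in table.data.itertuples(index=False):
        if not row.valid:
            continue
        i, j = gi[row.glucose], gj[row.galactose]
        if profile.mask[i, j]:
            continue
        total += (row.on_peak - profile.normalized_high[i, j]) ** 2
        total += (row.off_peak - profile.normalized_low[i, j]) ** 2
        n_used += 1
    if n_used == 0:
        raise ValueError("no valid conditions to score")
    return float(total)


def multi_strain_objective(
    shared_params: ModelParameters,
    strain_specs: Sequence[tuple[StrainTable, Sequence[str], Mapping[str, float]]],
    grid: SugarGrid | None = None,
    cfg: SolverConfig | None = None,
) -> tuple[float, dict[str, float]]:
    """Total and per-strain objective with shared parameters.

    Each spec is ``(table, knockouts, overrides)``; the strain is scored
    with the shared vector after applying its multiplicative overrides and
    structural knockouts.
    """
    if not strain_specs:
        raise ValueError("strain_specs must be non-empty")
    per: dict[str, float] = {}
    total = 0.0
    for table, knockouts, overrides in strain_specs:
        p = make_variant(shared_params, overrides, knockouts)
        obj = objective(p, table, grid, cfg)
        per[table.strain_id] = obj
        total += obj
    return float(total), per


# ------------------------------------------------------------ posterior --

def log_prior(params: ModelParameters, cfg: FitConfig) -> float:
    """Sum of log-normal prior log densities over the free parameters."""
    total = 0.0
    for name in cfg.free:
        v = params[name]
        if v <= 0:
            return -math.inf
        center, sd = cfg.prior_for(name)
        z = (math.log10(v) - math.log10(center)) / sd
        total += -0.5 * z * z - math.log(sd * math.sqrt(2 * math.pi))
    return total


def log_posterior(
    params: ModelParameters,
    strain_specs: Sequence[tuple[StrainTable, Sequence[str], Mapping[str, float]]],
    cfg: FitConfig,
    grid: SugarGrid | None = None,
    solver_cfg: SolverConfig | None = None,
) -> tuple[float, float]:
    """Log posterior (up to a constant) and the objective it contains.

    With no tables the score is prior-only (objective 0).  A non-positive
    free parameter yields -inf (rejected state).
    """
    lp = log_prior(params, cfg)
    if not math.isfinite(lp):
        return -math.inf, math.inf
    if not strain_specs:
        return lp, 0.0
    obj, _ = multi_strain_objective(params, strain_specs, grid, solver_cfg)
    return lp - obj / cfg.sigma ** 2, obj


# -------------------------------------------------------------- sampler --

def mh_sample(
    log_posterior_fn: Callable[[ModelParameters], tuple[float, float] | float],
    init_params: ModelParameters,
    cfg: FitConfig,
) -> Chain:
    """Metropolis-Hastings random walk over ``cfg.free`` in log10 space.

    Symmetric Gaussian proposals (per-parameter sd ``cfg.step_decades``),
    acceptance probability min(1, exp(delta log posterior)).  The trace is
    fully determined by ``cfg.seed``.  ``log_posterior_fn`` may return a
    bare log posterior or a ``(log_posterior, objective)`` pair; in the
    first case the negated log posterior stands in as the objective for
    best-so-far tracking.
    """
    if cfg.n_steps < 1:
        raise ValueError("chain length must be >= 1")
    free = tuple(cfg.free)
    if not free:
        raise ValueError("free parameter list is empty")

    def evaluate(p: ModelParameters) -> tuple[float, float]:
        out = log_posterior_fn(p)
        if isinstance(out, tuple):
            return float(out[0]), float(out[1])
        return float(out), -float(out)

    rng = np.random.default_rng(cfg.seed)
    x = np.array([math.log10(init_params[n]) for n in free])
    lp, obj = evaluate(init_params)
    if not math.isfinite(lp):
        raise ValueError("initial parameters have non-finite log posterior")

    n = cfg.n_steps
    samples = np.empty((n + 1, len(free)))
    lps = np.empty(n + 1)
    objs = np.empty(n + 1)
    accepted = np.zeros(n, dtype=bool)
    samples[0], lps[0], objs[0] = x, lp, obj
    best_obj, best_x = obj, x.copy()

    current = init_params
    for t in range(n):
        prop_x = x + rng.normal(0.0, cfg.step_decades, size=len(free))
        prop = current.replace(**{k: 10.0 ** v for k, v in zip(free, prop_x)})
        plp, pobj = evaluate(prop)
        if math.log(rng.uniform()) < plp - lp:
            x, lp, obj, current = prop_x, plp, pobj, prop
            accepted[t] = True
            if obj < best_obj:   # ties keep the earlier state
                best_obj, best_x = obj, x.copy()
        samples[t + 1], lps[t + 1], objs[t + 1] = x, lp, obj

    rate = float(accepted.mean())
    if not 0.05 < rate < 0.8:
        logger.warning(
            "MH acceptance rate %.3f outside (0.05, 0.8); "
            "consider adjusting step_decades", rate
        )
    best_params = init_params.replace(
        **{k: 10.0 ** v for k, v in zip(free, best_x)}
    )
    return Chain(
        free=free, samples=samples, log_posterior=lps, accepted=accepted,
        objective_trace=objs, best_params=best_params, best_objective=best_obj,
    )


def fit_strains(
    panel: Sequence[tuple[StrainTable, Sequence[str], Mapping[str, float]]],
    init_params: ModelParameters,
    cfg: FitConfig,
    grid: SugarGrid | None = None,
    solver_cfg: SolverConfig | None = None,
) -> tuple[ModelParameters, dict[str, float], Chain | None]:
    """Fit the shared parameter vector to a strain panel by MH sampling.

    Free parameters that are structurally zero in every panel member (all
    strains carry the corresponding knockout) are dropped from the free
    list.  An empty free list evaluates the objective once and returns the
    initial parameters unchanged.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    dead: set[str] = set()
    for name in cfg.free:
        if all(
            make_variant(init_params, ov, ko)[name] == 0.0
            for _, ko, ov in panel
        ):
            dead.add(name)
    free = tuple(n for n in cfg.free if n not in dead)
    if dead:
        logger.info("dropping structurally zero free parameters: %s",
                    sorted(dead))
    if not free:
        total, per = multi_strain_objective(init_params, panel, grid, solver_cfg)
        return init_params, per, None

    run_cfg = FitConfig(
        free=free, priors=dict(cfg.priors), sigma=cfg.sigma,
        step_decades=cfg.step_decades, n_steps=cfg.n_steps,
        burn_in=cfg.burn_in, seed=cfg.seed,
    )

    def score(p: ModelParameters) -> tuple[float, float]:
        return log_posterior(p, panel, run_cfg, grid, solver_cfg)

    chain = mh_sample(score, init_params, run_cfg)
    best = chain.best_params
    _, per = multi_strain_objective(best, panel, grid, solver_cfg)
    return best, per, chain


# ------------------------------------------------- model/results facade --

class GalPathwayModel:
    """GAL induction model bound to a panel of strain tables.

    Parameters
    ----------
    panel : sequence of (StrainTable, knockouts, overrides) or StrainTable
        Strains to fit simultaneously; bare tables are wrapped with their
        own recorded knockouts and no overrides.
    grid, solver_cfg : optional
        Sugar grid and steady-state solver settings.
    """

    def __init__(self, panel, grid=None, solver_cfg=None):
        specs = []
        for entry in panel:
            if isinstance(entry, StrainTable):
                specs.append((entry, tuple(entry.knockouts), {}))
            else:
                table, knockouts, overrides = entry
                specs.append((table, tuple(knockouts), dict(overrides)))
        if not specs:
            raise ValueError("panel must be non-empty")
        self.panel = specs
        self.grid = grid or default_grid()
        self.solver_cfg = solver_cfg or SolverConfig()

    @classmethod
    def from_tables(cls, tables: Sequence[StrainTable], **kw) -> "GalPathwayModel":
        return cls(list(tables), **kw)

    def loglike(self, params: ModelParameters, sigma: float = 0.1) -> float:
        obj, _ = multi_strain_objective(
            params, self.panel, self.grid, self.solver_cfg
        )
        return -obj / sigma ** 2

    def fit(
        self,
        start_params: ModelParameters | None = None,
        config: FitConfig | None = None,
    ) -> "GalPathwayResults":
        start = start_params or reference_parameters()
        cfg = config or FitConfig()
        best, per, chain = fit_strains(
            self.panel, start, cfg, self.grid, self.solver_cfg
        )
        return GalPathwayResults(self, best, per, chain, cfg, start)


@dataclass
class GalPathwayResults:
    """Fit results: best shared parameters, per-strain scores, the chain."""

    model: GalPathwayModel
    params: ModelParameters
    per_strain_objective: dict[str, float]
    chain: Chain | None
    config: FitConfig
    start_params: ModelParameters

    @property
    def objective(self) -> float:
        return float(sum(self.per_strain_objective.values()))

    def summary(self) -> str:
        lines = ["GAL pathway calibration", "=" * 47]
        lines.append(f"{'strains':<24}{len(self.model.panel):>23}")
        lines.append(f"{'total objective':<24}{self.objective:>23.6g}")
        for sid, obj in self.per_strain_objective.items():
            lines.append(f"  Obj[{sid:<16}]{obj:>24.6g}")
        if self.chain is not None:
            lines.append(
                f"{'chain steps':<24}{len(self.chain.accepted):>23}"
            )
            lines.append(
                f"{'acceptance rate':<24}{self.chain.acceptance_rate:>23.3f}"
            )
        lines.append("-" * 47)
        lines.append(f"{'parameter':<10}{'start':>12}{'fitted':>12}{'x-fold':>12}")
        for name in (self.chain.free if self.chain else ()):
            s, b = self.start_params[name], self.params[name]
            lines.append(f"{name:<10}{s:>12.5g}{b:>12.5g}{b / s:>12.3g}")
        return "\n".join(lines)
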