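"""Kinetic parameterization of the GAL regulatory-network model.

The model has 45 named kinetic constants.  The 36 non-Hill parameters are
the "free" set used by fitting and by the perturbation survey; the 9 Hill
coefficients are structural and never varied, to preserve the basic shape
of the control system.

Gene knockouts are represented structurally: the synthesis rate(s) of the
deleted gene product are set to zero and the knockout is recorded on the
parameter object, so that zero values can be told apart from invalid input.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "HILL_NAMES",
    "FREE_PARAMETERS",
    "KNOCKOUT_GENES",
    "STATE_NAMES",
    "ModelParameters",
    "SugarCondition",
    "reference_parameters",
    "apply_knockout",
    "make_variant",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """Raised for unknown parameter keys or non-positive values."""


# --- naming ---------------------------------------------------------------

SYNTHESIS_NAMES = (
    "a1", "ag1", "a2", "ag2", "a3", "ag3", "a80", "ag80",
    "a4", "ag4", "a0HXT", "aHXT", "aR",
)
ACTIVATION_K_NAMES = ("KG1", "KG2", "KG3", "KG80", "KHXT")
REPRESSION_K_NAMES = ("KR1", "KR3", "KR4", "KRs")
BINDING_NAMES = ("kf3", "kr3", "kf83", "kr83", "kf84", "kr84")
TRANSPORT_NAMES = ("kG2", "rG2", "KGgluc", "rcat", "rHXT", "KHXTgluc")
TURNOVER_NAMES = ("d", "dsugar")
HILL_NAMES = ("n1", "n2", "n3", "n80", "nHXT", "nR1", "nR3", "nR4", "nRs")

#: All 45 parameter names, in canonical order.
PARAM_NAMES: tuple[str, ...] = (
    SYNTHESIS_NAMES + ACTIVATION_K_NAMES + REPRESSION_K_NAMES
    + BINDING_NAMES + TRANSPORT_NAMES + TURNOVER_NAMES + HILL_NAMES
)

#: The 36 parameters treated as free in fits and surveys (everything but
#: the Hill coefficients).
FREE_PARAMETERS: tuple[str, ...] = tuple(
    n for n in PARAM_NAMES if n not in HILL_NAMES
)

#: Synthesis parameters zeroed by each supported gene deletion.
KNOCKOUT_GENES: dict[str, tuple[str, ...]] = {
    "MIG1": ("aR",),
    "GAL80": ("a80", "ag80"),
    "GAL3": ("a3", "ag3"),
    "GAL2": ("a2", "ag2"),
    "GAL1": ("a1", "ag1"),
}

#: The 12 dynamic species, in state-vector order.  The glucose-bound active
#: repressor Rs is algebraic (a function of Rtot and gluc_in) and is never
#: part of the state.
STATE_NAMES = (
    "G1", "G2", "G3", "G3star", "G80", "G4",
    "C83", "C84", "HXT", "Rtot", "gluc_in", "gal_in",
)

assert len(PARAM_NAMES) == 45
assert len(FREE_PARAMETERS) == 36


# --- packaged reference values -------------------------------------------
#
# Synthetic reference set.  The published best-fit table for this model is
# not machine-readable, so these defaults are literature-scale placeholder
# values constructed and verified in-package: on the default sugar grid
# they produce unimodal-OFF, bimodal and unimodal-ON regions, a straight
# log-log decision front, a galactose-insensitive gal80-deletion and an
# elevated mig1-deletion.  Units: abundances and thresholds in arbitrary
# model units, rates per unit model time, external sugars in % w/v.
_REFERENCE_VALUES: dict[str, float] = {
    # synthesis (basal / Gal4p-activated maximum)
    "a1": 0.01, "ag1": 1.0,
    "a2": 0.004, "ag2": 0.3,
    "a3": 0.45, "ag3": 1.5,
    "a80": 0.48, "ag80": 0.15,
    "a4": 0.22, "ag4": 0.10,
    "a0HXT": 0.2, "aHXT": 0.8,
    "aR": 1.0,
    # Gal4p activation thresholds
    "KG1": 0.03, "KG2": 0.03, "KG3": 0.03, "KG80": 0.03, "KHXT": 0.1,
    # repressor (Rs) thresholds
    "KR1": 5.0, "KR3": 1.0, "KR4": 0.3, "KRs": 0.0015,
    # binding / unbinding
    "kf3": 100.0, "kr3": 3.0,
    "kf83": 1000.0, "kr83": 1.0,
    "kf84": 1000.0, "kr84": 1.0,
    # transport
    "kG2": 40.0, "rG2": 1.0, "KGgluc": 0.005,
    "rcat": 0.055, "rHXT": 10.0, "KHXTgluc": 0.1,
    # turnover
    "d": 1.0, "dsugar": 20.0,
    # Hill coefficients (structural, not free)
    "n1": 3.0, "n2": 3.0, "n3": 2.0, "n80": 2.0, "nHXT": 2.0,
    "nR1": 2.0, "nR3": 2.0, "nR4": 2.0, "nRs": 2.0,
}


@dataclass(frozen=True)
class SugarCondition:
    """External sugar environment (% w/v), held constant during a run."""

    glucose_ext: float
    galactose_ext: float

    def __post_init__(self) -> None:
        if self.glucose_ext < 0 or self.galactose_ext < 0:
            raise ValueError("sugar concentrations must be non-negative")


@dataclass(frozen=True)
class ModelParameters:
    """Immutable set of the 45 kinetic constants plus knockout flags.

    ``values`` maps every parameter name to a float; ``knockouts`` records
    the gene deletions that have been applied (whose synthesis rates are
    therefore legitimately zero).
    """

    values: Mapping[str, float]
    knockouts: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter keys: {sorted(unknown)}"
            )
        missing = set(PARAM_NAMES) - set(self.values)
        if missing:
            raise InvalidParameterError(
                f"missing parameter keys: {sorted(missing)}"
            )
        zeroed = set()
        for gene in self.knockouts:
            if gene not in KNOCKOUT_GENES:
                raise InvalidParameterError(
                    f"unsupported knockout {gene!r}; supported genes: "
                    f"{sorted(KNOCKOUT_GENES)}"
                )
            zeroed.update(KNOCKOUT_GENES[gene])
        for name, v in self.values.items():
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} is not finite")
            if name in zeroed:
                if v < 0:
                    raise InvalidParameterError(f"{name} must be >= 0")
            elif v <= 0:
                raise InvalidParameterError(
                    f"{name} must be > 0 (got {v!r}); use a knockout for "
                    "structural zeros"
                )
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_vector(self) -> np.ndarray:
        """The 45 values in canonical ``PARAM_NAMES`` order."""
        return np.array([self.values[n] for n in PARAM_NAMES], dtype=float)

    def replace(self, **changes: float) -> "ModelParameters":
        unknown = set(changes) - set(PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter keys: {sorted(unknown)}"
            )
        vals = dict(self.values)
        vals.update(changes)
        return ModelParameters(vals, self.knockouts)

    def to_dict(self) -> dict:
        out: dict = {n: self.values[n] for n in PARAM_NAMES}
        if self.knockouts:
            out["knockouts"] = sorted(self.knockouts)
        return out


def reference_parameters() -> ModelParameters:
    """The packaged reference ('wild-type-like') parameter set.

    See the module docstring for its provenance: a documented synthetic
    placeholder set exhibiting all three modality classes on the default
    grid.
    """
    return ModelParameters(dict(_REFERENCE_VALUES))


def apply_knockout(params: ModelParameters, gene: str) -> ModelParameters:
    """Return a copy with ``gene``'s synthesis rates set to zero.

    Supported genes: MIG1 (aR=0), GAL80 (a80=ag80=0), GAL3 (a3=ag3=0),
    GAL2 (a2=ag2=0), GAL1 (a1=ag1=0).  Idempotent.
    """
    if gene not in KNOCKOUT_GENES:
        raise InvalidParameterError(
            f"unsupported gene {gene!r}; supported genes: "
            f"{sorted(KNOCKOUT_GENES)}"
        )
    vals = dict(params.values)
    for name in KNOCKOUT_GENES[gene]:
        vals[name] = 0.0
    return ModelParameters(vals, params.knockouts | {gene})


def make_variant(
    base: ModelParameters,
    modifications: Mapping[str, float] | None = None,
    knockouts: Iterable[str] = (),
) -> ModelParameters:
    """Multiplicatively perturb parameters, then apply knockouts.

    ``modifications`` maps parameter names to positive multipliers.  A zero
    multiplier is rejected: structural zeros must go through knockouts so
    they stay distinguishable from invalid input.
    """
    modifications = dict(modifications or {})
    unknown = set(modifications) - set(PARAM_NAMES)
    if unknown:
        raise InvalidParameterError(
            f"unknown parameter keys: {sorted(unknown)}"
        )
    for name, m in modifications.items():
        if m <= 0:
            raise InvalidParameterError(
                f"multiplier for {name} must be > 0; use knockouts for "
                "structural zeros"
            )
    vals = {n: v * modifications.get(n, 1.0) for n, v in base.values.items()}
    out = ModelParameters(vals, base.knockouts)
    for gene in knockouts:
        out = apply_knockout(out, gene)
    return out
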