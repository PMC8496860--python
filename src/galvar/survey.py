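"""Single-parameter perturbation survey of the bimodal range.

For a fixed glucose concentration, galactose is titrated along the twofold
ladder in both directions (continuation) and each ladder point is
classified as unimodal OFF, bimodal, or unimodal ON.  Two boundaries
summarize the row: ``gal_on``, the lowest galactose at which bimodality
has emerged, and ``gal_full``, the lowest galactose at which the
population is fully induced (bimodality has vanished upward).

Three metrics compare a perturbed parameter set against the reference:

* ``delta_on``    log2(gal_on'  / gal_on)   - shift of bimodality onset;
* ``delta_full``  log2(gal_full'/ gal_full) - shift of full induction;
* ``delta_level`` relative change of the un-normalized high steady-state
  Gal1p level at the highest ladder galactose.

Positive delta_on/delta_full mean the pathway needs more galactose (more
repressed); negative values mean easier induction.  On the twofold ladder
all finite boundary shifts are integers.  Boundaries that leave the ladder
are capped one twofold step beyond its ends and flagged, so capping can
never silently flip a classification; degeneration to a unimodal-OFF
system is flagged separately (``degenerate_to_off``).

The full survey perturbs each of the 36 free parameters by factors
{0.01, 0.1, 0.5, 2, 10, 100} (216 rows) and records the three metrics at
each of the 8 glucose levels (24 columns).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import FREE_PARAMETERS, ModelParameters, SugarCondition, make_variant
from .network import N_STATE
from .solvers import SolverConfig, equilibrate
from .steady_state import (
    BIMODAL,
    UNIMODAL_OFF,
    UNIMODAL_ON,
    classify_modality,
    default_grid,
)

__all__ = [
    "DEFAULT_FACTORS",
    "BimodalBoundaries",
    "bimodal_boundaries",
    "delta_on",
    "delta_full",
    "delta_level",
    "PerturbationMatrix",
    "build_matrix",
    "classify_rows",
    "embed_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_FACTORS = (0.01, 0.1, 0.5, 2.0, 10.0, 100.0)

MORE_INDUCIBLE = "more_inducible"
MORE_REPRESSED = "more_repressed"
INSENSITIVE = "bimodality_insensitive"
OTHER = "other"


@dataclass(frozen=True)
class BimodalBoundaries:
    """Bimodal-range boundaries of one glucose row."""

    glucose: float
    gal_on: float | None          # lowest ladder galactose that is bimodal
    gal_full: float | None        # lowest ladder galactose that is unimodal ON
    always_off: bool
    always_bimodal: bool
    level_full: float             # g1_high at the highest ladder galactose
    ladder: tuple[float, ...]
    n_masked: int = 0
    row_max: float = 0.0          # max high level over the ladder
    on_from_start: bool = False   # already fully induced at the ladder bottom


def bimodal_boundaries(
    params: ModelParameters,
    glucose: float,
    gal_ladder: tuple[float, ...] | None = None,
    cfg: SolverConfig | None = None,
    half_max: float | None = None,
) -> BimodalBoundaries:
    """Titrate galactose at fixed glucose and locate the bimodal region.

    The low branch is continued upward from the zero-galactose steady
    state, the high branch downward from the ladder maximum.  Ladder
    points whose relaxation fails to converge are masked out of the
    boundary search (counted in ``n_masked``).

    ``half_max`` is the induction level above which a non-bimodal point
    counts as fully induced.  By default it is half the row's own maximum
    high level; when comparing a perturbed system against a reference
    (the survey), pass half the *reference* row maximum so a perturbation
    that crushes the induction level classifies as degenerated-to-OFF
    rather than as trivially 'fully induced' on its own shrunken scale.
    """
    cfg = cfg or SolverConfig()
    if gal_ladder is None:
        gal_ladder = default_grid().galactose_ladder()
    ladder = tuple(gal_ladder)
    if list(ladder) != sorted(ladder) or any(g <= 0 for g in ladder):
        raise ValueError("gal_ladder must be strictly increasing and nonzero")

    lo: dict[float, float] = {}
    hi: dict[float, float] = {}
    ok: dict[float, bool] = {}
    y, c = equilibrate(params, SugarCondition(glucose, 0.0),
                       np.zeros(N_STATE), cfg)
    base_ok = c
    for ga in ladder:
        y, c = equilibrate(params, SugarCondition(glucose, ga), y, cfg)
        lo[ga] = y[0]
        ok[ga] = c and base_ok
    y, c = equilibrate(params, SugarCondition(glucose, ladder[-1]),
                       np.zeros(N_STATE), cfg)
    base_ok = c
    for ga in reversed(ladder):
        y, c = equilibrate(params, SugarCondition(glucose, ga), y, cfg)
        hi[ga] = y[0]
        ok[ga] = ok[ga] and c and base_ok

    valid = [ga for ga in ladder if ok[ga]]
    n_masked = len(ladder) - len(valid)
    if n_masked:
        logger.warning(
            "%d ladder points masked (non-convergence) at glucose %g",
            n_masked, glucose,
        )
    if not valid:
        return BimodalBoundaries(glucose, None, None, True, False, 0.0,
                                 ladder, n_masked, 0.0)

    highs = {ga: max(hi[ga], lo[ga]) for ga in valid}
    lows = {ga: min(hi[ga], lo[ga]) for ga in valid}
    row_max = max(highs.values())
    if half_max is not None:
        half = half_max
    else:
        half = 0.5 * row_max if row_max > 0 else 1.0

    modality = {
        ga: classify_modality(highs[ga], lows[ga], half,
                              cfg.fold_threshold, cfg.low_floor)
        for ga in valid
    }
    gal_on = next((ga for ga in valid if modality[ga] == BIMODAL), None)
    gal_full = next((ga for ga in valid if modality[ga] == UNIMODAL_ON), None)
    always_off = all(m == UNIMODAL_OFF for m in modality.values())
    always_bimodal = gal_on is not None and gal_full is None
    on_from_start = modality[valid[0]] == UNIMODAL_ON
    return BimodalBoundaries(
        glucose, gal_on, gal_full, always_off, always_bimodal,
        float(highs[valid[-1]]), ladder, n_masked, float(row_max),
        on_from_start,
    )


def _cap_high(ladder: tuple[float, ...]) -> float:
    return 2.0 * ladder[-1]


def _cap_low(ladder: tuple[float, ...]) -> float:
    return 0.5 * ladder[0]


def delta_on(
    ref: BimodalBoundaries, pert: BimodalBoundaries
) -> tuple[float, bool]:
    """log2 shift of the bimodality-onset boundary, with degeneracy flag.

    Requires the reference boundary.  A perturbed system that is unimodal
    OFF everywhere returns the positive cap (one step past the ladder top)
    with the degeneracy flag set.  A perturbed system with no bimodal
    point takes its onset from where induction appears instead: below the
    ladder (negative cap) when the row is already induced at the ladder
    bottom, or at its full-induction boundary when the bistable band has
    collapsed to zero width (a monostable graded row).
    """
    if ref.gal_on is None:
        raise ValueError("reference gal_on is undefined for this row")
    if pert.always_off:
        return math.log2(_cap_high(pert.ladder) / ref.gal_on), True
    if pert.gal_on is None:
        if pert.on_from_start:
            # onset below the measured range
            return math.log2(_cap_low(pert.ladder) / ref.gal_on), False
        return math.log2(pert.gal_full / ref.gal_on), False
    return math.log2(pert.gal_on / ref.gal_on), False


def delta_full(
    ref: BimodalBoundaries, pert: BimodalBoundaries
) -> tuple[float, bool]:
    """log2 shift of the full-induction boundary, with degeneracy flag.

    A row still bimodal at the ladder top is treated as having its
    full-induction boundary one twofold step past the top (the
    always-bimodal convention), for the reference and the perturbation
    alike; degeneration to unimodal OFF maps to the positive cap with the
    flag set.
    """
    ref_full = ref.gal_full if ref.gal_full is not None else _cap_high(ref.ladder)
    if pert.always_off:
        return math.log2(_cap_high(pert.ladder) / ref_full), True
    pert_full = (
        pert.gal_full if pert.gal_full is not None else _cap_high(pert.ladder)
    )
    return math.log2(pert_full / ref_full), False


def delta_level(ref_level: float, pert_level: float) -> float:
    """Relative change (pert - ref) / ref of the full-induction level."""
    if ref_level <= 0:
        raise ValueError("reference induction level must be > 0")
    return (pert_level - ref_level) / ref_level


@dataclass
class PerturbationMatrix:
    """Survey result: delta metrics for every (parameter, factor) row.

    ``values`` has one row per perturbation and 3 x n_glucose metric
    columns; ``degenerate`` and ``missing`` are same-shaped boolean masks
    (degenerate-to-OFF cells, undefined cells).  ``labels`` is filled by
    :func:`classify_rows`.
    """

    values: pd.DataFrame
    degenerate: pd.DataFrame
    missing: pd.DataFrame
    glucose_levels: tuple[float, ...]
    labels: pd.Series | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        if self.labels is not None:
            df["label"] = self.labels
        return df.reset_index()


def build_matrix(
    params: ModelParameters,
    free_names: tuple[str, ...] | None = None,
    factors: tuple[float, ...] = DEFAULT_FACTORS,
    glucose_levels: tuple[float, ...] | None = None,
    gal_ladder: tuple[float, ...] | None = None,
    cfg: SolverConfig | None = None,
) -> PerturbationMatrix:
    """Assemble the perturbation matrix (defaults: 36 x 6 = 216 rows).

    Reference boundaries are computed once per glucose level.  Per-cell
    failures (undefined reference boundary, non-convergence) are recorded
    in the missing mask and never abort the survey.
    """
    free_names = tuple(free_names or FREE_PARAMETERS)
    cfg = cfg or SolverConfig()
    if glucose_levels is None:
        glucose_levels = default_grid().glucose_levels
    if gal_ladder is None:
        gal_ladder = default_grid().galactose_ladder()

    refs = {
        g: bimodal_boundaries(params, g, gal_ladder, cfg)
        for g in glucose_levels
    }

    index = pd.MultiIndex.from_product(
        [free_names, factors], names=["parameter", "factor"]
    )
    cols = (
        [f"delta_on[{g:g}]" for g in glucose_levels]
        + [f"delta_full[{g:g}]" for g in glucose_levels]
        + [f"delta_level[{g:g}]" for g in glucose_levels]
    )
    values = pd.DataFrame(np.nan, index=index, columns=cols)
    degenerate = pd.DataFrame(False, index=index, columns=cols)
    missing = pd.DataFrame(True, index=index, columns=cols)

    for name in free_names:
        for factor in factors:
            pert_params = make_variant(params, {name: factor})
            for g in glucose_levels:
                ref = refs[g]
                ref_half = 0.5 * ref.row_max if ref.row_max > 0 else None
                try:
                    pert = bimodal_boundaries(pert_params, g, gal_ladder,
                                              cfg, half_max=ref_half)
                except Exception as exc:   # never abort the whole matrix
                    logger.warning(
                        "survey cell (%s, %g, glucose %g) failed: %s",
                        name, factor, g, exc,
                    )
                    continue
                row = (name, factor)
                if ref.gal_on is not None:
                    v, flag = delta_on(ref, pert)
                    values.loc[row, f"delta_on[{g:g}]"] = v
                    degenerate.loc[row, f"delta_on[{g:g}]"] = flag
                    missing.loc[row, f"delta_on[{g:g}]"] = False
                v, flag = delta_full(ref, pert)
                values.loc[row, f"delta_full[{g:g}]"] = v
                degenerate.loc[row, f"delta_full[{g:g}]"] = flag
                missing.loc[row, f"delta_full[{g:g}]"] = False
                if ref.level_full > 0:
                    values.loc[row, f"delta_level[{g:g}]"] = delta_level(
                        ref.level_full, pert.level_full
                    )
                    missing.loc[row, f"delta_level[{g:g}]"] = False
    return PerturbationMatrix(values, degenerate, missing,
                              tuple(glucose_levels))


def classify_rows(
    matrix: PerturbationMatrix,
    min_rows: int = 2,
    shift_threshold: float = 3.0,
    insensitive_band: float = 1.0,
    level_tol: float = 0.1,
) -> pd.Series:
    """Label each perturbation row by its effect on the bimodal range.

    * more_inducible: delta_on <= -shift_threshold (>= 8-fold easier) at
      >= min_rows glucose levels;
    * more_repressed: delta_on >= +shift_threshold at >= min_rows levels,
      or any degeneration to unimodal OFF;
    * bimodality_insensitive: every |delta_on|, |delta_full| within
      ``insensitive_band`` and every |delta_level| within ``level_tol``;
    * other: anything else.  Missing cells satisfy no predicate.
    """
    on_cols = [c for c in matrix.values.columns if c.startswith("delta_on")]
    full_cols = [c for c in matrix.values.columns if c.startswith("delta_full")]
    lvl_cols = [c for c in matrix.values.columns if c.startswith("delta_level")]
    labels = {}
    for row in matrix.values.index:
        on = matrix.values.loc[row, on_cols].astype(float)
        full = matrix.values.loc[row, full_cols].astype(float)
        lvl = matrix.values.loc[row, lvl_cols].astype(float)
        deg = bool(matrix.degenerate.loc[row].any())
        if (on <= -shift_threshold).sum() >= min_rows:
            labels[row] = MORE_INDUCIBLE
        elif deg or (on >= shift_threshold).sum() >= min_rows:
            labels[row] = MORE_REPRESSED
        elif (
            on.dropna().abs().le(insensitive_band).all()
            and full.dropna().abs().le(insensitive_band).all()
            and lvl.dropna().abs().le(level_tol).all()
            and not (on.isna().all() and full.isna().all())
        ):
            labels[row] = INSENSITIVE
        else:
            labels[row] = OTHER
    out = pd.Series(labels).reindex(matrix.values.index)
    matrix.labels = out
    return out


def embed_matrix(
    matrix: PerturbationMatrix,
    minkowski_order: float = 2.0,
    seed: int = 0,
    perplexity: float | None = None,
) -> pd.DataFrame:
    """Seeded 2-D t-SNE of the perturbation rows (visualization aid).

    Missing cells are imputed as 0 for the embedding only (classification
    always uses the raw values and flags).  Row distances are Minkowski of
    the given order; the embedding is deterministic under ``seed``.
    """
    from sklearn.manifold import TSNE

    X = matrix.values.to_numpy(dtype=float)
    X = np.where(np.isnan(X), 0.0, X)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate (constant) matrix cannot be embedded")
    n = X.shape[0]
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2, metric="minkowski",
        metric_params={"p": minkowski_order},
        random_state=seed, init="random", method="exact",
        perplexity=perplexity,
    )
    coords = tsne.fit_transform(X)
    out = pd.DataFrame(coords, columns=["x", "y"], index=matrix.values.index)
    return out.reset_index()
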