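"""Right-hand side of the GAL regulatory-network ODE system.

Twelve dynamic species: Gal1p (G1), Gal2p (G2), Gal3p (G3), activated
galactose-bound Gal3p (G3*), Gal80p (G80), Gal4p (G4), the Gal3*-Gal80
complex (C83), the Gal4-Gal80 complex (C84), the aggregate hexose
transporter (HXT), the total glucose repressor pool (Rtot, e.g. Mig1p),
and intracellular glucose and galactose.  The active, glucose-bound
repressor Rs is an algebraic function of Rtot and intracellular glucose.

Transcription uses Hill activation by free Gal4p and Hill repression by
Rs.  Sugar uptake uses competitive Michaelis-Menten forms on the two
shared transporters: Gal2p with glucose/galactose relative affinity rG2,
and HXT with relative affinity rHXT and catalytic scaling rcat*kG2.
External sugars are held constant (no depletion) during any integration.

A deliberate reading: the galactose concentration sensed by Gal3p is the
*intracellular* pool gal_in (Gal3p is an intracellular galactose sensor),
so the Gal3p activation terms use gal_in, never the external
concentration.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .params import (
    PARAM_NAMES,
    InvalidParameterError,
    ModelParameters,
    SugarCondition,
)

__all__ = ["hill_activation", "hill_repression", "active_repressor", "rhs"]

# parameter-vector indices (canonical PARAM_NAMES order)
_IX = {name: i for i, name in enumerate(PARAM_NAMES)}

N_STATE = 12
# state indices
(_G1, _G2, _G3, _G3S, _G80, _G4, _C83, _C84, _HXT, _RTOT, _GLU, _GAL) = range(12)


def hill_activation(x: float, K: float, n: float) -> float:
    """Hill activation fraction x^n / (x^n + K^n), in [0, 1].

    The repression form used throughout the model is the complement
    K^n / (K^n + x^n); see :func:`hill_repression`.
    """
    if K <= 0 or n <= 0:
        raise InvalidParameterError("Hill threshold K and coefficient n must be > 0")
    if x < 0:
        raise ValueError("Hill input must be non-negative")
    if x == 0.0:
        return 0.0
    xn = x ** n
    return xn / (xn + K ** n)


def hill_repression(x: float, K: float, n: float) -> float:
    """Hill repression fraction K^n / (K^n + x^n), in [0, 1]."""
    return 1.0 - hill_activation(x, K, n)


def active_repressor(Rtot: float, gluc_in: float, params: ModelParameters) -> float:
    """Active (glucose-bound) repressor Rs.

    Rs = gluc_in^nRs / (gluc_in^nRs + KRs^nRs) * Rtot, so 0 <= Rs <= Rtot.
    """
    if Rtot < 0 or gluc_in < 0:
        raise ValueError("abundances must be non-negative")
    if Rtot == 0.0:
        return 0.0
    return hill_activation(gluc_in, params["KRs"], params["nRs"]) * Rtot


@njit(cache=True)
def _hill_act(x, K, n):
    if x <= 0.0:
        return 0.0
    xn = x ** n
    return xn / (xn + K ** n)


@njit(cache=True)
def _hill_rep(x, K, n):
    Kn = K ** n
    if x <= 0.0:
        return 1.0
    return Kn / (Kn + x ** n)


@njit(cache=True)
def rhs_vec(y, p, glucex, galex):
    """Time derivatives of the 12 species; ``p`` in PARAM_NAMES order."""
    G1 = y[0]; G2 = y[1]; G3 = y[2]; G3s = y[3]; G80 = y[4]; G4 = y[5]
    C83 = y[6]; C84 = y[7]; HXT = y[8]; Rtot = y[9]
    gluc = y[10]; gal = y[11]

    a1 = p[0]; ag1 = p[1]; a2 = p[2]; ag2 = p[3]; a3 = p[4]; ag3 = p[5]
    a80 = p[6]; ag80 = p[7]; a4 = p[8]; ag4 = p[9]
    a0HXT = p[10]; aHXT = p[11]; aR = p[12]
    KG1 = p[13]; KG2 = p[14]; KG3 = p[15]; KG80 = p[16]; KHXT = p[17]
    KR1 = p[18]; KR3 = p[19]; KR4 = p[20]; KRs = p[21]
    kf3 = p[22]; kr3 = p[23]; kf83 = p[24]; kr83 = p[25]
    kf84 = p[26]; kr84 = p[27]
    kG2 = p[28]; rG2 = p[29]; KGgluc = p[30]
    rcat = p[31]; rHXT = p[32]; KHXTgluc = p[33]
    d = p[34]; dsugar = p[35]
    n1 = p[36]; n2 = p[37]; n3 = p[38]; n80 = p[39]; nHXT = p[40]
    nR1 = p[41]; nR3 = p[42]; nR4 = p[43]; nRs = p[44]

    # active glucose-bound repressor (algebraic)
    Rs = _hill_act(gluc, KRs, nRs) * Rtot

    kHXT = rcat * kG2

    dG1 = a1 + ag1 * _hill_act(G4, KG1, n1) * _hill_rep(Rs, KR1, nR1) - d * G1
    dG2 = a2 + ag2 * _hill_act(G4, KG2, n2) - d * G2
    dG3 = (a3 + ag3 * _hill_act(G4, KG3, n3) * _hill_rep(Rs, KR3, nR3)
           - kf3 * gal * G3 + kr3 * G3s - d * G3)
    dG3s = (kf3 * gal * G3 - kr3 * G3s
            - kf83 * G3s * G80 + kr83 * C83 - d * G3s)
    dG80 = (a80 + ag80 * _hill_act(G4, KG80, n80)
            - kf83 * G3s * G80 + kr83 * C83
            - kf84 * G4 * G80 + kr84 * C84 - d * G80)
    dG4 = (a4 + ag4 * _hill_rep(Rs, KR4, nR4)
           - kf84 * G4 * G80 + kr84 * C84 - d * G4)
    dC83 = kf83 * G3s * G80 - kr83 * C83 - d * C83
    dC84 = kf84 * G4 * G80 - kr84 * C84 - d * C84
    dHXT = a0HXT + aHXT * _hill_rep(G4, KHXT, nHXT) - d * HXT
    dRtot = aR - d * Rtot

    up_gluc_G2 = kG2 * G2 * glucex / (galex / rG2 + glucex + KGgluc)
    up_gluc_HXT = kHXT * HXT * glucex / (galex / rHXT + glucex + KHXTgluc)
    up_gal_G2 = kG2 * G2 * galex / (rG2 * glucex + galex + rG2 * KGgluc)
    up_gal_HXT = kHXT * HXT * galex / (rHXT * glucex + galex + rHXT * KHXTgluc)

    dgluc = up_gluc_G2 + up_gluc_HXT - dsugar * gluc
    dgal = (up_gal_G2 - kf3 * gal * G3 + kr3 * G3s
            + up_gal_HXT - dsugar * gal)

    out = np.empty(12)
    out[0] = dG1; out[1] = dG2; out[2] = dG3; out[3] = dG3s
    out[4] = dG80; out[5] = dG4; out[6] = dC83; out[7] = dC84
    out[8] = dHXT; out[9] = dRtot; out[10] = dgluc; out[11] = dgal
    return out


def rhs(
    state: np.ndarray,
    params: ModelParameters,
    condition: SugarCondition,
) -> np.ndarray:
    """Time derivative of the 12-component model state.

    Raises if any state component is below -1e-9; integrators are expected
    to clip smaller numerical undershoots to zero before calling.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have {N_STATE} components")
    if np.any(y < -1e-9):
        raise ValueError("negative state component passed to rhs")
    y = np.maximum(y, 0.0)
    return rhs_vec(y, params.as_vector(),
                   condition.glucose_ext, condition.galactose_ext)
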