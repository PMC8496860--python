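"""Independent literal transcription of the network equations.

This is a second, deliberately separate implementation of the model's
right-hand side, written directly from the printed equation forms with no
shared code, used as the oracle for the packaged implementation.  Keep it
dumb: every term spelled out, dictionary-based, no vectorization.
"""


def oracle_rhs(state: dict, p: dict, glucex: float, galex: float) -> dict:
    G1 = state["G1"]; G2 = state["G2"]; G3 = state["G3"]
    G3s = state["G3star"]; G80 = state["G80"]; G4 = state["G4"]
    C83 = state["C83"]; C84 = state["C84"]; HXT = state["HXT"]
    Rtot = state["Rtot"]; gluc = state["gluc_in"]; gal = state["gal_in"]

    # activated repressor bound by glucose
    Rs = (gluc ** p["nRs"] / (gluc ** p["nRs"] + p["KRs"] ** p["nRs"])) * Rtot \
        if gluc > 0 else 0.0

    out = {}
    out["G1"] = (
        p["a1"]
        + p["ag1"]
        * (G4 ** p["n1"] / (G4 ** p["n1"] + p["KG1"] ** p["n1"]) if G4 > 0 else 0.0)
        * (p["KR1"] ** p["nR1"] / (p["KR1"] ** p["nR1"] + Rs ** p["nR1"]))
        - p["d"] * G1
    )
    out["G2"] = (
        p["a2"]
        + p["ag2"]
        * (G4 ** p["n2"] / (G4 ** p["n2"] + p["KG2"] ** p["n2"]) if G4 > 0 else 0.0)
        - p["d"] * G2
    )
    out["G3"] = (
        p["a3"]
        + p["ag3"]
        * (G4 ** p["n3"] / (G4 ** p["n3"] + p["KG3"] ** p["n3"]) if G4 > 0 else 0.0)
        * (p["KR3"] ** p["nR3"] / (p["KR3"] ** p["nR3"] + Rs ** p["nR3"]))
        - p["kf3"] * gal * G3 + p["kr3"] * G3s - p["d"] * G3
    )
    out["G3star"] = (
        p["kf3"] * gal * G3 - p["kr3"] * G3s
        - p["kf83"] * G3s * G80 + p["kr83"] * C83 - p["d"] * G3s
    )
    out["G80"] = (
        p["a80"]
        + p["ag80"]
        * (G4 ** p["n80"] / (G4 ** p["n80"] + p["KG80"] ** p["n80"]) if G4 > 0 else 0.0)
        - p["kf83"] * G3s * G80 + p["kr83"] * C83
        - p["kf84"] * G4 * G80 + p["kr84"] * C84
        - p["d"] * G80
    )
    out["G4"] = (
        p["a4"]
        + p["ag4"]
        * (p["KR4"] ** p["nR4"] / (p["KR4"] ** p["nR4"] + Rs ** p["nR4"]))
        - p["kf84"] * G4 * G80 + p["kr84"] * C84 - p["d"] * G4
    )
    out["C83"] = p["kf83"] * G3s * G80 - p["kr83"] * C83 - p["d"] * C83
    out["C84"] = p["kf84"] * G4 * G80 - p["kr84"] * C84 - p["d"] * C84
    out["HXT"] = (
        p["a0HXT"]
        + p["aHXT"]
        * (p["KHXT"] ** p["nHXT"] / (p["KHXT"] ** p["nHXT"] + G4 ** p["nHXT"]))
        - p["d"] * HXT
    )
    out["Rtot"] = p["aR"] - p["d"] * Rtot
    out["gluc_in"] = (
        p["kG2"] * G2 * glucex
        / ((1.0 / p["rG2"]) * galex + glucex + p["KGgluc"])
        + (p["rcat"] * p["kG2"]) * HXT * glucex
        / ((1.0 / p["rHXT"]) * galex + glucex + p["KHXTgluc"])
        - p["dsugar"] * gluc
    )
    out["gal_in"] = (
        p["kG2"] * G2 * galex
        / (p["rG2"] * glucex + galex + p["rG2"] * p["KGgluc"])
        - p["kf3"] * gal * G3 + p["kr3"] * G3s
        + (p["rcat"] * p["kG2"]) * HXT * galex
        / (p["rHXT"] * glucex + galex + p["rHXT"] * p["KHXTgluc"])
        - p["dsugar"] * gal
    )
    return out
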