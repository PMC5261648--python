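"""Per-scan derived quantities: Hadlock EFW and fetal head ratios.

Lengths are stored in millimetres throughout the package; the Hadlock
formula is evaluated in its native centimetres internally.  Estimated fetal
weight (EFW) uses Hadlock's third formula (the HC/AC/FL one):

    log10 EFW[g] = 1.326 - 0.00326*AC*FL + 0.0107*HC + 0.0438*AC + 0.158*FL

with HC, AC, FL in cm.  EFW is kept at full precision; rounding to integer
grams happens only at chart/report emission.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, MissingMeasurementError

__all__ = ["efw_hadlock3", "head_ratios", "add_derived_measures",
           "PHYSIOLOGICAL_RANGES_MM"]

# plausible mm ranges over gestational weeks 14-40, used for soft validation
PHYSIOLOGICAL_RANGES_MM = {
    "bpd_mm": (15, 110),
    "hc_mm": (80, 370),
    "ac_mm": (60, 420),
    "fl_mm": (8, 85),
    "hl_mm": (8, 80),
}


def efw_hadlock3(hc_mm, ac_mm, fl_mm):
    """Estimated fetal weight in grams from HC, AC and FL in millimetres.

    Accepts scalars or arrays; strictly increasing in each argument over the
    physiological range.  Raises for non-positive inputs.
    """
    hc = np.asarray(hc_mm, dtype=float) / 10.0
    ac = np.asarray(ac_mm, dtype=float) / 10.0
    fl = np.asarray(fl_mm, dtype=float) / 10.0
    if np.any(hc <= 0) or np.any(ac <= 0) or np.any(fl <= 0):
        raise InvalidMeasurementError("HC, AC and FL must all be positive")
    log10_w = (1.326 - 0.00326 * ac * fl + 0.0107 * hc
               + 0.0438 * ac + 0.158 * fl)
    w = 10.0 ** log10_w
    return w.item() if np.ndim(w) == 0 else w


def head_ratios(fl_mm, hc_mm, bpd_mm):
    """Unit-free (FL/HC, FL/BPD) ratios used to screen head disproportion."""
    arrs = {"fl_mm": fl_mm, "hc_mm": hc_mm, "bpd_mm": bpd_mm}
    for name, v in arrs.items():
        a = np.asarray(v, dtype=float)
        if np.any(~np.isfinite(a)):
            raise MissingMeasurementError(f"{name} is missing")
        if np.any(a <= 0):
            raise InvalidMeasurementError(f"{name} must be positive")
    fl = np.asarray(fl_mm, dtype=float)
    fl_hc = fl / np.asarray(hc_mm, dtype=float)
    fl_bpd = fl / np.asarray(bpd_mm, dtype=float)
    if np.ndim(fl_hc) == 0 and np.ndim(fl_bpd) == 0:
        return fl_hc.item(), fl_bpd.item()
    return fl_hc, fl_bpd


def add_derived_measures(scans: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the scan table with efw_g, fl_hc and fl_bpd columns."""
    out = scans.copy()
    out["efw_g"] = efw_hadlock3(out["hc_mm"].to_numpy(),
                                out["ac_mm"].to_numpy(),
                                out["fl_mm"].to_numpy())
    fl_hc, fl_bpd = head_ratios(out["fl_mm"].to_numpy(),
                                out["hc_mm"].to_numpy(),
                                out["bpd_mm"].to_numpy())
    out["fl_hc"] = fl_hc
    out["fl_bpd"] = fl_bpd
    return out
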