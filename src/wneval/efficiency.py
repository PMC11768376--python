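"""Water- and nitrogen-use efficiency indices and percent contrasts.

WUE  = Y / ET        yield per unit water consumed      [t/(ha*mm)]
IWUE = Y / I         yield per unit irrigation applied  [t/(ha*mm)]
NPFP = 1000 * Y / F_N  yield (kg) per kg nitrogen       [kg/kg]

Y is yield in t/ha, ET seasonal water consumption in mm, I seasonal
irrigation in mm, F_N the nitrogen rate in kg/ha.  The factor 1000 in
NPFP converts yield from tonnes to kilograms so the index is kg yield
per kg N; it is undefined for the unfertilized control.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EfficiencyRecord",
    "wue",
    "iwue",
    "npfp",
    "relative_difference",
    "efficiency_table",
]


@dataclass(frozen=True)
class EfficiencyRecord:
    """Per-treatment, per-year efficiency indices (NPFP None for zero N)."""

    treatment: str
    year: int
    wue: float
    iwue: float
    npfp: float | None


def wue(Y: float, ET: float) -> float:
    """Water use efficiency Y/ET in t/(ha*mm)."""
    if ET <= 0:
        raise ValueError(f"ET must be > 0, got {ET}")
    return Y / ET


def iwue(Y: float, I: float) -> float:
    """Irrigation water use efficiency Y/I in t/(ha*mm)."""
    if I <= 0:
        raise ValueError(f"irrigation must be > 0, got {I}")
    return Y / I


def npfp(Y: float, F_N: float) -> float:
    """Nitrogen partial factor productivity 1000*Y/F_N in kg/kg."""
    if F_N <= 0:
        raise ValueError("NPFP is undefined for zero-N control (F_N <= 0)")
    return 1000.0 * Y / F_N


def relative_difference(a: float, b: float) -> float:
    """Percent difference of ``a`` relative to reference ``b``: (a-b)/b*100."""
    if b == 0:
        raise ValueError("reference must be nonzero")
    return (a - b) / b * 100.0


def efficiency_table(year: int) -> pd.DataFrame:
    """Efficiency indices for all ten treatments of one fixture season.

    Returns a DataFrame indexed by treatment with columns Y, ET, I, F_N,
    WUE, IWUE and NPFP (NaN for the zero-N control), recomputed from the
    measured ET/yield fixture and the design table.
    """
    from . import trial_data

    t1 = trial_data.load_fixture("table1")
    t1 = t1[t1["year"] == year].set_index("treatment")
    if t1.empty:
        raise KeyError(f"unknown fixture year {year!r}")
    treatments = trial_data.load_treatments()

    rows = {}
    for tid in trial_data.TREATMENT_ORDER:
        tr = treatments[tid]
        y = float(t1.loc[tid, "yield_t_ha"])
        et = float(t1.loc[tid, "et_mm"])
        irr = tr.irrigation_total[year]
        rows[tid] = {
            "Y": y,
            "ET": et,
            "I": irr,
            "F_N": tr.n_rate,
            "WUE": wue(y, et),
            "IWUE": iwue(y, irr),
            "NPFP": npfp(y, tr.n_rate) if tr.n_rate > 0 else float("nan"),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "treatment"
    return df
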