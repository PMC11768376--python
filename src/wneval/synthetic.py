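"""Synthetic water x nitrogen trials with the structure the pipeline assumes.

The generator emulates a 3x3 factorial deficit-irrigation x nitrogen
design: yield and quality indicators follow concave quadratic response
surfaces with an interior optimum in the (water, nitrogen) plane, water
consumption rises monotonically with irrigation level (and weakly with
nitrogen), and independent Gaussian noise is added per indicator.
Water levels are coded by the midpoint of their field-capacity band
(55 / 65 / 75 % FC) and nitrogen by rate (215 / 270 / 325 kg/ha);
default surface parameters and noise magnitudes are set to the scale of
a real eggplant trial (yields around 60-88 t/ha with sd near 2 t/ha).

A second generator emits layered soil-moisture records whose water
balance closes exactly on a prescribed per-stage ET, for testing the
water-balance stage; a third builds dispersion-stress matrices for
entropy-weighting property tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import efficiency
from .trial_data import IndicatorTable
from .water_balance import SoilLayer, StageWaterRecord

__all__ = [
    "QuadResponse",
    "SyntheticTrialSpec",
    "generate_indicator_table",
    "generate_soil_moisture_season",
    "generate_weighting_stress_matrix",
]


@dataclass(frozen=True)
class QuadResponse:
    """Concave quadratic response surface with an interior optimum.

    value = peak - curv_water*(w - opt_water)^2 - curv_n*(n - opt_n)^2
            + interaction*(w - opt_water)*(n - opt_n)
    """

    peak: float
    opt_water: float  # % FC
    opt_n: float  # kg/ha
    curv_water: float  # per (%FC)^2
    curv_n: float  # per (kg/ha)^2
    interaction: float = 0.0

    def __post_init__(self) -> None:
        if self.curv_water <= 0 or self.curv_n <= 0:
            raise ValueError(
                "curvatures must be positive for an interior optimum"
            )

    def __call__(self, w: float, n: float) -> float:
        dw, dn = w - self.opt_water, n - self.opt_n
        return (
            self.peak
            - self.curv_water * dw**2
            - self.curv_n * dn**2
            + self.interaction * dw * dn
        )


def _default_responses() -> dict[str, QuadResponse]:
    return {
        "Y": QuadResponse(peak=88.0, opt_water=65, opt_n=270,
                          curv_water=0.12, curv_n=0.005),
        "TSS": QuadResponse(peak=4.9, opt_water=65, opt_n=270,
                            curv_water=0.0015, curv_n=0.00025),
        "VC": QuadResponse(peak=63.0, opt_water=65, opt_n=270,
                           curv_water=0.03, curv_n=0.006),
    }


@dataclass
class SyntheticTrialSpec:
    """Design and response-surface parameters of a synthetic trial."""

    water_levels: tuple[float, ...] = (55.0, 65.0, 75.0)  # % FC midpoints
    n_levels: tuple[float, ...] = (215.0, 270.0, 325.0)  # kg/ha
    responses: dict[str, QuadResponse] = field(default_factory=_default_responses)
    #: ET = et_base + et_slope_water * w + et_slope_n * n  (mm)
    et_base: float = 60.0
    et_slope_water: float = 3.0  # mm per % FC; must be > 0 (monotone ET)
    et_slope_n: float = 0.15  # mm per kg/ha
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"Y": 2.0, "TSS": 0.1, "VC": 2.0, "ET": 5.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.water_levels) < 2 or len(self.n_levels) < 2:
            raise ValueError("need at least 2 levels per factor")
        if self.et_slope_water <= 0:
            raise ValueError("et_slope_water must be > 0 (ET monotone in water)")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sd must be >= 0")


def generate_indicator_table(spec: SyntheticTrialSpec) -> IndicatorTable:
    """Simulate one season and assemble the screened indicator table.

    Treatments are labelled WiNj in the same row order as the packaged
    fixtures.  Y, TSS, VC are drawn from their response surfaces plus
    noise; ET from its monotone linear model plus noise; WUE and NPFP
    are then derived through the efficiency module, never simulated
    directly.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows, labels = [], []
    for j, n in enumerate(spec.n_levels, start=1):
        for i, w in enumerate(spec.water_levels, start=1):
            labels.append(f"W{i}N{j}")
            et = spec.et_base + spec.et_slope_water * w + spec.et_slope_n * n
            et += rng.normal(0.0, spec.noise_sd.get("ET", 0.0))
            et = max(et, 1.0)
            vals = {}
            for name, resp in spec.responses.items():
                v = resp(w, n) + rng.normal(0.0, spec.noise_sd.get(name, 0.0))
                vals[name] = max(v, 0.0)
            y = vals.get("Y", 0.0)
            rec = {
                "ET": et,
                "Y": y,
                "WUE": efficiency.wue(y, et),
                "NPFP": efficiency.npfp(y, n),
            }
            rec.update({k: v for k, v in vals.items() if k != "Y"})
            rows.append(rec)
    values = pd.DataFrame(rows, index=pd.Index(labels, name="treatment"))
    return IndicatorTable(
        values=values,
        directions={c: "benefit" for c in values.columns},
        year="synthetic",
    )


def generate_soil_moisture_season(
    true_et_per_stage: list[float],
    schedule: list[tuple[float, float]] | None = None,
    layer_profile: list[tuple[float, float]] | None = None,
    start_content: float = 0.22,
    content_noise_sd: float = 0.0,
    saturation: float = 0.45,
    seed: int = 0,
    stage_names: list[str] | None = None,
) -> list[StageWaterRecord]:
    """Emit stage water records whose balance closes on a prescribed ET.

    ``schedule`` lists (irrigation, rainfall) mm per stage (default: a
    single irrigation event covering 80% of stage ET); ``layer_profile``
    lists (bulk_density, thickness_cm) per calculation layer (default:
    three 20-cm layers at 1.48 g/cm^3).  The storage change each stage
    is the residual ET - M - P, spread evenly across layers; moisture
    trajectories leaving [0.01, saturation] raise an error.  With
    ``content_noise_sd`` > 0 the emitted contents carry independent
    Gaussian measurement noise, so a single season's recovered ET is
    noisy but unbiased.
    """
    if not true_et_per_stage:
        raise ValueError("need at least one stage")
    if schedule is None:
        schedule = [(0.8 * et, 0.0) for et in true_et_per_stage]
    if len(schedule) != len(true_et_per_stage):
        raise ValueError("schedule length must match number of stages")
    if layer_profile is None:
        layer_profile = [(1.48, 20.0)] * 3

    rng = np.random.default_rng(seed)
    capacity = [10.0 * g * h for g, h in layer_profile]  # mm per unit content
    contents = [start_content] * len(layer_profile)
    records = []
    for k, (et, (m_irr, p_rain)) in enumerate(zip(true_et_per_stage, schedule)):
        residual = et - m_irr - p_rain  # mm drawn from (or added to) storage
        per_layer_mm = residual / len(layer_profile)
        new_contents = []
        for c, cap in zip(contents, capacity):
            c2 = c - per_layer_mm / cap
            if not 0.01 <= c2 <= saturation:
                raise ValueError(
                    f"stage {k}: moisture trajectory infeasible "
                    f"(content {c2:.3f} outside [0.01, {saturation}])"
                )
            new_contents.append(c2)
        layers = []
        for (g, h), c1, c2 in zip(layer_profile, contents, new_contents):
            eps1 = rng.normal(0.0, content_noise_sd) if content_noise_sd else 0.0
            eps2 = rng.normal(0.0, content_noise_sd) if content_noise_sd else 0.0
            layers.append(SoilLayer(g, h, c1 + eps1, c2 + eps2))
        records.append(
            StageWaterRecord(
                layers=layers,
                irrigation=m_irr,
                rainfall=p_rain,
                stage=stage_names[k] if stage_names else f"stage{k + 1}",
            )
        )
        contents = new_contents
    return records


def generate_weighting_stress_matrix(
    m: int,
    n: int,
    near_constant_columns: int | list[int] = 0,
    seed: int = 0,
    dispersion: float = 10.0,
    epsilon: float = 0.01,
) -> IndicatorTable:
    """Matrix mixing informative and near-constant indicator columns.

    Because min-max standardization removes raw scale, what entropy
    weighting actually rewards is the *shape* of a column: mass
    concentrated on few objects (low entropy) earns weight, mass spread
    evenly (entropy near 1) does not.  The stress columns are therefore
    tiny jitter (``epsilon``) around a large offset shaped as a plateau
    with a single low reading — after min-max the column is 1 on m-1
    objects and 0 on one, the highest-entropy shape attainable, with
    entropy ln(m-1)/ln(m).  Informative columns have one dominant
    object far above a low-level background, an almost one-hot shape
    with entropy near 0.  Used to assert that entropy weighting starves
    uninformative columns.
    """
    if m < 3:
        raise ValueError("need m >= 3 objects")
    if isinstance(near_constant_columns, int):
        near_constant = list(range(near_constant_columns))
    else:
        near_constant = list(near_constant_columns)
    rng = np.random.default_rng(seed)
    cols = {}
    for j in range(n):
        if j in near_constant:
            jitter = np.full(m, epsilon)
            jitter[rng.integers(m)] = 0.0
            jitter += rng.normal(0.0, 0.02 * epsilon, size=m)
            cols[f"X{j + 1}"] = 100.0 + jitter
        else:
            col = rng.uniform(0.0, 0.1 * dispersion, size=m)
            col[rng.integers(m)] = dispersion * rng.uniform(1.0, 1.5)
            cols[f"X{j + 1}"] = col
    values = pd.DataFrame(cols, index=pd.Index([f"obj{i + 1}" for i in range(m)]))
    return IndicatorTable(
        values=values, directions={c: "benefit" for c in values.columns}
    )
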