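"""Soil-water balance: gravimetric moisture, irrigation quota, stage ET.

Water consumption (evapotranspiration, ET) is estimated per growth stage
from the change in soil-water storage of the profile plus the water added
during the stage:

    ET = 10 * sum_i gamma_i * H_i * (w_i1 - w_i2) + M + P + K - C   [mm]

with gamma_i the layer bulk density (g/cm^3), H_i the layer thickness
(cm), w_i1/w_i2 the start/end gravimetric water contents (fractions),
M irrigation, P effective rainfall, K groundwater recharge and C deep
percolation (all mm).  At a site with a deep water table and drip
irrigation sized below field capacity, K = C = 0.

Moisture contents are handled as mass fractions throughout; percent
formatting belongs to the presentation layer only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SoilLayerSample",
    "IrrigationPlan",
    "SoilLayer",
    "StageWaterRecord",
    "gravimetric_water_content",
    "irrigation_volume",
    "stage_water_consumption",
    "total_water_consumption",
    "read_stage_records",
]


@dataclass(frozen=True)
class SoilLayerSample:
    """One oven-drying measurement of one depth layer."""

    wet_mass: float  # g
    dry_mass: float  # g
    bulk_density: float = 1.0  # g/cm^3
    thickness: float = 20.0  # cm

    def __post_init__(self) -> None:
        if self.dry_mass <= 0:
            raise ValueError(f"dry_mass must be > 0, got {self.dry_mass}")
        if self.wet_mass < self.dry_mass:
            raise ValueError("wet_mass must be >= dry_mass")
        if self.bulk_density <= 0 or self.thickness <= 0:
            raise ValueError("bulk_density and thickness must be > 0")


@dataclass(frozen=True)
class IrrigationPlan:
    """Design quota bringing the planned wetted layer up to its target.

    The planned wetted layer defaults to 0-60 cm (the managed root zone:
    three 20-cm calculation layers).
    """

    bulk_density: float  # g/cm^3
    target_content: float  # mass fraction, upper design limit
    measured_content: float  # mass fraction, current
    wetted_depth: float = 60.0  # cm
    wetting_ratio: float = 1.0  # fraction of area wetted, (0, 1]

    def __post_init__(self) -> None:
        if not 0 < self.wetting_ratio <= 1:
            raise ValueError("wetting_ratio must be in (0, 1]")
        for name in ("target_content", "measured_content"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be a fraction in [0, 1), got {v}")
        if self.bulk_density <= 0 or self.wetted_depth <= 0:
            raise ValueError("bulk_density and wetted_depth must be > 0")


@dataclass(frozen=True)
class SoilLayer:
    """Start/end moisture state of one calculation layer over a stage."""

    bulk_density: float  # g/cm^3
    thickness: float  # cm
    content_start: float  # mass fraction
    content_end: float  # mass fraction


@dataclass
class StageWaterRecord:
    """Everything needed to close the water balance for one growth stage."""

    layers: list[SoilLayer]
    irrigation: float = 0.0  # mm
    rainfall: float = 0.0  # effective rainfall, mm
    groundwater_recharge: float = 0.0  # mm
    deep_percolation: float = 0.0  # mm
    stage: str | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("layer list must be non-empty")
        if self.irrigation < 0 or self.rainfall < 0:
            raise ValueError("irrigation and rainfall must be >= 0")
        if self.groundwater_recharge < 0 or self.deep_percolation < 0:
            raise ValueError("recharge and percolation must be >= 0")


def gravimetric_water_content(sample: SoilLayerSample) -> float:
    """Mass water content (wet - dry) / dry, as a fraction."""
    return (sample.wet_mass - sample.dry_mass) / sample.dry_mass


def irrigation_volume(plan: IrrigationPlan) -> float:
    """Design irrigation depth in mm: 10 * gamma * H * P * (w_target - w_now).

    Clamped at zero when the profile is already at or above target — the
    schedule only triggers irrigation when moisture falls to the lower
    design limit, so negative demand means no irrigation is due.
    """
    depth = (
        10.0
        * plan.bulk_density
        * plan.wetted_depth
        * plan.wetting_ratio
        * (plan.target_content - plan.measured_content)
    )
    return max(depth, 0.0)


def stage_water_consumption(record: StageWaterRecord) -> float:
    """Stage ET (mm) by soil-water balance over the record's layers."""
    storage_change = 10.0 * sum(
        lay.bulk_density * lay.thickness * (lay.content_start - lay.content_end)
        for lay in record.layers
    )
    return (
        storage_change
        + record.irrigation
        + record.rainfall
        + record.groundwater_recharge
        - record.deep_percolation
    )


def total_water_consumption(stage_et: list[float]) -> float:
    """Seasonal ET as the sum of per-stage ET values."""
    if not stage_et:
        raise ValueError("need at least one stage")
    return float(sum(stage_et))


def read_stage_records(moisture_csv, events_csv) -> list[StageWaterRecord]:
    """Assemble stage records from two CSVs.

    ``moisture_csv`` columns: stage, layer_top_cm, layer_bottom_cm,
    bulk_density, content_start, content_end (contents as fractions).
    ``events_csv`` columns: stage, irrigation_mm, rainfall_mm.
    Stages keep their order of first appearance in the moisture file.
    """
    moist = pd.read_csv(moisture_csv)
    events = pd.read_csv(events_csv).set_index("stage")
    records = []
    for stage in moist["stage"].drop_duplicates():
        sub = moist[moist["stage"] == stage]
        layers = [
            SoilLayer(
                bulk_density=float(r["bulk_density"]),
                thickness=float(r["layer_bottom_cm"]) - float(r["layer_top_cm"]),
                content_start=float(r["content_start"]),
                content_end=float(r["content_end"]),
            )
            for _, r in sub.iterrows()
        ]
        if stage not in events.index:
            raise ValueError(f"no irrigation/rainfall events for stage {stage!r}")
        ev = events.loc[stage]
        records.append(
            StageWaterRecord(
                layers=layers,
                irrigation=float(ev["irrigation_mm"]),
                rainfall=float(ev["rainfall_mm"]),
                stage=str(stage),
            )
        )
    return records
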