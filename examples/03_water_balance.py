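"""Close the soil-water balance for a growth stage.

A layered moisture profile (oven-dried gravimetric contents, three 20-cm
calculation layers) plus the stage's irrigation and effective rainfall
give the stage crop water consumption ET in mm; an irrigation plan shows
the design quota that refills the planned wetted layer to its target.
"""

from wneval import water_balance as wb

sample = wb.SoilLayerSample(wet_mass=125.0, dry_mass=100.0)
content = wb.gravimetric_water_content(sample)
print(f"Gravimetric water content of the sample: {content:.2%}")

plan = wb.IrrigationPlan(
    bulk_density=1.48, target_content=0.192, measured_content=0.172
)
print(f"Design irrigation quota to refill 0-60 cm: {wb.irrigation_volume(plan):.2f} mm")

record = wb.StageWaterRecord(
    layers=[
        wb.SoilLayer(bulk_density=1.48, thickness=20, content_start=0.20, content_end=0.18),
        wb.SoilLayer(bulk_density=1.50, thickness=20, content_start=0.21, content_end=0.20),
        wb.SoilLayer(bulk_density=1.52, thickness=20, content_start=0.22, content_end=0.21),
    ],
    irrigation=30.0,
    rainfall=10.0,
    stage="flowering",
)
et = wb.stage_water_consumption(record)
print(f"Stage ET by water balance: {et:.2f} mm")
print(
    "ET = storage change + irrigation + effective rainfall; groundwater "
    "recharge and percolation are zero at a deep-water-table drip site."
)
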