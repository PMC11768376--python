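"""wneval — evaluation pipeline for water x nitrogen field trials.

From layered soil-moisture records to a ranked recommendation: the
package computes crop water consumption by soil-water balance, derives
water- and nitrogen-use efficiency indices, screens correlated
indicators, and ranks treatments with an entropy-weighted TOPSIS score.
Packaged fixtures from a two-season deficit-irrigation eggplant trial
let the whole pipeline run end to end with no external data.
"""

from . import (
    cli,
    efficiency,
    ewm_topsis,
    screening,
    synthetic,
    trial_data,
    water_balance,
)
from .efficiency import iwue, npfp, relative_difference, wue
from .ewm_topsis import EwmWeights, TopsisResult, evaluate
from .screening import pearson_matrix, prune_indicators, screen
from .synthetic import SyntheticTrialSpec, generate_indicator_table
from .trial_data import (
    IndicatorTable,
    Treatment,
    build_indicator_table,
    load_fixture,
    read_indicator_table,
    write_result_table,
)
from .water_balance import (
    IrrigationPlan,
    SoilLayerSample,
    StageWaterRecord,
    gravimetric_water_content,
    irrigation_volume,
    stage_water_consumption,
    total_water_consumption,
)

__version__ = "0.1.0"


def evaluate_year(year: int, variant: str = "weights-linear"):
    """Run the full fixture evaluation for one season.

    Convenience wrapper: builds the screened all-benefit indicator
    table for ``year`` from the packaged fixtures and evaluates it.
    Returns ``(EwmWeights, TopsisResult)``.
    """
    table = build_indicator_table(year)
    return evaluate(table, variant=variant)
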