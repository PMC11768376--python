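"""Domain types, CSV I/O, and packaged trial fixtures.

The package ships the printed summary tables of a two-season (2022/2023)
water x nitrogen eggplant trial as CSV fixtures, so the full evaluation
pipeline runs without any external download.  Three deficit-irrigation
levels (W1 moderate 50-60% FC, W2 mild 60-70% FC, W3 full 70-80% FC,
applied during flowering and fruiting) are crossed with three nitrogen
rates (N1 215, N2 270, N3 325 kg/ha); a zero-nitrogen fully irrigated
control (CK) completes the design.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TREATMENT_ORDER",
    "FERTILIZED_TREATMENTS",
    "SCREENED_INDICATORS",
    "CANDIDATE_INDICATORS",
    "Treatment",
    "IndicatorTable",
    "load_fixture",
    "load_treatments",
    "build_indicator_table",
    "read_indicator_table",
    "write_indicator_table",
    "write_result_table",
]

#: Row order used everywhere (fixture table order; CK last).
TREATMENT_ORDER = [
    "W1N1", "W2N1", "W3N1",
    "W1N2", "W2N2", "W3N2",
    "W1N3", "W2N3", "W3N3",
    "CK",
]

#: The nine treatments that receive nitrogen and enter the evaluation.
FERTILIZED_TREATMENTS = TREATMENT_ORDER[:9]

#: Indicators retained after correlation screening.
SCREENED_INDICATORS = ["ET", "Y", "WUE", "NPFP", "TSS", "VC"]

#: Full candidate set available from the printed tables (fruit diameters
#: were only reported graphically and are not part of the fixtures).
CANDIDATE_INDICATORS = ["ET", "Y", "WUE", "IWUE", "NPFP", "SP", "SSC", "TSS", "VC"]

_FIXTURES = {"table1", "table2", "table6", "table7"}


@dataclass(frozen=True)
class Treatment:
    """One water x nitrogen treatment of the factorial design.

    ``moisture_bounds`` maps growth-stage name to the (lower, upper)
    soil-moisture band as percent of field capacity; ``irrigation_total``
    maps year to the seasonal irrigation depth in mm.
    """

    id: str
    water_level: str
    n_rate: float  # kg/ha
    irrigation_total: dict[int, float] = field(default_factory=dict)
    moisture_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rate < 0:
            raise ValueError(f"{self.id}: n_rate must be >= 0, got {self.n_rate}")
        for year, irr in self.irrigation_total.items():
            if irr <= 0:
                raise ValueError(f"{self.id}: irrigation_total[{year}] must be > 0")
        for stage, (lo, hi) in self.moisture_bounds.items():
            if not lo < hi:
                raise ValueError(
                    f"{self.id}: stage {stage!r} lower bound {lo} not below upper {hi}"
                )


@dataclass
class IndicatorTable:
    """An objects x indicators decision matrix with direction tags.

    ``values`` is a DataFrame whose index holds the evaluation-object
    labels (treatments) and whose columns are the indicators.
    ``directions`` assigns ``"benefit"`` (larger is better) or ``"cost"``
    (smaller is better) to every column; ``year`` is a free label.
    """

    values: pd.DataFrame
    directions: dict[str, str]
    year: int | str | None = None

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[0] < 2:
            raise ValueError("indicator table needs at least 2 objects")
        if df.shape[1] < 1:
            raise ValueError("indicator table needs at least 1 indicator")
        if df.isna().any().any():
            cell = df.stack(future_stack=True)
            bad = cell[cell.isna()].index[0]
            raise ValueError(f"missing value at {bad[0]}, {bad[1]}")
        missing = [c for c in df.columns if c not in self.directions]
        if missing:
            raise ValueError(f"direction missing for indicator(s): {missing}")
        bad_dir = {c: d for c, d in self.directions.items()
                   if c in df.columns and d not in ("benefit", "cost")}
        if bad_dir:
            raise ValueError(f"directions must be 'benefit' or 'cost': {bad_dir}")

    @property
    def object_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, indicators: list[str]) -> "IndicatorTable":
        """Restrict to the given indicator columns (order preserved)."""
        missing = [c for c in indicators if c not in self.values.columns]
        if missing:
            raise KeyError(f"unknown indicator(s): {missing}")
        return IndicatorTable(
            values=self.values[indicators].copy(),
            directions={c: self.directions[c] for c in indicators},
            year=self.year,
        )


def load_fixture(name: str) -> pd.DataFrame:
    """Return a packaged fixture table by name (``table1`` .. ``table7``).

    table1: seasonal water consumption (ET, mm) and yield (t/ha);
    table2: fruit quality (SP, SSC, TSS, VC);
    table6: design — moisture bands, N rates, seasonal irrigation;
    table7: growth-stage date ranges.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    ref = importlib.resources.files("wneval.data").joinpath(f"{name}.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_reference(name: str) -> pd.DataFrame:
    """Published reference values of the two-season evaluation.

    ``"weights"``: per-indicator entropy e, utility d and weight (in %)
    per year; ``"ranking"``: per-treatment d+, d-, closeness and rank
    per year.  Used for regression tests and the reproduction report.
    """
    if name not in {"weights", "ranking"}:
        raise KeyError(f"unknown reference table {name!r}")
    ref = importlib.resources.files("wneval.data").joinpath(f"reference_{name}.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_treatments() -> dict[str, Treatment]:
    """Build the ten :class:`Treatment` objects from the design fixture."""
    t6 = load_fixture("table6")
    stages = ["seedling", "flowering", "full", "later"]
    out: dict[str, Treatment] = {}
    for _, row in t6.iterrows():
        out[row["treatment"]] = Treatment(
            id=row["treatment"],
            water_level=row["water_level"],
            n_rate=float(row["n_rate_kg_ha"]),
            irrigation_total={
                2022: float(row["irrigation_2022_mm"]),
                2023: float(row["irrigation_2023_mm"]),
            },
            moisture_bounds={
                s: (float(row[f"{s}_lo"]), float(row[f"{s}_hi"])) for s in stages
            },
        )
    return out


def build_indicator_table(
    year: int,
    indicators: list[str] | None = None,
    directions: dict[str, str] | None = None,
) -> IndicatorTable:
    """Assemble the evaluation matrix for one season from the fixtures.

    Rows are the nine fertilized treatments in fixture order (CK is
    excluded: with no nitrogen applied its NPFP is undefined).  ET and Y
    come from the measured table, TSS/VC/SP/SSC from the quality table;
    WUE, IWUE and NPFP are recomputed from those inputs rather than
    transcribed, so the printed efficiency table never enters the matrix.

    By default the screened six-indicator set is returned with every
    direction set to ``benefit`` — the convention under which the
    published weights and ranking are reproduced.
    """
    from . import efficiency  # deferred: efficiency imports this module

    if indicators is None:
        indicators = list(SCREENED_INDICATORS)
    unknown = [c for c in indicators if c not in CANDIDATE_INDICATORS]
    if unknown:
        raise KeyError(f"unknown indicator(s): {unknown}")

    t1 = load_fixture("table1")
    t2 = load_fixture("table2")
    t1 = t1[t1["year"] == year].set_index("treatment")
    t2 = t2[t2["year"] == year].set_index("treatment")
    if t1.empty:
        raise KeyError(f"unknown fixture year {year!r}")
    treatments = load_treatments()

    rows = []
    for tid in FERTILIZED_TREATMENTS:
        tr = treatments[tid]
        et = float(t1.loc[tid, "et_mm"])
        y = float(t1.loc[tid, "yield_t_ha"])
        rec = {
            "ET": et,
            "Y": y,
            "WUE": efficiency.wue(y, et),
            "IWUE": efficiency.iwue(y, tr.irrigation_total[year]),
            "NPFP": efficiency.npfp(y, tr.n_rate),
            "SP": float(t2.loc[tid, "sp_mg_g"]),
            "SSC": float(t2.loc[tid, "ssc_pct"]),
            "TSS": float(t2.loc[tid, "tss_pct"]),
            "VC": float(t2.loc[tid, "vc_mg_kg"]),
        }
        rows.append({k: rec[k] for k in indicators})

    values = pd.DataFrame(rows, index=pd.Index(FERTILIZED_TREATMENTS, name="treatment"))
    if directions is None:
        directions = {c: "benefit" for c in indicators}
    return IndicatorTable(values=values, directions=directions, year=year)


def read_indicator_table(
    path, directions: dict[str, str], year: int | str | None = None
) -> IndicatorTable:
    """Read an indicator CSV (first column = object id, rest numeric).

    Raises ``ValueError`` naming the offending row/column for a missing
    or non-numeric cell, and for any column without a direction tag.
    """
    df = pd.read_csv(path, index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(f"non-numeric cell at {bad.idxmax()}, {col}")
        df[col] = coerced
    if df.isna().any().any():
        cell = df.stack(future_stack=True)
        obj, col = cell[cell.isna()].index[0]
        raise ValueError(f"missing value at {obj}, {col}")
    return IndicatorTable(values=df, directions=directions, year=year)


def write_indicator_table(table: IndicatorTable, path) -> None:
    """Write an indicator table to CSV (6-decimal round-trip precision)."""
    table.values.to_csv(path, float_format="%.6f")


def write_result_table(result, path) -> None:
    """Write a ranking result as CSV: object, d_plus, d_minus, closeness, rank."""
    df = result.to_frame()
    if df.empty:
        raise ValueError("cannot write an empty result table")
    df.to_csv(path, float_format="%.6f")
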