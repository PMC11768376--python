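"""Entropy-weight method (EWM) and TOPSIS ranking.

The evaluation takes an objects x indicators matrix X, min-max
standardizes each column according to its direction,

    benefit:  z_ij = (x_ij - min_i x_ij) / (max_i x_ij - min_i x_ij)
    cost:     z_ij = (max_i x_ij - x_ij) / (max_i x_ij - min_i x_ij)

derives objective weights from column information entropy,

    P_ij = z_ij / sum_i z_ij
    e_j  = -(1/ln m) * sum_i P_ij ln P_ij        (0*ln 0 := 0)
    w_j  = (1 - e_j) / sum_k (1 - e_k)

and ranks objects by relative closeness to the ideal alternatives

    d_i+/- = sqrt( sum_j w_j * (z_ij - z_j+/-)^2 )
    T_i    = d_i- / (d_i- + d_i+)

with Z+ / Z- the column-wise maxima / minima of the standardized matrix
(the all-ones / all-zeros vectors under min-max with no constant
column).  A dispersed column carries low entropy, hence high information
utility d_j = 1 - e_j and high weight.

Two weighted-distance conventions circulate in the EWM-TOPSIS
literature.  The default, ``weights-linear``, puts the weight linearly
inside the squared deviations as above; ``literal`` first forms the
weighted matrix v_ij = w_j * z_ij and measures plain Euclidean distances
on it (equivalent to squared weights).  The default is the convention
under which the published two-season evaluation of this trial is
reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import IndicatorTable

__all__ = [
    "StandardizedMatrix",
    "EwmWeights",
    "TopsisResult",
    "standardize",
    "proportions",
    "entropy",
    "entropy_weights",
    "ideal_solutions",
    "distances",
    "closeness",
    "rank",
    "evaluate",
]

VARIANTS = ("weights-linear", "literal")


@dataclass
class StandardizedMatrix:
    """Min-max standardized matrix in [0, 1] plus the directions used."""

    z: pd.DataFrame
    directions: dict[str, str]


@dataclass
class EwmWeights:
    """Per-indicator entropy e, information utility d = 1 - e, weight w."""

    entropy: pd.Series
    utility: pd.Series
    weights: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"e": self.entropy, "d": self.utility, "w": self.weights}
        ).rename_axis("indicator")


@dataclass
class TopsisResult:
    """Distances to the ideal alternatives, closeness, and ranks."""

    d_plus: pd.Series
    d_minus: pd.Series
    closeness: pd.Series
    rank: pd.Series
    z_plus: pd.Series
    z_minus: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "closeness": self.closeness,
                "rank": self.rank,
            }
        ).rename_axis("object")


def standardize(table: IndicatorTable, constant_policy: str = "error") -> StandardizedMatrix:
    """Min-max standardize every column in its tagged direction.

    A constant column has no min-max image; by default it raises, while
    ``constant_policy="drop"`` removes it (it would receive zero weight
    in any case).
    """
    df = table.values.astype(float)
    lo, hi = df.min(axis=0), df.max(axis=0)
    span = hi - lo
    constant = span[span == 0].index.tolist()
    if constant:
        if constant_policy == "error":
            raise ValueError(f"constant indicator column(s): {constant}")
        if constant_policy != "drop":
            raise ValueError(f"unknown constant_policy {constant_policy!r}")
        df = df.drop(columns=constant)
        lo, hi, span = lo.drop(constant), hi.drop(constant), span.drop(constant)

    z = (df - lo) / span
    for col, direction in table.directions.items():
        if col in z.columns and direction == "cost":
            z[col] = 1.0 - z[col]
    return StandardizedMatrix(
        z=z, directions={c: table.directions[c] for c in z.columns}
    )


def proportions(z: pd.DataFrame) -> pd.DataFrame:
    """Column proportions P_ij = z_ij / sum_i z_ij (each column sums to 1)."""
    colsum = z.sum(axis=0)
    if (colsum == 0).any():
        bad = colsum[colsum == 0].index.tolist()
        raise ValueError(f"all-zero standardized column(s): {bad}")
    return z / colsum


def entropy(p_column: np.ndarray | pd.Series, m: int | None = None) -> float:
    """Information entropy of one proportion column, normalized by ln m.

    Uses the convention 0*ln 0 = 0, which is load-bearing here: min-max
    standardization produces an exact zero in every column.
    """
    p = np.asarray(p_column, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    if m is None:
        m = p.size
    if m < 2:
        raise ValueError("need at least 2 objects")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return float(-plogp.sum() / np.log(m))


def entropy_weights(e: pd.Series | np.ndarray, index=None) -> EwmWeights:
    """Weights w_j = (1 - e_j) / sum_k (1 - e_k) from column entropies."""
    if index is None and isinstance(e, pd.Series):
        index = e.index
    e = pd.Series(np.asarray(e, dtype=float), index=index)
    if ((e < 0) | (e > 1 + 1e-12)).any():
        raise ValueError("entropies must lie in [0, 1]")
    d = 1.0 - e
    if d.sum() <= 0:
        raise ValueError("no discriminating indicator (all entropies are 1)")
    return EwmWeights(entropy=e, utility=d, weights=d / d.sum())


def ideal_solutions(z: StandardizedMatrix | pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Positive/negative ideal alternatives: column-wise max and min of z."""
    df = z.z if isinstance(z, StandardizedMatrix) else z
    return df.max(axis=0), df.min(axis=0)


def distances(
    z: StandardizedMatrix | pd.DataFrame,
    weights: EwmWeights | pd.Series,
    z_plus: pd.Series,
    z_minus: pd.Series,
    variant: str = "weights-linear",
) -> tuple[pd.Series, pd.Series]:
    """Weighted distances of every object to the two ideal alternatives."""
    df = z.z if isinstance(z, StandardizedMatrix) else z
    w = weights.weights if isinstance(weights, EwmWeights) else weights
    w = w.reindex(df.columns)
    if w.isna().any():
        raise ValueError("weights not aligned with matrix columns")
    if variant == "weights-linear":
        d_plus = np.sqrt(((df - z_plus) ** 2 * w).sum(axis=1))
        d_minus = np.sqrt(((df - z_minus) ** 2 * w).sum(axis=1))
    elif variant == "literal":
        v = df * w
        d_plus = np.sqrt(((v - z_plus * w) ** 2).sum(axis=1))
        d_minus = np.sqrt(((v - z_minus * w) ** 2).sum(axis=1))
    else:
        raise ValueError(f"unknown distance variant {variant!r}; choose from {VARIANTS}")
    return d_plus, d_minus


def closeness(d_plus: pd.Series, d_minus: pd.Series) -> pd.Series:
    """Relative closeness T_i = d_i- / (d_i- + d_i+), in [0, 1]."""
    total = d_plus + d_minus
    if (total == 0).any():
        bad = total[total == 0].index.tolist()
        raise ValueError(f"degenerate object(s) with d+ = d- = 0: {bad}")
    return d_minus / total


def rank(T: pd.Series) -> pd.Series:
    """Ranks 1..m by descending closeness; ties broken by input order."""
    order = sorted(range(len(T)), key=lambda i: (-T.iloc[i], i))
    ranks = pd.Series(0, index=T.index, dtype=int)
    for pos, i in enumerate(order, start=1):
        ranks.iloc[i] = pos
    return ranks


def evaluate(
    table: IndicatorTable,
    variant: str = "weights-linear",
    constant_policy: str = "error",
) -> tuple[EwmWeights, TopsisResult]:
    """Full pipeline: standardize -> entropy weights -> TOPSIS ranking."""
    std = standardize(table, constant_policy=constant_policy)
    P = proportions(std.z)
    m = std.z.shape[0]
    e = pd.Series({col: entropy(P[col], m) for col in P.columns})
    w = entropy_weights(e)
    z_plus, z_minus = ideal_solutions(std)
    d_plus, d_minus = distances(std, w, z_plus, z_minus, variant=variant)
    T = closeness(d_plus, d_minus)
    return w, TopsisResult(
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=T,
        rank=rank(T),
        z_plus=z_plus,
        z_minus=z_minus,
    )
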