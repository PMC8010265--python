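"""Readers/writers, the packaged cultivar reference table, and summaries.

The package ships a transcription of the published reference table for the
80-cultivar white clover panel (release decade, country, leaf size, drought
and irrigated total dry weights in grams, and the critical fraction of
transpirable soil water, FTSWc).  21 cultivars have no FTSWc ("/" in the
source, encoded as missing); they are excluded from all FTSWc statistics
and never imputed.

Note two internal inconsistencies of the source, which the table resolves
in favour of the tabulated values: the narrative gives the FTSWc range as
0.11-0.50 while the table's extremes are 0.12 (AberHerald) and 0.52
(Tribute), and it gives the drought dry-weight maximum as 23.32 g while the
table's is 23.33 g.  All statistics here are computed from the table.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .pipeline import validate_weighing
from .simulate import WEIGHING_COLUMNS

__all__ = [
    "load_table1_fixture",
    "table1_digest",
    "SummaryReport",
    "summarize_ftswc",
    "summarize_dry_weights",
    "rank_cultivars",
    "read_weighing_csv",
    "write_weighing_csv",
    "write_truth_csv",
]

TABLE1_COLUMNS = [
    "cultivar",
    "decade",
    "country",
    "leaf_size",
    "dw_drought_g",
    "dw_irrigated_g",
    "ftswc",
]

#: SHA-256 of the packaged reference table, pinned so silent edits fail loudly.
TABLE1_SHA256 = "13ebdfe55bdf79bfcff5558b6202a8dc083c3758fb3429ab670056e12f40199a"


def _table1_path():
    return resources.files("cloverdry").joinpath("data/table1.csv")


def table1_digest() -> str:
    """SHA-256 hex digest of the packaged reference table bytes."""
    return hashlib.sha256(_table1_path().read_bytes()).hexdigest()


def load_table1_fixture(check_digest: bool = True) -> pd.DataFrame:
    """Load and validate the packaged 80-cultivar reference table.

    Missing FTSWc ("/" or empty in the file) becomes NaN.  Validation pins
    the row count, column schema, leaf-size vocabulary, positive dry
    weights and, by default, the file digest.
    """
    if check_digest and table1_digest() != TABLE1_SHA256:
        raise ValueError("packaged reference table failed its integrity digest")
    df = pd.read_csv(_table1_path(), na_values=["/", ""])
    if list(df.columns) != TABLE1_COLUMNS:
        raise ValueError(f"unexpected reference-table columns: {list(df.columns)}")
    if len(df) != 80:
        raise ValueError(f"reference table must have 80 cultivars, found {len(df)}")
    if set(df["leaf_size"]) - {"small", "medium", "large"}:
        raise ValueError("unknown leaf sizes in reference table")
    if (df[["dw_drought_g", "dw_irrigated_g"]] <= 0).any().any():
        raise ValueError("dry weights must be positive")
    df["decade"] = df["decade"].astype(int)
    return df


@dataclass(frozen=True)
class SummaryReport:
    """Mean/min/max of one numeric column with the extreme cultivars named."""

    column: str
    n: int
    mean: float
    min: float
    max: float
    argmin: str
    argmax: str

    def rounded(self, ndigits: int = 2) -> dict:
        """Presentation view: values rounded half-to-even, names kept."""
        r = lambda v: float(np.round(v, ndigits))
        return {
            "column": self.column,
            "n": self.n,
            "mean": r(self.mean),
            "min": r(self.min),
            "max": r(self.max),
            "argmin": self.argmin,
            "argmax": self.argmax,
        }


def _summarize(df: pd.DataFrame, column: str) -> SummaryReport:
    sub = df.dropna(subset=[column])
    if sub.empty:
        raise ValueError(f"no defined values in column {column!r}")
    vals = sub[column]
    return SummaryReport(
        column=column,
        n=len(sub),
        mean=float(vals.mean()),
        min=float(vals.min()),
        max=float(vals.max()),
        argmin=str(sub.loc[vals.idxmin(), "cultivar"]),
        argmax=str(sub.loc[vals.idxmax(), "cultivar"]),
    )


def summarize_ftswc(table: pd.DataFrame) -> SummaryReport:
    """Mean/min/max FTSWc over cultivars with a defined threshold."""
    return _summarize(table, "ftswc")


def summarize_dry_weights(table: pd.DataFrame) -> dict[str, SummaryReport]:
    """Summaries of both dry-weight columns over all cultivars."""
    return {
        "drought": _summarize(table, "dw_drought_g"),
        "irrigated": _summarize(table, "dw_irrigated_g"),
    }


def rank_cultivars(table: pd.DataFrame, k: int = 5, column: str = "ftswc") -> dict[str, pd.DataFrame]:
    """Bottom-k (ascending) and top-k (descending) cultivars by ``column``.

    Ties are broken alphabetically by cultivar name; missing values are
    excluded.  Raises if fewer than ``k`` defined values exist.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    sub = table.dropna(subset=[column])[["cultivar", column]]
    if len(sub) < k:
        raise ValueError(f"k={k} exceeds the {len(sub)} defined values")
    bottom = sub.sort_values([column, "cultivar"], ascending=[True, True]).head(k)
    top = sub.sort_values([column, "cultivar"], ascending=[False, True]).head(k)
    return {
        "bottom": bottom.reset_index(drop=True),
        "top": top.reset_index(drop=True),
    }


# ---------------------------------------------------------------------------
# weighing CSV round trip
# ---------------------------------------------------------------------------

def read_weighing_csv(path) -> pd.DataFrame:
    """Read and validate a long-format weighing CSV.

    Bare pots carry no cultivar; an empty cultivar field reads back as ""
    rather than NaN so round trips are value-identical.
    """
    df = pd.read_csv(path)
    if "cultivar" in df.columns:
        df["cultivar"] = df["cultivar"].fillna("").astype(str)
    return validate_weighing(df)


def write_weighing_csv(df: pd.DataFrame, path) -> None:
    """Write a weighing table in the canonical column order."""
    validate_weighing(df)[WEIGHING_COLUMNS].to_csv(path, index=False)


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    """Write simulator ground truth: cultivar, ftswc_true, plateau_true, t_pot_g."""
    cols = ["cultivar", "ftswc_true", "plateau_true", "t_pot_g"]
    truth[cols].to_csv(path, index=False)
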