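"""Annual stock-assessment series and derived exploitation/productivity indices.

The central container is :class:`StockSeriesTable`: one row per calendar year
with spawning stock biomass (SSB, tonnes), recruitment at age 1 (count, in a
configurable unit), instantaneous fishing mortality F (per year) and annual
mean sea surface temperature SST (degrees C).  Two derived indices are always
carried alongside the observed columns:

``productivity``
    R/SSB — recruits produced per unit spawning biomass, an index of stock
    productivity.
``scaled_pressure``
    F/R — fishing mortality normalised by year-class strength, the
    exploitation pressure actually experienced per unit of incoming
    production.

Both indices are scale-covariant in the recruitment unit; every downstream
fit standardises covariates internally, so the unit choice cannot change any
segmentation, break placement or state classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class StockDataError(ValueError):
    """Base class for ingest and validation failures."""


class FormatError(StockDataError):
    """Input file or column-map problem (missing/unparseable columns)."""


class ValidationError(StockDataError):
    """Structurally valid input violating a domain invariant."""


#: canonical observed columns, in storage order
CORE_COLUMNS = ("year", "ssb", "recruitment", "f", "sst")
#: columns derived from the observed ones
DERIVED_COLUMNS = ("productivity", "scaled_pressure")

#: accepted spellings for variable names in configs and relationship lists
VARIABLE_ALIASES: Mapping[str, str] = {
    "year": "year",
    "ssb": "ssb",
    "r": "recruitment",
    "recruitment": "recruitment",
    "f": "f",
    "sst": "sst",
    "productivity": "productivity",
    "r/ssb": "productivity",
    "r_ssb": "productivity",
    "scaled_pressure": "scaled_pressure",
    "f/r": "scaled_pressure",
    "f_r": "scaled_pressure",
}


def resolve_variable(name: str) -> str:
    """Map a user-facing variable name (e.g. ``"F/R"``) to its column name."""
    key = str(name).strip().lower()
    if key not in VARIABLE_ALIASES:
        known = ", ".join(sorted(set(VARIABLE_ALIASES)))
        raise ValidationError(f"unknown variable {name!r}; known names: {known}")
    return VARIABLE_ALIASES[key]


def _check_years(years: np.ndarray) -> None:
    if len(years) == 0:
        raise ValidationError("empty table")
    diffs = np.diff(years)
    if np.any(diffs != 1):
        gaps = []
        for y0, d in zip(years[:-1], diffs):
            if d != 1:
                gaps.extend(range(int(y0) + 1, int(y0) + int(d)))
        if gaps:
            raise ValidationError(
                "years must be strictly consecutive; gap at "
                + ", ".join(str(g) for g in gaps)
            )
        raise ValidationError("years must be strictly increasing by 1")


@dataclass(frozen=True)
class StockSeriesTable:
    """Validated annual stock series with derived indices.

    Parameters
    ----------
    data
        Frame with columns ``year, ssb, recruitment, f, sst`` (derived
        columns are recomputed on construction).  Rows are sorted by year.
    recruitment_unit
        Free-text label for the recruitment unit (default ``"millions"``);
        carried for reporting only.
    """

    data: pd.DataFrame
    recruitment_unit: str = "millions"

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        try:
            years = df["year"].astype(float)
        except (TypeError, ValueError) as exc:  # pragma: no cover - pandas raises early
            raise FormatError("year column not parseable as integers") from exc
        if not np.allclose(years, np.round(years)):
            raise FormatError("year column not parseable as integers")
        df["year"] = np.round(years).astype(int)
        df = df.sort_values("year").reset_index(drop=True)
        _check_years(df["year"].to_numpy())

        for col in ("ssb", "recruitment", "f", "sst"):
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                bad = df["year"].to_numpy()[~np.isfinite(vals)]
                raise ValidationError(
                    f"column {col!r} has missing/non-finite values in years "
                    + ", ".join(str(int(y)) for y in bad)
                )
            df[col] = vals
        for col in ("ssb", "recruitment"):
            vals = df[col].to_numpy()
            if np.any(vals <= 0):
                bad = df["year"].to_numpy()[vals <= 0]
                raise ValidationError(
                    f"column {col!r} must be strictly positive; offending years: "
                    + ", ".join(str(int(y)) for y in bad)
                )
        df["productivity"] = df["recruitment"] / df["ssb"]
        df["scaled_pressure"] = df["f"] / df["recruitment"]
        object.__setattr__(self, "data", df[list(CORE_COLUMNS + DERIVED_COLUMNS)])

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def years(self) -> np.ndarray:
        return self.data["year"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        """Return a column by canonical name or alias."""
        return self.data[resolve_variable(name)].to_numpy(dtype=float)

    @property
    def ssb(self) -> np.ndarray:
        return self.column("ssb")

    @property
    def recruitment(self) -> np.ndarray:
        return self.column("recruitment")

    @property
    def f(self) -> np.ndarray:
        return self.column("f")

    @property
    def sst(self) -> np.ndarray:
        return self.column("sst")

    @property
    def productivity(self) -> np.ndarray:
        return self.column("productivity")

    @property
    def scaled_pressure(self) -> np.ndarray:
        return self.column("scaled_pressure")

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table (RFC-4180, header row, UTF-8) with a fixed float
        format so identical tables produce byte-identical files."""
        self.data.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_stock_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> StockSeriesTable:
    """Read an annual stock table from CSV and validate it.

    ``column_map`` maps canonical names (``year, ssb, recruitment, f, sst``)
    to the column headers actually present in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = pd.read_csv(path)
    column_map = dict(column_map or {})
    frame = {}
    for canon in CORE_COLUMNS:
        source = column_map.get(canon, canon)
        if source not in raw.columns:
            raise FormatError(f"missing column: {source!r} (for {canon!r})")
        frame[canon] = raw[source]
    return StockSeriesTable(pd.DataFrame(frame))


def derive_indices(table: StockSeriesTable) -> StockSeriesTable:
    """Recompute productivity (R/SSB) and scaled pressure (F/R).

    Idempotent: the constructor already maintains both indices, so a second
    call returns an equal table.
    """
    return StockSeriesTable(table.data[list(CORE_COLUMNS)].copy(),
                            recruitment_unit=table.recruitment_unit)


@dataclass(frozen=True)
class ReferenceLevels:
    """ICES-style biomass and fishing-mortality reference points.

    Used only to annotate reports; no computation depends on them.
    """

    b_lim: float
    msy_b_trigger: float
    f_msy: float
    f_pa: float

    def __post_init__(self) -> None:
        for name in ("b_lim", "msy_b_trigger", "f_msy", "f_pa"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"reference level {name} must be > 0")
        if self.b_lim > self.msy_b_trigger:
            raise ValidationError("b_lim must not exceed msy_b_trigger")


#: the six response~covariate relationships analysed by default
DEFAULT_RELATIONSHIPS: tuple[tuple[str, str], ...] = (
    ("ssb", "f"),
    ("ssb", "scaled_pressure"),
    ("recruitment", "ssb"),
    ("recruitment", "sst"),
    ("productivity", "ssb"),
    ("productivity", "sst"),
)

#: series scanned for mean changepoints by default
DEFAULT_CHANGEPOINT_SERIES: tuple[str, ...] = ("ssb", "recruitment", "productivity")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters shared across the three analysis stages."""

    min_segment_length: int = 10
    penalty_kind: str = "aic"
    max_breaks: int = 5
    min_break_fraction: float = 0.15
    seed: int = 0
    relationships: tuple[tuple[str, str], ...] = DEFAULT_RELATIONSHIPS
    changepoint_series: tuple[str, ...] = DEFAULT_CHANGEPOINT_SERIES
    state_var: str = "ssb"
    asym_var: str = "scaled_pressure"
    bifur_var: str = "sst"
    reference_levels: ReferenceLevels | None = None

    def __post_init__(self) -> None:
        if self.min_segment_length < 2:
            raise ValidationError("min_segment_length must be >= 2")
        if not (0.0 < self.min_break_fraction < 0.5):
            raise ValidationError("min_break_fraction must be in (0, 0.5)")
        if self.penalty_kind not in ("aic",):
            raise ValidationError(f"unknown penalty_kind {self.penalty_kind!r}")
        resolved = tuple(
            (resolve_variable(r), resolve_variable(c)) for r, c in self.relationships
        )
        object.__setattr__(self, "relationships", resolved)
        object.__setattr__(
            self,
            "changepoint_series",
            tuple(resolve_variable(s) for s in self.changepoint_series),
        )
        for name in ("state_var", "asym_var", "bifur_var"):
            object.__setattr__(self, name, resolve_variable(getattr(self, name)))

    def breakpoint_min_segment(self, n: int) -> int:
        """Minimum regime length for break estimation: ceil(fraction * n), >= 2."""
        return max(2, math.ceil(self.min_break_fraction * n))
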