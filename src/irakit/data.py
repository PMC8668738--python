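"""Annual multivariate tables and their preprocessing.

The exchange types are thin, validated wrappers around pandas objects:
:class:`AnnualMatrix` (years x variables), :class:`SeriesVector` (one value
per year) and :class:`CategoryMatrix` (traffic-light quintile codes).
Preprocessing covers LPUC construction (landings per unit of fleet
capacity, kg/GT), anomaly standardization, lagging, distance-correlation
screening of redundant variables, and quintile categorization for
traffic-light displays.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError

__all__ = [
    "AnnualMatrix",
    "SeriesVector",
    "CategoryMatrix",
    "compute_lpuc",
    "standardize",
    "lag_series",
    "distance_correlation",
    "prune_correlated",
    "quintile_categorize",
]


def _check_years(years: np.ndarray, min_len: int = 3) -> None:
    if len(years) < min_len:
        raise DataError(f"need at least {min_len} years, got {len(years)}")
    steps = np.diff(years)
    if not np.all(steps == 1):
        raise DataError("years must be strictly increasing with step 1")


@dataclass(frozen=True)
class AnnualMatrix:
    """A years x variables table of annual values.

    Invariants: consecutive calendar years (step 1), no missing cells,
    unique variable names, at least 3 years.
    """

    frame: pd.DataFrame  # index = years (int), columns = variable names

    def __post_init__(self) -> None:
        f = self.frame
        if not isinstance(f, pd.DataFrame):
            raise DataError("AnnualMatrix requires a DataFrame")
        years = np.asarray(f.index, dtype=int)
        _check_years(years)
        if f.columns.duplicated().any():
            dupes = f.columns[f.columns.duplicated()].tolist()
            raise DataError(f"duplicate variable names: {dupes}")
        if f.isna().any().any():
            raise DataError("missing cells are not allowed (no imputation)")
        object.__setattr__(
            self, "frame", f.astype(float).set_axis(years, axis=0)
        )

    @property
    def years(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def column(self, name: str) -> "SeriesVector":
        if name not in self.frame.columns:
            raise DataError(f"no variable named {name!r}")
        return SeriesVector(self.frame[name])

    @classmethod
    def from_arrays(
        cls, years, values, variables
    ) -> "AnnualMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=np.asarray(years, dtype=int),
                                columns=list(variables)))

    @classmethod
    def read_csv(cls, path) -> "AnnualMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.columns[0] != "year":
            raise DataError(
                f"first CSV column must be 'year', got {df.columns[0]!r}"
            )
        df = df.set_index("year")
        return cls(df)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "year"
        out.to_csv(path)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnualMatrix) and self.frame.equals(other.frame)


@dataclass(frozen=True)
class SeriesVector:
    """One annual series: a value per consecutive calendar year."""

    series: pd.Series  # index = years (int)

    def __post_init__(self) -> None:
        s = self.series
        if not isinstance(s, pd.Series):
            raise DataError("SeriesVector requires a Series")
        years = np.asarray(s.index, dtype=int)
        # length 1 admitted: lagging and windowing legitimately shorten series
        _check_years(years, min_len=1)
        if s.isna().any():
            raise DataError("missing values are not allowed")
        object.__setattr__(
            self, "series", s.astype(float).set_axis(years)
        )

    @property
    def years(self) -> np.ndarray:
        return self.series.index.to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy()

    @property
    def label(self) -> str:
        return str(self.series.name)

    def __len__(self) -> int:
        return len(self.series)

    @classmethod
    def from_arrays(cls, years, values, label="series") -> "SeriesVector":
        return cls(pd.Series(np.asarray(values, dtype=float),
                             index=np.asarray(years, dtype=int), name=label))


@dataclass(frozen=True)
class CategoryMatrix:
    """Traffic-light quintile codes (1..5), rows in a stated variable order."""

    frame: pd.DataFrame  # index = variables (ordered), columns = years

    @property
    def years(self) -> np.ndarray:
        return self.frame.columns.to_numpy()

    @property
    def variables(self) -> list[str]:
        return list(self.frame.index)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "variable"
        out.to_csv(path)


def _aligned_values(x: SeriesVector, y: SeriesVector) -> tuple[np.ndarray, np.ndarray]:
    if len(x) != len(y) or not np.array_equal(x.years, y.years):
        raise AlignmentError(
            f"series are not aligned: {x.years[[0, -1]]} vs {y.years[[0, -1]]}"
        )
    return x.values, y.values


def compute_lpuc(landings: AnnualMatrix, capacity: SeriesVector) -> AnnualMatrix:
    """Landings per unit of capacity: landings[year, taxon] / capacity[year].

    ``landings`` in kg per taxon, ``capacity`` the fleet gross tonnage (GT);
    the result is a biomass proxy in kg/GT. Capacity must be strictly
    positive and cover exactly the landings years.
    """
    if not np.array_equal(landings.years, capacity.years):
        raise AlignmentError("landings and capacity must cover identical years")
    cap = capacity.values
    if np.any(cap <= 0):
        bad = capacity.years[cap <= 0]
        raise DataError(f"capacity must be strictly positive; bad years: {bad.tolist()}")
    return AnnualMatrix(landings.frame.div(cap, axis=0))


def standardize(m: AnnualMatrix) -> AnnualMatrix:
    """Anomaly-standardize each variable: (x - mean) / sd, sd with n-1."""
    vals = m.values
    sd = vals.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [m.variables[i] for i in zero]
        raise DataError(f"zero-variance variables cannot be standardized: {names}")
    out = (vals - vals.mean(axis=0)) / sd
    return AnnualMatrix.from_arrays(m.years, out, m.variables)


def lag_series(x: SeriesVector, lag: int) -> SeriesVector:
    """Shift a series forward in time by ``lag`` years.

    The returned series assigns to year t the value of year t - lag; the
    first ``lag`` years (which have no lagged value) are dropped.
    """
    if lag < 0:
        raise DataError("lag must be non-negative")
    if lag >= len(x):
        raise DataError(f"lag {lag} >= series length {len(x)}")
    if lag == 0:
        return x
    return SeriesVector.from_arrays(
        x.years[lag:], x.values[:-lag], f"{x.label}_lag{lag}"
    )


def _double_centered_distances(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()


def distance_correlation(x: SeriesVector, y: SeriesVector) -> float:
    """Empirical distance correlation (energy statistics) of two series.

    Double-centers the pairwise-distance matrices of each series and
    returns dCov / sqrt(dVarx * dVary); 0 if either distance variance
    vanishes. Detects non-linear as well as linear dependence and is 0
    iff the samples look independent.
    """
    xv, yv = _aligned_values(x, y)
    if len(xv) < 3:
        raise DataError("distance correlation needs at least 3 observations")
    a = _double_centered_distances(xv)
    b = _double_centered_distances(yv)
    dcov2 = (a * b).mean()
    dvarx = (a * a).mean()
    dvary = (b * b).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


@dataclass(frozen=True)
class PruneReport:
    """Record of one dropped variable during correlation screening."""

    dropped: str
    kept: str
    dcor: float


def prune_correlated(
    m: AnnualMatrix, threshold: float = 0.9
) -> tuple[AnnualMatrix, list[PruneReport]]:
    """Greedy redundancy screen: drop variables too correlated with a kept one.

    Walks the variables in column order; a variable whose distance
    correlation with any already-retained variable exceeds ``threshold``
    is dropped. Returns the reduced matrix and a report of
    (dropped, kept, dCor) triples.
    """
    if not 0 < threshold < 1:
        raise DataError(f"threshold must be in (0,1), got {threshold}")
    kept: list[str] = []
    reports: list[PruneReport] = []
    for name in m.variables:
        col = m.column(name)
        hit = None
        for k in kept:
            d = distance_correlation(col, m.column(k))
            if d > threshold:
                hit = PruneReport(dropped=name, kept=k, dcor=d)
                break
        if hit is None:
            kept.append(name)
        else:
            reports.append(hit)
    return AnnualMatrix(m.frame[kept]), reports


def quintile_categorize(m: AnnualMatrix, variable_order: list[str]) -> CategoryMatrix:
    """Traffic-light categorization: per-variable quintile codes 1..5.

    Each variable's raw values are binned by its own empirical 20/40/60/80
    percentiles (linear interpolation); ties go to the lowest admissible
    quintile. Rows are emitted in ``variable_order`` (normally ranked by
    PC1 loading).
    """
    if sorted(variable_order) != sorted(m.variables):
        raise DataError("variable_order must be a permutation of the variables")
    rows = {}
    for name in variable_order:
        v = m.frame[name].to_numpy()
        breaks = np.percentile(v, [20, 40, 60, 80])
        rows[name] = np.searchsorted(breaks, v, side="left") + 1
    frame = pd.DataFrame(rows, index=m.years).T
    frame = frame.loc[variable_order]
    return CategoryMatrix(frame)
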