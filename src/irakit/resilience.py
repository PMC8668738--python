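"""Attractors, tipping points, annual resilience and the folded
stability landscape.

The branches of the optimal TGAM stage fits are taken as the alternate
attractors of the system in the (stressor score, system score) plane.
Tipping points are placed on the stressor axis so that every year's
resilience within its regime is non-negative, with equality for the
binding year: resilience of a year is

    Res_y = hComp_y - vComp_y

where hComp is the distance of the year's stressor score to its regime's
(nearest) tipping point and vComp the vertical distance of the year to
its fitted attractor. Relative resilience rRes = Res / max(Res) is
interpolated piecewise-linearly (Delaunay) onto a 100 x 100 grid; two
theoretical repulsion "years" between the fold pairs keep the landscape
from bridging basins with spurious high-resilience corridors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .errors import DataError
from .tgam import GamFit, TgamFit

__all__ = [
    "SystemStates",
    "Attractor",
    "TippingPoint",
    "ResilienceSeries",
    "StabilityLandscape",
    "assign_regimes",
    "build_attractors",
    "place_tipping_points",
    "compute_resilience",
    "insert_repulsion_states",
    "interpolate_landscape",
]

_CURVE_POINTS = 200


@dataclass(frozen=True)
class SystemStates:
    """Per-year (stressor score, system score) states with regime labels.

    ``regime`` is 1-based; excluded years (e.g. a final year outside all
    observed ranges) carry regime 0 and take no part in attractor,
    tipping-point or basin computation."""

    years: np.ndarray
    x: np.ndarray  # stressor score (PC1str)
    y: np.ndarray  # system score (PC1sys)
    regime: np.ndarray


def assign_regimes(
    years: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    threshold_years: list[int],
    exclude_years: tuple[int, ...] = (),
) -> SystemStates:
    """Label years by the threshold years (last year of each old regime)."""
    years = np.asarray(years)
    regime = np.ones(len(years), dtype=int)
    for t in sorted(threshold_years):
        regime[years > t] += 1
    for y_ex in exclude_years:
        regime[years == y_ex] = 0
    return SystemStates(years=years, x=np.asarray(x, dtype=float),
                        y=np.asarray(y, dtype=float), regime=regime)


@dataclass(frozen=True)
class Attractor:
    """One regime's fitted response curve with linear end extensions."""

    regime: int
    year_range: tuple[int, int]
    curve_x: np.ndarray  # dense grid over the regime's observed stressor range
    curve_y: np.ndarray
    end_slopes: tuple[float, float]  # (left, right)

    def value(self, xq) -> np.ndarray:
        """Curve value at xq, continuing linearly outside the range."""
        xq = np.atleast_1d(np.asarray(xq, dtype=float))
        lo, hi = self.curve_x[0], self.curve_x[-1]
        out = np.interp(np.clip(xq, lo, hi), self.curve_x, self.curve_y)
        below, above = xq < lo, xq > hi
        out[below] = self.curve_y[0] + self.end_slopes[0] * (xq[below] - lo)
        out[above] = self.curve_y[-1] + self.end_slopes[1] * (xq[above] - hi)
        return out


@dataclass(frozen=True)
class TippingPoint:
    label: str  # F1..F4
    x: float
    regime: int
    direction: int  # +1: bounds the basin toward increasing stressor


@dataclass(frozen=True)
class ResilienceSeries:
    """Per-year resilience components and the normalized landscape value."""

    table: pd.DataFrame  # year, regime, x, y, hcomp, vcomp, res, rres

    @property
    def max_res(self) -> float:
        return float(self.table["res"].max())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class StabilityLandscape:
    grid_x: np.ndarray  # 100
    grid_y: np.ndarray  # 100
    rres: np.ndarray  # 100 x 100, NaN outside the convex hull
    points: pd.DataFrame  # the augmented (x, y, rres) point set used

    def to_long_csv(self, path) -> None:
        gx, gy = np.meshgrid(self.grid_x, self.grid_y, indexing="ij")
        pd.DataFrame(
            {"x": gx.ravel(), "y": gy.ravel(), "rres": self.rres.ravel()}
        ).to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        z = [[None if np.isnan(v) else float(v) for v in row] for row in self.rres]
        return {
            "grid_x": self.grid_x.tolist(),
            "grid_y": self.grid_y.tolist(),
            "rres": z,
        }


def _branch_curve(fit: GamFit, regime: int, years: np.ndarray,
                  x: np.ndarray) -> Attractor:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-9:
        cx = np.array([lo - 1e-6, lo + 1e-6])
        cy = fit.predict(np.array([lo, lo]))
        return Attractor(regime=regime, year_range=(int(years.min()), int(years.max())),
                         curve_x=cx, curve_y=cy, end_slopes=(0.0, 0.0))
    cx = np.linspace(lo, hi, _CURVE_POINTS)
    cy = fit.predict(cx)
    sl = (
        float((cy[1] - cy[0]) / (cx[1] - cx[0])),
        float((cy[-1] - cy[-2]) / (cx[-1] - cx[-2])),
    )
    return Attractor(regime=regime, year_range=(int(years.min()), int(years.max())),
                     curve_x=cx, curve_y=cy, end_slopes=sl)


def build_attractors(stage_fits: list[TgamFit], states: SystemStates) -> list[Attractor]:
    """Map TGAM stage branches to regime attractors.

    One stage fit yields 2 regimes (its two branches); two stage fits
    yield 3 (stage 1's first branch, then stage 2's two branches). Each
    curve is evaluated over its regime's observed stressor range.
    """
    if len(stage_fits) not in (1, 2):
        raise DataError("need 1 or 2 stage fits")
    n_regimes = len(stage_fits) + 1
    observed = states.regime[states.regime > 0]
    if observed.max() != n_regimes:
        raise DataError(
            f"states label {observed.max()} regimes but fits imply {n_regimes}"
        )
    if len(stage_fits) == 1:
        branch_fits = [stage_fits[0].branch_before, stage_fits[0].branch_after]
    else:
        branch_fits = [
            stage_fits[0].branch_before,
            stage_fits[1].branch_before,
            stage_fits[1].branch_after,
        ]
    attractors = []
    for regime, fit in enumerate(branch_fits, start=1):
        mask = states.regime == regime
        if not mask.any():
            raise DataError(f"regime {regime} has no assigned years")
        attractors.append(
            _branch_curve(fit, regime, states.years[mask], states.x[mask])
        )
    return attractors


def _vcomp(states: SystemStates, attractors: list[Attractor]) -> np.ndarray:
    v = np.full(len(states.years), np.nan)
    for a in attractors:
        mask = states.regime == a.regime
        v[mask] = np.abs(states.y[mask] - a.value(states.x[mask]))
    return v


def place_tipping_points(
    attractors: list[Attractor], states: SystemStates
) -> list[TippingPoint]:
    """Place the fold points F1..F4 (F1, F2 for a two-regime system).

    Each regime is bounded on the side(s) facing its neighboring
    regime(s) — the middle regime of a three-regime system on both
    sides. For a side toward increasing stressor the tipping point is
    max over the regime's years of (x_y + vComp_y); toward decreasing,
    min of (x_y - vComp_y). This makes every within-regime Res_y
    non-negative with equality for the binding year.
    """
    v = _vcomp(states, attractors)
    n_reg = len(attractors)
    mean_x = []
    for a in attractors:
        mask = states.regime == a.regime
        mean_x.append(states.x[mask].mean())
    # fold-wise sides: for each fold between regime r and r+1, the tip of
    # regime r facing r+1 and the tip of regime r+1 facing back
    sides: list[tuple[int, int]] = []  # (regime, direction)
    for r in range(1, n_reg):
        d = 1 if mean_x[r] >= mean_x[r - 1] else -1
        sides.append((r, d))
        sides.append((r + 1, -d))
    tips = []
    for i, (r, d) in enumerate(sides):
        mask = states.regime == r
        if not mask.any():
            raise DataError(f"regime {r} is empty")
        if d > 0:
            xt = float(np.max(states.x[mask] + v[mask]))
        else:
            xt = float(np.min(states.x[mask] - v[mask]))
        tips.append(TippingPoint(label=f"F{i + 1}", x=xt, regime=r, direction=d))
    return tips


def compute_resilience(
    states: SystemStates,
    attractors: list[Attractor],
    tipping_points: list[TippingPoint],
) -> ResilienceSeries:
    """Res_y = hComp_y - vComp_y per assigned year; rRes_y = Res_y / max.

    hComp is the distance to the regime's nearest tipping point along
    the stressor axis, vComp the vertical distance to the regime's
    attractor (using its linear extension when needed)."""
    v = _vcomp(states, attractors)
    rows = []
    for i, year in enumerate(states.years):
        r = states.regime[i]
        if r == 0:
            rows.append((int(year), 0, states.x[i], states.y[i],
                         np.nan, np.nan, np.nan))
            continue
        own_tips = [t for t in tipping_points if t.regime == r]
        if not own_tips:
            raise DataError(f"regime {r} has no tipping point")
        h = min(abs(states.x[i] - t.x) for t in own_tips)
        rows.append((int(year), int(r), states.x[i], states.y[i],
                     h, v[i], h - v[i]))
    table = pd.DataFrame(
        rows, columns=["year", "regime", "x", "y", "hcomp", "vcomp", "res"]
    )
    max_res = table["res"].max()
    if not max_res > 0:
        raise DataError("maximum resilience is not positive; degenerate geometry")
    table["rres"] = table["res"] / max_res
    return ResilienceSeries(table=table)


def insert_repulsion_states(
    tipping_points: list[TippingPoint],
    attractors: list[Attractor],
    resilience: ResilienceSeries,
) -> pd.DataFrame:
    """Augment the observed point set with one theoretical repulsion
    "year" per fold pair (between F1–F2 and F3–F4).

    Each synthetic state sits at the midpoint stressor coordinate of its
    fold pair, midway between the two adjacent attractors, and its
    resilience uses the same hComp - vComp rule with the nearer tipping
    point and nearer attractor; normalization reuses the observed
    maximum. Returns the augmented long-form (x, y, rres) table."""
    obs = resilience.table
    pts = obs.loc[obs["regime"] > 0, ["x", "y", "rres"]].copy()
    pts["kind"] = "year"
    max_res = obs["res"].max()
    synth = []
    for i in range(0, len(tipping_points) - 1, 2):
        t_a, t_b = tipping_points[i], tipping_points[i + 1]
        a_a = next(a for a in attractors if a.regime == t_a.regime)
        a_b = next(a for a in attractors if a.regime == t_b.regime)
        xm = 0.5 * (t_a.x + t_b.x)
        ya, yb = float(a_a.value(xm)[0]), float(a_b.value(xm)[0])
        ym = 0.5 * (ya + yb)
        h = min(abs(xm - t_a.x), abs(xm - t_b.x))
        v = min(abs(ym - ya), abs(ym - yb))
        synth.append({"x": xm, "y": ym, "rres": (h - v) / max_res, "kind": "repulsion"})
    return pd.concat([pts, pd.DataFrame(synth)], ignore_index=True)


def interpolate_landscape(points: pd.DataFrame, grid_n: int = 100) -> StabilityLandscape:
    """Piecewise-linear (Delaunay) interpolation of rRes onto a grid.

    The grid spans the bounding box of the point set; cells outside the
    convex hull are NaN; the surface reproduces the input values at the
    input points exactly."""
    if len(points) < 3:
        raise DataError("need at least 3 points to interpolate")
    xy = points[["x", "y"]].to_numpy()
    z = points["rres"].to_numpy()
    try:
        interp = LinearNDInterpolator(xy, z)
    except QhullError as exc:
        raise DataError(f"point set is degenerate (collinear?): {exc}") from exc
    gx = np.linspace(xy[:, 0].min(), xy[:, 0].max(), grid_n)
    gy = np.linspace(xy[:, 1].min(), xy[:, 1].max(), grid_n)
    mx, my = np.meshgrid(gx, gy, indexing="ij")
    zz = interp(mx, my)
    return StabilityLandscape(grid_x=gx, grid_y=gy, rres=zz, points=points)
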