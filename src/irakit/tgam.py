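"""GAM and threshold-GAM (TGAM) modelling of the system–stressor relation.

The smooth is a penalized cubic B-spline on uniform knots (P-spline) with
the smoothing parameter chosen by generalized cross-validation,
GCV = n RSS / (n - edf)^2. A TGAM splits the years at a threshold year
into two independent branches, one smooth each, and searches the
threshold over a grid of candidate years between quantiles of the year
range by minimizing the combined GCV. Model classes are compared by the
"genuine" cross-validatory squared prediction error (gCV): leave-one-out
prediction error in which the *entire* procedure — threshold search
included — is re-estimated on every fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .data import SeriesVector, lag_series
from .errors import AlignmentError, DataError, NumericalError

__all__ = [
    "GamFit",
    "TgamFit",
    "ModelComparison",
    "SequentialResult",
    "fit_pspline_gam",
    "fit_tgam",
    "genuine_cv",
    "compare_models",
    "detect_regimes_sequential",
]

_LAMBDA_GRID = np.logspace(-7, 9, 49)
_DEGENERATE_SPAN = 1e-10


# ---------------------------------------------------------------------------
# penalized spline core

@dataclass(frozen=True)
class GamFit:
    """One fitted penalized-spline smooth of y on x.

    Predictions outside the training x-range continue linearly with the
    boundary slope.
    """

    knots: np.ndarray | None  # None for a degenerate (zero x-span) fit
    coefs: np.ndarray | None
    x_range: tuple[float, float]
    mean_value: float  # used by degenerate fits
    lambda_: float
    edf: float
    rss: float
    gcv: float
    deviance_explained: float
    n: int

    def predict(self, xnew) -> np.ndarray:
        x = np.atleast_1d(np.asarray(xnew, dtype=float))
        lo, hi = self.x_range
        if self.knots is None:
            out = np.full_like(x, self.mean_value)
            return out
        spline = BSpline(self.knots, self.coefs, 3, extrapolate=False)
        deriv = spline.derivative()
        xc = np.clip(x, lo, hi)
        out = spline(xc)
        below = x < lo
        above = x > hi
        if below.any():
            out[below] = spline(lo) + deriv(lo) * (x[below] - lo)
        if above.any():
            out[above] = spline(hi) + deriv(hi) * (x[above] - hi)
        return out


def _second_difference_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


def _fit_pspline(xv: np.ndarray, yv: np.ndarray, k: int) -> GamFit:
    """Penalized cubic B-spline fit with GCV-selected lambda.

    Uniform knots over [min x, max x], second-difference coefficient
    penalty; ties in GCV resolve toward the smoother (larger lambda)
    fit. Degenerate x-spans fall back to the mean model.
    """
    n = len(xv)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    lo, hi = float(xv.min()), float(xv.max())
    if hi - lo < _DEGENERATE_SPAN:
        rss = tss
        return GamFit(
            knots=None, coefs=None, x_range=(lo, hi), mean_value=float(yv.mean()),
            lambda_=np.inf, edf=1.0, rss=rss,
            gcv=n * rss / (n - 1) ** 2,
            deviance_explained=0.0 if tss > 0 else 1.0, n=n,
        )
    k = max(4, min(k, n))
    d = (hi - lo) / (k - 3)
    knots = lo + d * (np.arange(k + 4) - 3.0)
    knots[3], knots[-4] = lo, hi  # pin the boundary knots against rounding
    b = BSpline.design_matrix(np.clip(xv, lo, hi), knots, 3,
                              extrapolate=False).toarray()
    s = b.T @ b
    p = _second_difference_penalty(k)
    ridge = 1e-10 * (np.trace(s) / k + 1.0)
    s_r = s + ridge * np.eye(k)
    try:
        from scipy.linalg import eigh

        mu, v = eigh(p, s_r)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"spline fit failed: {exc}") from exc
    mu = np.clip(mu, 0.0, None)
    c = b @ v
    z = v.T @ (b.T @ yv)
    shrink = 1.0 / (1.0 + np.outer(_LAMBDA_GRID, mu))  # n_lambda x k
    resid = yv[None, :] - shrink * z @ c.T  # n_lambda x n
    rss_all = np.einsum("ij,ij->i", resid, resid)
    edf_all = shrink.sum(axis=1)
    denom = n - edf_all
    with np.errstate(divide="ignore", invalid="ignore"):
        gcv_all = np.where(denom > 0, n * rss_all / denom**2, np.inf)
    # scan ascending lambda, preferring the smoother fit on (near-)ties
    best = 0
    for i in range(1, len(_LAMBDA_GRID)):
        if gcv_all[i] <= gcv_all[best] * (1 + 1e-9):
            best = i
    gcv, lam, edf, rss = (float(gcv_all[best]), float(_LAMBDA_GRID[best]),
                          float(edf_all[best]), float(rss_all[best]))
    coefs = z * shrink[best]
    return GamFit(
        knots=knots, coefs=v @ coefs, x_range=(lo, hi), mean_value=float(yv.mean()),
        lambda_=lam, edf=edf, rss=rss, gcv=gcv,
        deviance_explained=1.0 - rss / tss if tss > 0 else 1.0, n=n,
    )


def _aligned(x: SeriesVector, y: SeriesVector) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not np.array_equal(x.years, y.years):
        raise AlignmentError("x and y must cover identical years")
    return x.years, x.values, y.values


def fit_pspline_gam(x: SeriesVector, y: SeriesVector, basis_dim: int = 5) -> GamFit:
    """Gaussian identity-link penalized cubic regression spline of y on x."""
    if basis_dim < 3:
        raise DataError("basis_dim must be >= 3")
    _, xv, yv = _aligned(x, y)
    if len(xv) < basis_dim + 2:
        raise DataError(
            f"need at least basis_dim + 2 = {basis_dim + 2} points, got {len(xv)}"
        )
    return _fit_pspline(xv, yv, max(4, basis_dim))


# ---------------------------------------------------------------------------
# threshold GAM

@dataclass(frozen=True)
class TgamFit:
    """A two-branch threshold GAM: separate smooths before/after a
    threshold year, threshold chosen by minimum combined GCV."""

    threshold_year: int
    branch_before: GamFit  # years <= threshold
    branch_after: GamFit  # years > threshold
    gcv: float  # combined: n (RSS1 + RSS2) / (n - edf1 - edf2)^2
    rss: float
    deviance_explained: float
    candidate_years: np.ndarray
    candidate_gcv: np.ndarray
    n: int

    def predict(self, xnew, years) -> np.ndarray:
        x = np.atleast_1d(np.asarray(xnew, dtype=float))
        yr = np.atleast_1d(np.asarray(years))
        out = np.empty_like(x)
        before = yr <= self.threshold_year
        out[before] = self.branch_before.predict(x[before])
        out[~before] = self.branch_after.predict(x[~before])
        return out


def _candidate_years(years: np.ndarray, q_low: float, q_high: float,
                     n_candidates: int) -> np.ndarray:
    lo, hi = np.quantile(years, [q_low, q_high])
    grid = np.unique(np.round(np.linspace(lo, hi, n_candidates)).astype(int))
    return grid


def fit_tgam(
    x: SeriesVector,
    y: SeriesVector,
    q_low: float = 0.2,
    q_high: float = 0.8,
    n_candidates: int = 50,
    basis_dim: int = 5,
    min_branch: int = 4,
) -> TgamFit:
    """Fit a TGAM: search candidate threshold years (an evenly spaced,
    whole-year, de-duplicated grid between the q_low and q_high
    quantiles of the year range) and keep the split minimizing the
    combined GCV; ties go to the earliest year."""
    years, xv, yv = _aligned(x, y)
    n = len(xv)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    candidates = _candidate_years(years, q_low, q_high, n_candidates)
    rows = []
    best = None
    for theta in candidates:
        before = years <= theta
        n1, n2 = int(before.sum()), int((~before).sum())
        if n1 < min_branch or n2 < min_branch:
            rows.append((theta, np.inf))
            continue
        f1 = _fit_pspline(xv[before], yv[before], min(basis_dim, n1))
        f2 = _fit_pspline(xv[~before], yv[~before], min(basis_dim, n2))
        denom = n - f1.edf - f2.edf
        gcv = n * (f1.rss + f2.rss) / denom**2 if denom > 0 else np.inf
        rows.append((theta, gcv))
        if best is None or gcv < best[0]:
            best = (gcv, theta, f1, f2)
    if best is None:
        raise DataError("no candidate threshold admits two viable branches")
    gcv, theta, f1, f2 = best
    rss = f1.rss + f2.rss
    return TgamFit(
        threshold_year=int(theta),
        branch_before=f1,
        branch_after=f2,
        gcv=gcv,
        rss=rss,
        deviance_explained=1.0 - rss / tss if tss > 0 else 1.0,
        candidate_years=np.array([r[0] for r in rows]),
        candidate_gcv=np.array([r[1] for r in rows]),
        n=n,
    )


# ---------------------------------------------------------------------------
# genuine cross-validation

def genuine_cv(
    x: SeriesVector,
    y: SeriesVector,
    model_kind: str = "gam",
    basis_dim: int = 5,
    q_low: float = 0.2,
    q_high: float = 0.8,
    n_candidates: int = 50,
    fixed_threshold: int | None = None,
    return_report: bool = False,
):
    """Leave-one-out squared prediction error with full re-estimation.

    For every held-out year the entire procedure is refit on the
    remaining years — smoothing-parameter selection and, for a TGAM, the
    threshold search — and the held-out response is predicted (a
    held-out year falls to the branch its year side implies). Folds
    whose refit is unfittable are predicted by the global fit and
    flagged. ``model_kind``: "gam", "tgam" or "mean" (intercept-only,
    mainly for verification). ``fixed_threshold`` freezes the TGAM
    threshold instead of re-searching per fold (non-default shortcut).
    """
    years, xv, yv = _aligned(x, y)
    n = len(xv)
    if model_kind not in {"gam", "tgam", "mean"}:
        raise DataError(f"unknown model_kind {model_kind!r}")

    # LOO breaks the consecutive-year invariant, so folds work on raw arrays
    errors = np.empty(n)
    flagged: list[int] = []
    global_pred = None
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        try:
            pred = _fold_predict(model_kind, years, xv, yv, tr, i,
                                 basis_dim, q_low, q_high, n_candidates,
                                 fixed_threshold)
        except (DataError, NumericalError):
            if global_pred is None:
                global_pred = _global_predict(model_kind, years, xv, yv,
                                              basis_dim, q_low, q_high,
                                              n_candidates, fixed_threshold)
            pred = global_pred[i]
            flagged.append(int(years[i]))
        errors[i] = (yv[i] - pred) ** 2
    gcv = float(errors.mean())
    if return_report:
        return gcv, {"fallback_years": flagged, "per_year_sq_error": errors}
    return gcv


def _fold_predict(model_kind, years, xv, yv, tr, i, basis_dim,
                  q_low, q_high, n_candidates, fixed_threshold) -> float:
    if model_kind == "mean":
        return float(yv[tr].mean())
    if model_kind == "gam":
        f = _fit_pspline(xv[tr], yv[tr], basis_dim)
        return float(f.predict(xv[i])[0])
    if fixed_threshold is not None:
        theta = fixed_threshold
    else:
        theta = _search_threshold(years[tr], xv[tr], yv[tr],
                                  q_low, q_high, n_candidates, basis_dim)
    before = years[tr] <= theta
    if before.sum() < 2 or (~before).sum() < 2:
        raise DataError("branch too small in fold")
    if years[i] <= theta:
        f = _fit_pspline(xv[tr][before], yv[tr][before], basis_dim)
    else:
        f = _fit_pspline(xv[tr][~before], yv[tr][~before], basis_dim)
    return float(f.predict(xv[i])[0])


def _search_threshold(years, xv, yv, q_low, q_high, n_candidates,
                      basis_dim, min_branch: int = 4) -> int:
    n = len(xv)
    best = None
    for theta in _candidate_years(years, q_low, q_high, n_candidates):
        before = years <= theta
        n1, n2 = int(before.sum()), int((~before).sum())
        if n1 < min_branch or n2 < min_branch:
            continue
        f1 = _fit_pspline(xv[before], yv[before], min(basis_dim, n1))
        f2 = _fit_pspline(xv[~before], yv[~before], min(basis_dim, n2))
        denom = n - f1.edf - f2.edf
        gcv = n * (f1.rss + f2.rss) / denom**2 if denom > 0 else np.inf
        if best is None or gcv < best[0]:
            best = (gcv, int(theta))
    if best is None:
        raise DataError("no viable threshold in fold")
    return best[1]


def _global_predict(model_kind, years, xv, yv, basis_dim, q_low, q_high,
                    n_candidates, fixed_threshold) -> np.ndarray:
    if model_kind == "mean":
        return np.full(len(yv), yv.mean())
    if model_kind == "gam":
        return _fit_pspline(xv, yv, basis_dim).predict(xv)
    theta = (fixed_threshold if fixed_threshold is not None
             else _search_threshold(years, xv, yv, q_low, q_high,
                                    n_candidates, basis_dim))
    before = years <= theta
    f1 = _fit_pspline(xv[before], yv[before], basis_dim)
    f2 = _fit_pspline(xv[~before], yv[~before], basis_dim)
    out = np.empty(len(yv))
    out[before] = f1.predict(xv[before])
    out[~before] = f2.predict(xv[~before])
    return out


# ---------------------------------------------------------------------------
# model comparison across lags, sequential detection

@dataclass(frozen=True)
class ModelComparison:
    """Per-lag GAM vs TGAM gCV table; best = (lag, model) of minimum gCV."""

    table: pd.DataFrame  # columns: lag, gam_gcv, gam_dev, tgam_gcv, tgam_dev, threshold_year
    best_lag: int
    best_model: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _align_lagged(system: SeriesVector, stressor: SeriesVector, lag: int):
    lagged = lag_series(stressor, lag)
    common = np.intersect1d(system.years, lagged.years)
    if len(common) < 10:
        raise DataError(f"too few overlapping years at lag {lag}")
    sy = SeriesVector(system.series.loc[common])
    st = SeriesVector(lagged.series.loc[common])
    return st, sy


def compare_models(
    system_pc1: SeriesVector,
    stressor_pc1: SeriesVector,
    lags: tuple[int, ...] = (0, 1, 2),
    basis_dim: int = 5,
    q_low: float = 0.2,
    q_high: float = 0.8,
    n_candidates: int = 50,
) -> ModelComparison:
    """GAM vs TGAM of the system score on the (lagged) stressor score.

    For each lag the stressor is shifted, both models are fitted, and
    their genuine cross-validatory prediction errors and full-data
    deviances explained are tabulated; the minimum-gCV (lag, model)
    combination is flagged."""
    rows = []
    for lag in lags:
        st, sy = _align_lagged(system_pc1, stressor_pc1, lag)
        gam = fit_pspline_gam(st, sy, basis_dim)
        tg = fit_tgam(st, sy, q_low, q_high, n_candidates, basis_dim)
        gam_gcv = genuine_cv(st, sy, "gam", basis_dim)
        tgam_gcv = genuine_cv(st, sy, "tgam", basis_dim, q_low, q_high, n_candidates)
        rows.append(
            {
                "lag": lag,
                "gam_gcv": gam_gcv,
                "gam_dev": gam.deviance_explained,
                "tgam_gcv": tgam_gcv,
                "tgam_dev": tg.deviance_explained,
                "threshold_year": tg.threshold_year,
            }
        )
    table = pd.DataFrame(rows)
    stacked = pd.concat(
        [
            table[["lag", "gam_gcv"]].rename(columns={"gam_gcv": "gcv"}).assign(model="gam"),
            table[["lag", "tgam_gcv"]].rename(columns={"tgam_gcv": "gcv"}).assign(model="tgam"),
        ],
        ignore_index=True,
    )
    winner = stacked.loc[stacked["gcv"].idxmin()]
    return ModelComparison(
        table=table, best_lag=int(winner["lag"]), best_model=str(winner["model"])
    )


@dataclass(frozen=True)
class SequentialResult:
    """Outcome of the two-stage TGAM regime search."""

    stages: list[TgamFit]
    gcv_gam: list[float]  # per stage, the competing GAM's gCV
    gcv_tgam: list[float]
    warnings: list[str]

    @property
    def threshold_years(self) -> list[int]:
        return [s.threshold_year for s in self.stages]


def detect_regimes_sequential(
    system_pc1: SeriesVector,
    stressor_pc1: SeriesVector,
    basis_dim: int = 5,
    q_low: float = 0.2,
    q_high: float = 0.8,
    n_candidates: int = 50,
    exclude_last: int = 1,
    min_stage2_years: int = 10,
) -> SequentialResult:
    """Two-stage threshold detection.

    Stage 1 fits the full-series TGAM and keeps it only if its gCV beats
    the GAM's. Stage 2 restricts to the years strictly after the first
    threshold — trimming the final ``exclude_last`` year(s), which may
    belong to a state not yet established — and again keeps the TGAM
    only if its gCV beats the window's GAM. No further recursion."""
    st, sy = _align_lagged(system_pc1, stressor_pc1, 0)
    notes: list[str] = []
    gam_gcv = genuine_cv(st, sy, "gam", basis_dim)
    tgam_gcv = genuine_cv(st, sy, "tgam", basis_dim, q_low, q_high, n_candidates)
    if not tgam_gcv < gam_gcv:
        notes.append("stage 1: GAM favored by gCV; no threshold retained")
        return SequentialResult([], [gam_gcv], [tgam_gcv], notes)
    stage1 = fit_tgam(st, sy, q_low, q_high, n_candidates, basis_dim)
    stages = [stage1]
    gams, tgams = [gam_gcv], [tgam_gcv]

    last_year = int(sy.years[-1]) - exclude_last
    window = (sy.years > stage1.threshold_year) & (sy.years <= last_year)
    if window.sum() < min_stage2_years:
        notes.append(
            f"stage 2 skipped: only {int(window.sum())} post-threshold years"
        )
        return SequentialResult(stages, gams, tgams, notes)
    st2 = SeriesVector.from_arrays(sy.years[window], st.values[window])
    sy2 = SeriesVector.from_arrays(sy.years[window], sy.values[window])
    gam2 = genuine_cv(st2, sy2, "gam", basis_dim)
    tgam2 = genuine_cv(st2, sy2, "tgam", basis_dim, q_low, q_high, n_candidates)
    gams.append(gam2)
    tgams.append(tgam2)
    if tgam2 < gam2:
        stages.append(fit_tgam(st2, sy2, q_low, q_high, n_candidates, basis_dim))
    else:
        notes.append("stage 2: GAM favored by gCV; single threshold retained")
    return SequentialResult(stages, gams, tgams, notes)
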