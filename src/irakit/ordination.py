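"""Principal component analysis of the system and stressor blocks.

Correlation-matrix PCA (variables standardized) is the default, since the
blocks mix units (kg/GT landings vs. temperatures, salinities, nutrient
concentrations). Components are sign-oriented deterministically so that
scores, loadings and downstream threshold estimates are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import AnnualMatrix, SeriesVector
from .errors import DataError

__all__ = ["PCAResult", "fit_pca", "orient_components"]


@dataclass(frozen=True)
class PCAResult:
    """Scores per year, loadings per variable, explained-variance fractions."""

    scores: pd.DataFrame  # years x PC1..PCk
    loadings: pd.DataFrame  # variables x PC1..PCk
    explained_fraction: np.ndarray  # per component, sums to 1 over all PCs
    eigenvalues: np.ndarray
    scaled: bool

    @property
    def years(self) -> np.ndarray:
        return self.scores.index.to_numpy()

    def score_series(self, component: int = 1) -> SeriesVector:
        """One PC-score series (1-based component index), e.g. PC1sys."""
        name = f"PC{component}"
        if name not in self.scores.columns:
            raise DataError(f"no component {name}")
        return SeriesVector(self.scores[name])

    def loading_ranking(self, component: int = 1) -> list[str]:
        """Variables sorted by descending loading on the component."""
        name = f"PC{component}"
        return list(self.loadings[name].sort_values(ascending=False).index)


def fit_pca(m: AnnualMatrix, scale: bool = True) -> PCAResult:
    """PCA via eigendecomposition of the covariance (or, if ``scale``,
    correlation) matrix of the column-centered data.

    Components are ordered by decreasing eigenvalue;
    ``explained_fraction`` is eigenvalue / trace. Loadings are the unit
    eigenvectors, scores the projections of the (centered, optionally
    scaled) data onto them.
    """
    if len(m.variables) < 2:
        raise DataError("PCA needs at least 2 variables")
    x = m.values
    xc = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [m.variables[i] for i in zero]
            raise DataError(f"zero-variance variables cannot be scaled: {names}")
        xc = xc / sd
    cov = (xc.T @ xc) / (len(m.years) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    scores = xc @ eigvec
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.years, columns=comps),
        loadings=pd.DataFrame(eigvec, index=m.variables, columns=comps),
        explained_fraction=eigval / eigval.sum(),
        eigenvalues=eigval,
        scaled=scale,
    )


def orient_components(r: PCAResult) -> PCAResult:
    """Fix the arbitrary PCA signs: flip each component so its
    largest-magnitude loading is positive (exact ties broken by
    variable-name order). Scores are flipped consistently; explained
    fractions are unaffected."""
    loadings = r.loadings.copy()
    scores = r.scores.copy()
    byname = loadings.reindex(sorted(loadings.index))
    for comp in loadings.columns:
        col = byname[comp].to_numpy()
        top = np.flatnonzero(np.abs(col) == np.abs(col).max())[0]
        if col[top] < 0:
            loadings[comp] = -loadings[comp]
            scores[comp] = -scores[comp]
    return replace(r, scores=scores, loadings=loadings)
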