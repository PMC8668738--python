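"""Seeded generator of system/stressor annual tables with known regime structure.

The generator emulates the statistical anatomy of a climate-driven
multivariate regime shift: a latent stressor score that trends upward and
takes abrupt step changes, a latent system score that responds through
regime-specific smooth branches (switching branch at known threshold
years, with different intercepts over overlapping stressor ranges — i.e.
hysteresis), and observed variables that load linearly on their latent
score plus idiosyncratic noise. Every downstream stage can therefore be
tested against ground truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .data import AnnualMatrix
from .errors import ConfigError

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_scenario",
    "aegean_like_preset",
    "continuous_like_preset",
]

BranchFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic scenario.

    ``stressor_step_years`` / ``system_threshold_years`` use the
    last-year-of-the-old-regime convention: a step listed at 1988 first
    affects 1989; a system threshold at 1991 means the new regime starts
    in 1992.
    """

    n_years: int = 52
    start_year: int = 1966
    n_stressor_vars: int = 12
    n_system_vars: int = 12
    stressor_step_years: tuple[int, ...] = ()
    stressor_step_sizes: tuple[float, ...] = ()
    stressor_trend: float = 0.0  # latent units per year
    system_threshold_years: tuple[int, ...] = ()
    branch_functions: tuple[BranchFn, ...] = ()
    stressor_loadings: tuple[float, ...] = ()
    system_loadings: tuple[float, ...] = ()
    noise_sd_latent: float = 0.0
    noise_sd_idiosyncratic: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        lo, hi = self.start_year, self.start_year + self.n_years - 1
        if self.n_years < 3:
            problems.append("n_years must be >= 3")
        for y in list(self.stressor_step_years) + list(self.system_threshold_years):
            if not (lo < y < hi):
                problems.append(f"year {y} not strictly inside ({lo}, {hi})")
        if len(self.stressor_step_years) != len(self.stressor_step_sizes):
            problems.append("step years and step sizes differ in length")
        if len(self.branch_functions) != len(self.system_threshold_years) + 1:
            problems.append("need one branch function per regime")
        if self.noise_sd_latent < 0 or self.noise_sd_idiosyncratic < 0:
            problems.append("noise sds must be >= 0")
        if len(self.stressor_loadings) != self.n_stressor_vars:
            problems.append("need one stressor loading per stressor variable")
        if len(self.system_loadings) != self.n_system_vars:
            problems.append("need one system loading per system variable")
        if any(v == 0 for v in self.stressor_loadings + self.system_loadings):
            problems.append("loadings must be non-zero")
        if problems:
            raise ConfigError("invalid scenario config: " + "; ".join(problems))


@dataclass(frozen=True)
class GroundTruth:
    """Latent scores, true threshold years and regime labels of a scenario."""

    years: np.ndarray
    latent_stressor: np.ndarray
    latent_system: np.ndarray
    threshold_years: tuple[int, ...]
    regime_labels: np.ndarray  # 1-based, contiguous blocks

    def to_json(self, path) -> None:
        payload = {
            "years": self.years.tolist(),
            "latent_stressor": self.latent_stressor.tolist(),
            "latent_system": self.latent_system.tolist(),
            "threshold_years": list(self.threshold_years),
            "regime_labels": self.regime_labels.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _regime_labels(years: np.ndarray, thresholds: Sequence[int]) -> np.ndarray:
    labels = np.ones(len(years), dtype=int)
    for t in sorted(thresholds):
        labels[years > t] += 1
    return labels


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[AnnualMatrix, AnnualMatrix, GroundTruth]:
    """Draw one scenario: (stressors, system, ground truth).

    Latent stressor: linear trend + step changes + Gaussian noise.
    Latent system: the current regime's branch function applied to the
    latent stressor, plus Gaussian noise. Observed variables load
    linearly on their latent score with idiosyncratic Gaussian noise.
    Bit-reproducible for a given seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    years = np.arange(config.start_year, config.start_year + config.n_years)
    t = years - config.start_year

    latent_str = config.stressor_trend * t.astype(float)
    for y, size in zip(config.stressor_step_years, config.stressor_step_sizes):
        latent_str = latent_str + size * (years > y)
    latent_str = latent_str + rng.normal(0.0, config.noise_sd_latent, len(years))

    labels = _regime_labels(years, config.system_threshold_years)
    latent_sys = np.empty(len(years))
    for regime, fn in enumerate(config.branch_functions, start=1):
        mask = labels == regime
        latent_sys[mask] = fn(latent_str[mask])
    latent_sys = latent_sys + rng.normal(0.0, config.noise_sd_latent, len(years))

    def observe(latent, loadings, prefix):
        loadings = np.asarray(loadings, dtype=float)
        noise = rng.normal(
            0.0, config.noise_sd_idiosyncratic, (len(latent), len(loadings))
        )
        vals = latent[:, None] * loadings[None, :] + noise
        names = [f"{prefix}{i + 1:02d}" for i in range(len(loadings))]
        return AnnualMatrix.from_arrays(years, vals, names)

    stressors = observe(latent_str, config.stressor_loadings, "str")
    system = observe(latent_sys, config.system_loadings, "sys")
    truth = GroundTruth(
        years=years,
        latent_stressor=latent_str,
        latent_system=latent_sys,
        threshold_years=tuple(sorted(config.system_threshold_years)),
        regime_labels=labels,
    )
    return stressors, system, truth


def _branch_initial(s: np.ndarray) -> np.ndarray:
    # high system level, insensitive to the stressor over its basin
    return np.full_like(np.asarray(s, dtype=float), 2.4)


def _branch_intermediate(s: np.ndarray) -> np.ndarray:
    # collapsed level over stressor range shared with both neighbors
    return -1.0 + 0.5 * (s - 2.0)


def _branch_recent(s: np.ndarray) -> np.ndarray:
    # second collapse; stays low when the stressor partially reverses
    return np.full_like(np.asarray(s, dtype=float), -2.4)


def aegean_like_preset(
    seed: int = 0,
    noise_sd_latent: float = 0.3,
    noise_sd_idiosyncratic: float = 0.3,
) -> ScenarioConfig:
    """A 52-year, 12+12-variable scenario shaped like an eastern
    Mediterranean demersal community under climate forcing.

    The latent stressor rises over 1966–2017 as a staircase of step
    increases after 1975, 1988 and 1999 (the decadal climate steps),
    then partially reverses after 2008. The system responds
    discontinuously with threshold years 1991 and 2002, and both folds
    show hysteresis: the second regime spans stressor levels already
    visited by the first regime and later revisited by the third, whose
    collapsed state persists when the stressor falls back. Forcing is
    step-dominated (no continuous trend term) so that in the noise-free
    limit the system series is piecewise-constant up to the middle
    branch's slope across its two stressor levels — the identifiability
    limit of segment-mean shift detectors. Loadings mix signs, as real
    assemblages do (winner and loser taxa).
    """
    str_loadings = (1.0, 0.9, 0.8, 0.7, 0.9, -0.6, -0.8, 0.75, 0.85, -0.7, 0.95, 0.65)
    sys_loadings = (1.0, 0.85, 0.9, -0.7, -0.8, 0.75, 0.8, -0.65, 0.9, 0.7, -0.75, 0.6)
    return ScenarioConfig(
        n_years=52,
        start_year=1966,
        n_stressor_vars=12,
        n_system_vars=12,
        stressor_step_years=(1975, 1988, 1999, 2008),
        stressor_step_sizes=(0.8, 1.2, 1.0, -1.0),
        stressor_trend=0.0,
        system_threshold_years=(1991, 2002),
        branch_functions=(_branch_initial, _branch_intermediate, _branch_recent),
        stressor_loadings=str_loadings,
        system_loadings=sys_loadings,
        noise_sd_latent=noise_sd_latent,
        noise_sd_idiosyncratic=noise_sd_idiosyncratic,
        seed=seed,
    )


def _branch_continuous(s: np.ndarray) -> np.ndarray:
    # one linear response — no regime structure, and nothing for a
    # penalized smooth to over- or under-fit
    return 1.2 - 0.8 * np.asarray(s, dtype=float)


def continuous_like_preset(
    seed: int = 0,
    noise_sd_latent: float = 0.3,
    noise_sd_idiosyncratic: float = 0.3,
) -> ScenarioConfig:
    """Null counterpart of :func:`aegean_like_preset`: same observation
    model and noise levels, but the system follows a single smooth
    (linear) response branch with no threshold years.

    The forcing has two steps that bracket the threshold-candidate
    window (after 1975 and 2008), so every candidate split severs the
    long middle stressor level: a threshold model always loses pooled
    information here, making its extra flexibility visible to the gCV
    comparison. A linear response keeps the single smooth unbiased, so
    the comparison isolates the threshold model's added variance. Used
    to check that the model comparison does not invent discontinuities."""
    base = aegean_like_preset(seed, noise_sd_latent, noise_sd_idiosyncratic)
    return ScenarioConfig(
        n_years=base.n_years,
        start_year=base.start_year,
        n_stressor_vars=base.n_stressor_vars,
        n_system_vars=base.n_system_vars,
        stressor_step_years=(1975, 2008),
        stressor_step_sizes=(1.5, 1.5),
        stressor_trend=0.0,
        system_threshold_years=(),
        branch_functions=(_branch_continuous,),
        stressor_loadings=base.stressor_loadings,
        system_loadings=base.system_loadings,
        noise_sd_latent=noise_sd_latent,
        noise_sd_idiosyncratic=noise_sd_idiosyncratic,
        seed=seed,
    )
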