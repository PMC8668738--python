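"""End-to-end orchestration: data -> PCA -> shift detection -> TGAM ->
resilience landscape, with reproducible artifacts on disk.
"""

from __future__ import annotations

import json
import logging

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import AnnualMatrix, quintile_categorize, standardize
from .errors import ConfigError, DataError, IrakitError
from .ordination import fit_pca, orient_components
from .resilience import (
    assign_regimes,
    build_attractors,
    compute_resilience,
    insert_repulsion_states,
    interpolate_landscape,
    place_tipping_points,
)
from .shifts import StarsParams, coniss, cut_dendrogram, detect_breakpoints, stars
from .simulate import aegean_like_preset, continuous_like_preset, generate_scenario
from .tgam import compare_models, detect_regimes_sequential

log = logging.getLogger("irakit")

__all__ = ["PipelineConfig", "run_pipeline"]

ARTIFACTS = [
    "anomalies_system.csv",
    "anomalies_stressors.csv",
    "pca_scores.csv",
    "pca_loadings.csv",
    "traffic_light.csv",
    "shifts.csv",
    "model_comparison.csv",
    "tgam_stages.json",
    "resilience.csv",
    "landscape.json",
]


@dataclass
class PipelineConfig:
    """Everything one run needs; echoable to YAML for exact reruns."""

    system_csv: str | None = None
    stressors_csv: str | None = None
    preset: str | None = None  # "aegean" or "continuous"; overrides the CSVs
    noise_sd_latent: float = 0.3
    noise_sd_idiosyncratic: float = 0.3
    pca_scale: bool = True
    coniss_k: int = 2
    breakpoint_max_m: int = 5
    breakpoint_min_seg_frac: float = 0.15
    stars_cutoff: int = 15
    stars_significance: float = 0.05
    n_perm: int = 199
    tgam_q_low: float = 0.2
    tgam_q_high: float = 0.8
    tgam_candidates: int = 50
    tgam_basis_dim: int = 5
    lags: tuple[int, ...] = (0, 1, 2)
    exclude_final_year: bool = True  # 2017-style trailing-year handling
    out_dir: str = "irakit_out"
    seed: int = 0

    def validate(self) -> None:
        if self.preset is None:
            if not (self.system_csv and self.stressors_csv):
                raise ConfigError("need either a preset or both input CSV paths")
            for p in (self.system_csv, self.stressors_csv):
                if not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")
        elif self.preset not in ("aegean", "continuous"):
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.coniss_k < 1:
            raise ConfigError("coniss_k must be >= 1")
        if not 0 < self.tgam_q_low < self.tgam_q_high < 1:
            raise ConfigError("need 0 < tgam_q_low < tgam_q_high < 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "lags" in raw:
            raw["lags"] = tuple(raw["lags"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lags"] = list(self.lags)
        return d


def _load_inputs(config: PipelineConfig):
    if config.preset is not None:
        maker = aegean_like_preset if config.preset == "aegean" else continuous_like_preset
        scenario = maker(
            seed=config.seed,
            noise_sd_latent=config.noise_sd_latent,
            noise_sd_idiosyncratic=config.noise_sd_idiosyncratic,
        )
        stressors, system, truth = generate_scenario(scenario)
        return system, stressors, truth
    system = AnnualMatrix.read_csv(config.system_csv)
    stressors = AnnualMatrix.read_csv(config.stressors_csv)
    if not np.array_equal(system.years, stressors.years):
        raise DataError("system and stressor tables must cover identical years")
    return system, stressors, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full assessment and write the artifact bundle.

    Returns a dict with the in-memory results and the manifest. Identical
    config + seed produce byte-identical artifacts. A failing stage
    leaves the already-written artifacts plus a FAILED marker naming the
    stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        system, stressors, truth = _load_inputs(config)

        stage = "standardize"
        anom_sys = standardize(system)
        anom_str = standardize(stressors)
        anom_sys.to_csv(out / "anomalies_system.csv")
        anom_str.to_csv(out / "anomalies_stressors.csv")

        stage = "pca"
        pca_sys = orient_components(fit_pca(system, scale=config.pca_scale))
        pca_str = orient_components(fit_pca(stressors, scale=config.pca_scale))
        scores = pd.DataFrame(
            {
                "pc1_sys": pca_sys.scores["PC1"],
                "pc2_sys": pca_sys.scores["PC2"],
                "pc1_str": pca_str.scores["PC1"],
                "pc2_str": pca_str.scores["PC2"],
            }
        )
        scores.index.name = "year"
        scores.to_csv(out / "pca_scores.csv")
        loadings = pd.concat(
            [
                pca_sys.loadings[["PC1", "PC2"]].assign(
                    block="system",
                    pc1_explained=pca_sys.explained_fraction[0],
                    pc2_explained=pca_sys.explained_fraction[1],
                ),
                pca_str.loadings[["PC1", "PC2"]].assign(
                    block="stressor",
                    pc1_explained=pca_str.explained_fraction[0],
                    pc2_explained=pca_str.explained_fraction[1],
                ),
            ]
        )
        loadings.index.name = "variable"
        loadings.to_csv(out / "pca_loadings.csv")

        stage = "traffic_light"
        tl = quintile_categorize(system, pca_sys.loading_ranking(1))
        tl.to_csv(out / "traffic_light.csv")

        stage = "shift_detection"
        pc1sys = pca_sys.score_series(1)
        cres = coniss(anom_sys)
        _, coniss_thresholds = cut_dendrogram(cres, config.coniss_k)
        bres = detect_breakpoints(
            pc1sys,
            max_m=config.breakpoint_max_m,
            min_seg_frac=config.breakpoint_min_seg_frac,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        sres = stars(
            pc1sys,
            StarsParams(config.stars_cutoff, config.stars_significance),
        )
        rows = [
            {"method": "coniss", "threshold_year": t, "statistic": np.nan,
             "p_value": np.nan}
            for t in coniss_thresholds
        ]
        rows += [
            {"method": "breakpoint", "threshold_year": t,
             "statistic": bres.supf_statistic, "p_value": bres.supf_pvalue}
            for t in bres.breakpoint_years
        ]
        rows += [
            {"method": "stars", "threshold_year": t, "statistic": rsi,
             "p_value": config.stars_significance}
            for t, rsi in zip(sres.threshold_years, sres.rsi)
        ]
        shifts_table = pd.DataFrame(
            rows, columns=["method", "threshold_year", "statistic", "p_value"]
        )
        shifts_table.to_csv(out / "shifts.csv", index=False)
        (out / "dendrogram_system.nwk").write_text(cres.to_newick() + "\n")

        stage = "model_comparison"
        pc1str = pca_str.score_series(1)
        comparison = compare_models(
            pc1sys, pc1str, config.lags,
            basis_dim=config.tgam_basis_dim,
            q_low=config.tgam_q_low, q_high=config.tgam_q_high,
            n_candidates=config.tgam_candidates,
        )
        comparison.to_csv(out / "model_comparison.csv")

        stage = "sequential_tgam"
        seq = detect_regimes_sequential(
            pc1sys, pc1str,
            basis_dim=config.tgam_basis_dim,
            q_low=config.tgam_q_low, q_high=config.tgam_q_high,
            n_candidates=config.tgam_candidates,
            exclude_last=1 if config.exclude_final_year else 0,
        )
        stages_payload = {
            "threshold_years": seq.threshold_years,
            "gcv_gam": seq.gcv_gam,
            "gcv_tgam": seq.gcv_tgam,
            "warnings": seq.warnings,
        }
        (out / "tgam_stages.json").write_text(json.dumps(stages_payload, indent=1))

        stage = "resilience"
        if not seq.stages:
            raise DataError(
                "no discontinuous response detected; resilience landscape undefined"
            )
        common = np.intersect1d(pc1sys.years, pc1str.years)
        exclude = (int(common[-1]),) if config.exclude_final_year else ()
        states = assign_regimes(
            common,
            pc1str.series.loc[common].to_numpy(),
            pc1sys.series.loc[common].to_numpy(),
            seq.threshold_years,
            exclude_years=exclude,
        )
        attractors = build_attractors(seq.stages, states)
        tips = place_tipping_points(attractors, states)
        res = compute_resilience(states, attractors, tips)
        res.to_csv(out / "resilience.csv")
        points = insert_repulsion_states(tips, attractors, res)
        landscape = interpolate_landscape(points)
        payload = landscape.to_json_dict()
        payload["tipping_points"] = [
            {"label": t.label, "x": t.x, "regime": t.regime, "direction": t.direction}
            for t in tips
        ]
        (out / "landscape.json").write_text(json.dumps(payload, indent=1))

        stage = "manifest"
        manifest = {
            "irakit_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "artifacts": ARTIFACTS,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except IrakitError as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise
    return {
        "manifest": manifest,
        "scores": scores,
        "shifts": shifts_table,
        "comparison": comparison,
        "sequential": seq,
        "resilience": res,
        "landscape": landscape,
        "tipping_points": tips,
        "truth": truth,
        "out_dir": str(out),
    }
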