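"""End-to-end orchestration: simulate or ingest, quantify, fit, contrast,
compare variance structures, screen effect sizes, and emit a manifest.

The pipeline is deterministic given its seed: re-running with the same
configuration reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import (
    ModelSpec,
    derived_contrasts,
    map_estimate,
    psis_loo,
    sample_posterior,
)
from .fitness import factorial_lm, genus_effect_sizes
from .io import read_config, read_isolates, write_table
from .synthetic import SyntheticConfig, simulate_siderophore

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("siderotrait")

_MODEL_DEFAULTS = {
    "variance_structure": "per_group",
    "chains": 4,
    "iterations": 1000,
    "warmup": None,
    "target_accept": 0.8,
}
_LOO_STRUCTURES = ["per_group", "by_isolate_type", "by_copper", "single"]


class PipelineConfig:
    """Validated pipeline configuration (YAML/JSON mapping or dict)."""

    def __init__(self, cfg: dict):
        if not isinstance(cfg, dict):
            raise ValueError("pipeline configuration must be a mapping")
        has_synth = "synthetic" in cfg
        has_inputs = "inputs" in cfg
        if has_synth == has_inputs:
            raise ValueError(
                "configuration must contain exactly one of 'synthetic' or 'inputs'"
            )
        self.seed = int(cfg.get("seed", 0))
        self.output_dir = Path(cfg.get("output_dir", "siderotrait_out"))
        self.synthetic = (
            SyntheticConfig(**{"seed": self.seed, **cfg["synthetic"]})
            if has_synth
            else None
        )
        self.inputs = cfg.get("inputs")
        if self.inputs is not None and "isolates" not in self.inputs:
            raise ValueError("'inputs' must provide an 'isolates' path")
        model = {**_MODEL_DEFAULTS, **cfg.get("model", {})}
        self.chains = int(model.pop("chains"))
        self.iterations = int(model.pop("iterations"))
        warmup = model.pop("warmup")
        self.warmup = None if warmup is None else int(warmup)
        self.target_accept = float(model.pop("target_accept"))
        self.spec = ModelSpec(**model)
        self.loo_structures = cfg.get("loo", {}).get("structures", _LOO_STRUCTURES)
        self.effect_sizes = cfg.get("effect_sizes", {})
        self.raw = cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls(read_config(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig | dict, persist_draws: bool = False) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns the report as a dict; on a stage failure the completed stages'
    outputs remain on disk next to a ``failure_manifest.json``.
    """
    if isinstance(config, dict):
        config = PipelineConfig(config)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {"seed": config.seed, "version": __version__}
    t_start = time.time()

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = out / name
        write_table(df, path, seed=config.seed)
        written.append(path)
        return path

    try:
        # --- stage: data -------------------------------------------------
        t0 = time.time()
        if config.synthetic is not None:
            isolates = simulate_siderophore(config.synthetic)
            report["data_source"] = "synthetic"
        else:
            isolates = read_isolates(
                config.inputs["isolates"], config.inputs.get("column_map")
            )
            report["data_source"] = str(config.inputs["isolates"])
        emit("isolates.csv", isolates.drop(columns=["true_lambda"], errors="ignore"))
        report["n_isolates"] = int(len(isolates))
        log.info("data stage: %d isolates (%.2fs)", len(isolates), time.time() - t0)

        # --- stage: hierarchical fit ------------------------------------
        t0 = time.time()
        draws = sample_posterior(
            isolates,
            config.spec,
            chains=config.chains,
            iterations=config.iterations,
            warmup=config.warmup,
            seed=config.seed,
            target_accept=config.target_accept,
        )
        mapres = map_estimate(isolates, config.spec, seed=config.seed)
        summary = draws.summary()
        mapflat = mapres.flat()
        summary["map"] = [mapflat.get(p, float("nan")) for p in summary["parameter"]]
        emit("posterior_summary.csv", summary)
        report["fit"] = {
            "converged": bool(draws.converged),
            "max_rhat": float(max(np.max(v) for v in draws.rhat.values())),
            "n_divergent": int(draws.n_divergent),
            "map_log_posterior": mapres.log_posterior,
            "parameters": {
                p: {
                    "map": mapflat.get(p, None),
                    "hpd95": [row.hpd_low, row.hpd_high],
                }
                for p, row in zip(summary["parameter"], summary.itertuples())
            },
        }
        if persist_draws:
            rows = []
            for name, arr in draws.params.items():
                c, i, k = arr.shape
                for jj in range(k):
                    sub = pd.DataFrame(
                        {
                            "chain": np.repeat(np.arange(c), i),
                            "iteration": np.tile(np.arange(i), c),
                            "parameter": f"{name}[{jj + 1}]",
                            "value": arr[:, :, jj].ravel(),
                        }
                    )
                    rows.append(sub)
            emit("draws.csv", pd.concat(rows, ignore_index=True))
        log.info("fit stage done (%.2fs)", time.time() - t0)

        # --- stage: contrasts -------------------------------------------
        contrasts = derived_contrasts(draws, map_params=mapres.params)
        emit("contrasts.csv", pd.DataFrame([asdict(c) for c in contrasts]))
        report["contrasts"] = {
            c.name: {"map": c.map_estimate, "hpd95": [c.hpd_low, c.hpd_high]}
            for c in contrasts
        }

        # --- stage: LOO comparison --------------------------------------
        t0 = time.time()
        if len(config.loo_structures) > 1:
            specs, fits = [], []
            for vs in config.loo_structures:
                spec = ModelSpec(
                    variance_structure=vs,
                    prior_alpha_sd=config.spec.prior_alpha_sd,
                    prior_beta_sd=config.spec.prior_beta_sd,
                    prior_scale_sigma=config.spec.prior_scale_sigma,
                    prior_scale_tau=config.spec.prior_scale_tau,
                )
                specs.append(spec)
                fits.append(
                    draws
                    if vs == config.spec.variance_structure
                    else sample_posterior(
                        isolates,
                        spec,
                        chains=config.chains,
                        iterations=config.iterations,
                        warmup=config.warmup,
                        seed=config.seed,
                        target_accept=config.target_accept,
                    )
                )
            loo_table = psis_loo(isolates, specs, fits)
            emit("loo.csv", loo_table)
            report["loo"] = loo_table.to_dict(orient="records")
            log.info("loo stage done (%.2fs)", time.time() - t0)

        # --- stage: effect sizes ----------------------------------------
        if "genus" in isolates.columns and isolates["genus"].nunique() > 3:
            try:
                records, spearman = genus_effect_sizes(
                    isolates[isolates["isolate_type"] == "community"],
                    **config.effect_sizes,
                )
                emit("effect_sizes.csv", pd.DataFrame([asdict(r) for r in records]))
                report["effect_sizes"] = {
                    "n_genera": len(records),
                    "spearman_rho": spearman.rho,
                    "spearman_S": spearman.S,
                    "spearman_p": spearman.pvalue,
                }
            except ValueError as err:
                report["effect_sizes"] = {"skipped": str(err)}

        # --- stage: per-microcosm means + factorial model ---------------
        per_unit = (
            isolates.groupby(["microcosm_id", "isolate_type", "copper"], as_index=False)
            .agg(mean_siderophore=("siderophore", "mean"))
        )
        emit("microcosm_means.csv", per_unit)
        try:
            lm = factorial_lm(per_unit, "mean_siderophore", "copper", "isolate_type")
            emit("marginal_means.csv", lm.marginal_means)
            report["factorial_model"] = {
                "coefficients": lm.coefficients,
                "anova": lm.anova.reset_index().to_dict(orient="records"),
                "marginal_means": lm.marginal_means.to_dict(orient="records"),
            }
        except ValueError as err:
            report["factorial_model"] = {"skipped": str(err)}

        # --- manifest ----------------------------------------------------
        # runtime stays out of report.json so same-seed reruns are byte-identical
        log.info("pipeline done (%.2fs)", time.time() - t_start)
        report_path = out / "report.json"
        report_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
        written.append(report_path)
        manifest = {
            "seed": config.seed,
            "version": __version__,
            "files": {p.name: _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return report
    except Exception as err:
        failure = {
            "seed": config.seed,
            "version": __version__,
            "error": f"{type(err).__name__}: {err}",
            "completed_files": {p.name: _sha256(p) for p in written if p.exists()},
        }
        (out / "failure_manifest.json").write_text(json.dumps(failure, indent=2))
        raise
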