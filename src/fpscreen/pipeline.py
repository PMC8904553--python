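"""End-to-end orchestration: simulate -> extract -> split -> evaluate.

Ties the four computational stages into one reproducible run.  All stage
randomness derives from the master seed, so two runs with the same config
and seed produce bitwise-identical feature tables and identical tree/Bayes
reports.  Artifacts are written under an output directory: spectra and
their manifest (when synthetic), ``features.csv``, ``plan.csv``, a
``report/`` directory and a ``run_manifest.json`` recording the config
hash, the seed and stage row counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as fio
from .classify import ClassifierSpec, EvaluationReport, run_experiment
from .config import PipelineConfig
from .data import LabeledDataset, build_dataset, split_validation, stratified_kfold
from .exceptions import StageError
from .features import extract_features
from .sim import (
    CavityModel,
    Interferogram,
    LiquidPanel,
    default_wavelength_grid,
    generate_study_design,
)

__all__ = ["base_model_from_config", "panel_from_config", "simulate_stage",
           "extract_stage", "split_stage", "run_pipeline", "generate_fixtures"]

logger = logging.getLogger(__name__)


def base_model_from_config(config: PipelineConfig, refractive_index: float = 1.30) -> CavityModel:
    sim = config.simulator
    return CavityModel(
        refractive_index=refractive_index,
        cavity_length_um=sim.cavity_length_um,
        center_wavelength_nm=sim.center_wavelength_nm,
        spectral_width_nm=sim.spectral_width_nm,
        visibility=sim.visibility,
        noise_sd=sim.noise_sd,
        noise_correlation_nm=sim.noise_correlation_nm,
        wavelength_grid=default_wavelength_grid(sim.grid_min_nm, sim.grid_max_nm, sim.grid_points),
    )


def panel_from_config(config: PipelineConfig) -> LiquidPanel:
    return LiquidPanel(
        label_indices=config.simulator.label_indices(),
        replicates=config.simulator.replicates,
    )


def simulate_stage(config: PipelineConfig, seed: int) -> list[Interferogram]:
    try:
        spectra = generate_study_design(panel_from_config(config), base_model_from_config(config), seed)
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise StageError("simulate", str(exc)) from exc
    logger.info("simulate: generated %d spectra", len(spectra))
    return spectra


def extract_stage(config: PipelineConfig, spectra: list[Interferogram]) -> LabeledDataset:
    try:
        rows, indices = [], []
        for igram in spectra:
            model = base_model_from_config(
                config, refractive_index=float(igram.metadata["operating_index"])
            )
            row = extract_features(igram, model, threshold=config.preprocessing.threshold)
            row["replicate"] = igram.metadata.get("replicate", 0)
            row["source"] = igram.metadata.get("source", "synthetic")
            rows.append(row)
            indices.append(float(igram.metadata["label_index"]))
        ds = build_dataset(rows, indices)
    except Exception as exc:
        raise StageError("extract", str(exc)) from exc
    logger.info("extract: %d rows in -> %d feature rows out", len(spectra), len(ds))
    return ds


def split_stage(config: PipelineConfig, ds: LabeledDataset, seed: int):
    try:
        train_ds, val_ds = split_validation(
            ds, config.split.validation_fraction, seed,
            group_aware=config.split.group_aware,
        )
        plan = stratified_kfold(train_ds, config.split.k, seed)
        plan.validation_indices = val_ds.frame.index.to_numpy()
    except Exception as exc:
        raise StageError("split", str(exc)) from exc
    return train_ds, val_ds, plan


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    spectra: list[Interferogram] | None = None,
) -> EvaluationReport:
    """Run the full pipeline and write all artifacts.

    ``spectra=None`` requests synthetic generation of the configured study
    design; otherwise pass spectra loaded from a manifest of measured files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()

    synthetic = spectra is None
    if synthetic:
        spectra = simulate_stage(config, seeds["simulate"])
        fio.write_study(spectra, out_dir / "spectra", seeds["simulate"])
    elif len(spectra) == 0:
        raise StageError("input", "no spectra to process (empty manifest)")

    ds = extract_stage(config, spectra)
    fio.write_feature_table(ds, out_dir / "features.csv")

    train_ds, val_ds, plan = split_stage(config, ds, seeds["split"])
    fio.write_fold_plan(plan, out_dir / "plan.csv")

    try:
        specs = [
            ClassifierSpec(family=c.family, hyperparameters=c.hyperparameters,
                           seed=seeds["classify"])
            for c in config.classifiers
        ]
        report = run_experiment(train_ds, plan, specs, validation=val_ds)
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc
    fio.write_report(report, out_dir / "report")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "synthetic": synthetic,
        "n_spectra": len(spectra),
        "n_rows": len(ds),
        "n_train": len(train_ds),
        "n_validation": len(val_ds),
        "class_counts": {str(k): v for k, v in ds.class_counts.items()},
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def generate_fixtures(seed: int, scale: str = "small", out_dir: str | Path | None = None):
    """Deterministic fixture spectra for tests and demos.

    ``small``: 3 liquids (1.30, 1.38, 1.50) x 2 replicates on a 201-point
    grid — 6 spectra spanning both classes.  ``full``: the 21 x 10 study
    design on the default grid — 210 spectra.  Writes spectra plus manifest
    when ``out_dir`` is given; always returns the spectra.
    """
    if scale == "small":
        panel = LiquidPanel(label_indices=(1.30, 1.38, 1.50), replicates=2)
        model = CavityModel(refractive_index=1.30,
                            wavelength_grid=default_wavelength_grid(num=201))
    elif scale == "full":
        panel = LiquidPanel()
        model = CavityModel(refractive_index=1.30)
    else:
        raise ValueError(f"scale must be 'small' or 'full', got {scale!r}")
    spectra = generate_study_design(panel, model, seed)
    if out_dir is not None:
        fio.write_study(spectra, out_dir, seed)
    return spectra
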