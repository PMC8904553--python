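import numpy as np
import pytest

from fpscreen import (
    CavityModel,
    ClassifierSpec,
    default_wavelength_grid,
    load_config,
    run_pipeline,
)
from fpscreen.classify import CLASSICAL_FAMILIES
from fpscreen.pipeline import extract_stage, simulate_stage, split_stage


@pytest.fixture
def noiseless_model():
    """Default study cavity (n=1.30, l=280 um) without noise."""
    return CavityModel(refractive_index=1.30, noise_sd=0.0)


@pytest.fixture
def small_grid():
    return default_wavelength_grid(num=201)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-design pipeline run (210 spectra, 1% noise, seed 0).

    Returns (dataset, train, validation, plan, report) with the three
    classical classifiers plus the neural net evaluated.
    """
    cfg = load_config()  # defaults: 21 liquids x 10 replicates, seed 0
    out = tmp_path_factory.mktemp("default_run")
    report = run_pipeline(cfg, out)
    seeds = cfg.stage_seeds()
    spectra = simulate_stage(cfg, seeds["simulate"])
    ds = extract_stage(cfg, spectra)
    train_ds, val_ds, plan = split_stage(cfg, ds, seeds["split"])
    return {
        "config": cfg,
        "dataset": ds,
        "train": train_ds,
        "validation": val_ds,
        "plan": plan,
        "report": report,
        "out_dir": out,
    }


def classical_specs(seed: int) -> list[ClassifierSpec]:
    return [ClassifierSpec(family=f, seed=seed) for f in CLASSICAL_FAMILIES]
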