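"""Shared fixtures: a small candy-cane phantom sized for fast tests."""

import numpy as np
import pytest

import revflow
from revflow import PhantomSpec, PipelineConfig


def small_spec(**overrides) -> PhantomSpec:
    """Compact candy-cane phantom (48x48x72 grid, 8 mm lumen) used by
    most tests; same waveform and artifact defaults as the full-size
    phantom."""
    base = dict(
        grid_shape=(48, 48, 72),
        tube_radius_mm=8.0,
        ascending_len_mm=28.0,
        arch_radius_mm=13.0,
        descending_len_mm=32.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def config_for(spec: PhantomSpec, **overrides) -> PipelineConfig:
    seeds = spec.default_seeds()
    cfg = PipelineConfig(
        seed_valve=seeds[0],
        seed_distal=seeds[1],
        landmarks=spec.default_landmarks(),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_phantom():
    spec = small_spec()
    dataset, truth = revflow.generate_dataset(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def small_run(small_phantom):
    spec, dataset, truth = small_phantom
    result = revflow.run_pipeline(dataset, config_for(spec))
    return spec, dataset, truth, result


@pytest.fixture(scope="session")
def full_phantom():
    """Default full-size (64x64x96, 15-frame) phantom, noise-free."""
    spec = PhantomSpec()
    dataset, truth = revflow.generate_dataset(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def full_run(full_phantom):
    spec, dataset, truth = full_phantom
    result = revflow.run_pipeline(dataset, config_for(spec))
    return spec, dataset, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
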