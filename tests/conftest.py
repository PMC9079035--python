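"""Shared fixtures: small, fast simulated embryos."""

import pytest

from cidlab.model import ModelParams
from cidlab.synthetic import EmbryoSimConfig, generate_timelapse


def small_config(e: float = 1.0, seed: int = 0, **overrides) -> EmbryoSimConfig:
    """Two-cycle, 8-nucleus embryo on a small field; fast to render."""
    kwargs = dict(
        field_size_px=(112, 112),
        n_z=12,
        n_cycles=2,
        nuclei_at_start=8,
        catastrophe_rate_per_mitosis=0.0,
        seed=seed,
        model=ModelParams(
            initial_intensity=90000.0,
            loading_efficiency=e,
            partition_cv=0.02,
            loading_cv=0.05,
        ),
    )
    kwargs.update(overrides)
    return EmbryoSimConfig(**kwargs)


def noise_free_config(e: float = 1.0, seed: int = 0, **overrides) -> EmbryoSimConfig:
    """Small embryo with all noise sources off (deterministic photometry)."""
    base = dict(
        shot_noise=False,
        read_noise_sd=0.0,
        model=ModelParams(initial_intensity=90000.0, loading_efficiency=e),
    )
    base.update(overrides)
    return small_config(e=e, seed=seed, **base)


@pytest.fixture(scope="session")
def default_embryo():
    """One embryo at the default three-cycle configuration (shared)."""
    config = EmbryoSimConfig(seed=42)
    stack, gt, track = generate_timelapse(config, embryo_id="fix")
    return config, stack, gt, track


@pytest.fixture(scope="session")
def small_embryo():
    config = small_config(e=1.0, seed=5)
    stack, gt, track = generate_timelapse(config, embryo_id="small")
    return config, stack, gt, track
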