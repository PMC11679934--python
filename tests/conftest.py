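import numpy as np
import pytest

from tsrefine.config import RunConfig
from tsrefine.synth import SyntheticSpec, generate_dataset


def tiny_run_config(n_classes: int = 3, **stage_overrides) -> RunConfig:
    """Desk-scale configuration used across stage and CLI tests."""
    stages = {"epochs_pretrain": 30, "epochs_refine": 15,
              "epochs_finetune": 60, "batch_size": 16, "lr_finetune": 1e-2,
              "finetune_augment": False}
    stages.update(stage_overrides)
    return RunConfig.from_dict({
        "encoder": {"d_model": 32, "n_heads": 2, "ff_dim": 64,
                    "patch_len": 16, "d_agg": 32, "pyramid_dims": [64, 32, 16],
                    "latent_dim": 16, "n_classes": n_classes, "dropout": 0.0,
                    "decoder_dim": 32},
        "stages": stages,
        "seed": 0,
    })


@pytest.fixture(scope="session")
def easy_dataset():
    """Three well-separated spectral classes, low noise."""
    return generate_dataset(SyntheticSpec(
        n_samples=60, n_channels=1, n_timesteps=256, n_classes=3,
        class_freqs=[[4.0], [12.0], [24.0]], sampling_rate=64.0,
        noise_sd=0.3, seed=42))
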