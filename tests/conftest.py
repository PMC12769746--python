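"""Shared fixtures: small synthetic datasets and reduced backbones.

Everything is generated at test time; nothing is read from disk.
"""

import warnings

import numpy as np
import pytest

import fedlora as fl
from fedlora.backbone import calibrate_batchnorm


@pytest.fixture(scope="session")
def small_smear():
    """4 x 20 images at 64 px — enough for IO/shape/partition tests."""
    spec = fl.SmearDatasetSpec(images_per_class=(20,) * 4, resolution=64, seed=11)
    images, labels, manifest = fl.generate_dataset(spec)
    return images, labels, manifest


@pytest.fixture(scope="session")
def smoke_smear():
    """The desk-scale federation dataset (4 x 200 at 96 px)."""
    images, labels, _ = fl.generate_dataset(fl.smoke_dataset_spec(seed=0))
    return images, labels


@pytest.fixture()
def s0_model():
    return fl.build_backbone("s0", 4, seed=3)


@pytest.fixture()
def s0_with_adapters(s0_model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state = fl.inject_lora(s0_model, fl.LoRAConfig(rank=4, alpha=8.0), seed=5)
    return s0_model, state


@pytest.fixture(scope="session")
def calibrated_s0(small_smear):
    """A calibrated frozen s0 backbone over the small dataset (64 px)."""
    images, labels, _ = small_smear
    mean, std = fl.normalization_stats(images)
    x = fl.to_model_input(images, mean, std)
    model = fl.build_backbone("s0", 4, seed=3)
    calibrate_batchnorm(model, x[::2][:40])
    return model, x, labels
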