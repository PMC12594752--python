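import numpy as np
import pytest

from autoqc.io_datasets import Image
from autoqc.synthetic_data import SceneSpec, generate_normal


@pytest.fixture(scope="session")
def tiny_scene() -> SceneSpec:
    """Small scene used by training tests: 32x32, 3 cells."""
    return SceneSpec(height=32, width=32, cell_count=3, seed=0)


@pytest.fixture(scope="session")
def tiny_normals(tiny_scene) -> list[Image]:
    from dataclasses import replace

    return [generate_normal(replace(tiny_scene, seed=i)) for i in range(3)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_e2e(tmp_path_factory):
    """Full desk-scale protocol: benchmark generation, pDDPM + AE training,
    threshold fitting on validation, evaluation on the test split.

    Session-scoped because training dominates the suite's runtime; every
    consumer reads from the same fitted models.
    """
    from autoqc.evaluation import evaluate_method
    from autoqc.io_datasets import load_image
    from autoqc.pipeline import fit_thresholds_on_validation, train_method
    from autoqc.presets import (
        DESK_AGG,
        desk_ae_config,
        desk_benchmark,
        desk_pddpm_config,
    )
    from autoqc.scoring import AggregatorConfig

    seed = 1
    root = tmp_path_factory.mktemp("desk_benchmark")
    manifest = desk_benchmark(root, seed=seed)
    train_images = [load_image(p) for p in manifest.train_normal]
    agg = AggregatorConfig(**DESK_AGG)

    out = {"manifest": manifest, "agg": agg}
    for name, config in (
        ("pddpm", desk_pddpm_config(seed=seed)),
        ("ae", desk_ae_config(seed=seed)),
    ):
        model = train_method(name, train_images, config)
        thresholds = fit_thresholds_on_validation(model, manifest, agg)
        out[f"{name}_model"] = model
        out[f"{name}_thresholds"] = thresholds
        out[f"{name}_report"] = evaluate_method(manifest, model, thresholds, agg)
    return out
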