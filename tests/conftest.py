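import numpy as np
import pytest

import stemfit


@pytest.fixture(scope="session")
def small_config() -> stemfit.ForestConfig:
    """A light plot (8 stems, reduced densities) for fast per-module tests."""
    return stemfit.ForestConfig(
        n_trees=8,
        plot_extent=(16.0, 14.0),
        points_per_m2_stem_surface=2000.0,
        points_per_m2_ground=300.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_scene(small_config) -> stemfit.SyntheticScene:
    return stemfit.generate_forest(small_config)


@pytest.fixture(scope="session")
def default_scene() -> stemfit.SyntheticScene:
    """The study-plot defaults: 71 stems, sigma = 1 cm, undulation, clutter."""
    return stemfit.generate_forest(stemfit.ForestConfig(seed=0))


@pytest.fixture(scope="session")
def default_pipeline_runs(default_scene):
    """Full pipeline runs on the default plot for seeds 0-4.

    Shared between the end-to-end recovery, degradation and clustering tests
    because each run takes tens of seconds.
    """
    runs = []
    for seed in range(5):
        scene = default_scene if seed == 0 else stemfit.generate_forest(
            stemfit.ForestConfig(seed=seed)
        )
        result = stemfit.run_pipeline(
            scene.cloud, truth=scene.truth, config=stemfit.PipelineConfig(seed=seed)
        )
        runs.append((scene, result))
    return runs


def label_instances(scene: stemfit.SyntheticScene) -> list[stemfit.TreeInstance]:
    """Oracle segmentation: one instance per stem, straight from the labels."""
    instances = []
    for _, row in scene.truth.iterrows():
        tid = int(row["tree_id"])
        idx = np.flatnonzero(scene.labels == tid)
        instances.append(
            stemfit.TreeInstance(tid, idx, (float(row["x"]), float(row["y"])))
        )
    return instances


def analytic_heights(scene: stemfit.SyntheticScene) -> np.ndarray:
    """Height above local ground from the simulator's exact terrain surface."""
    cloud = scene.cloud
    return cloud.coords[:, 2] - stemfit.ground_elevation(scene.config, cloud.coords[:, :2])
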