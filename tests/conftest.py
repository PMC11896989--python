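"""Shared fixtures: one full-size default scene (reused across modules, it
is the expensive object) and a small fast scene for plumbing tests."""

from __future__ import annotations

import numpy as np
import pytest

from chlorotex.mlra import FeatureGroup
from chlorotex.spectral_features import roi_feature_means, vi_images
from chlorotex.synthetic_scene import SceneConfig, generate_scene
from chlorotex.texture_features import pca_transform, texture_feature_images


@pytest.fixture(scope="session")
def default_scene():
    """The default-condition scene: 74 points, 164 bands, seed 42."""
    return generate_scene(SceneConfig(seed=42))


@pytest.fixture(scope="session")
def small_scene_config():
    """A compact scene for I/O and plumbing tests (12 points, 40 bands)."""
    return SceneConfig(
        seed=7, n_rows=80, n_cols=160, n_points=12, spacing=20,
        wavelengths=np.linspace(350, 1000, 40),
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_config):
    return generate_scene(small_scene_config)


@pytest.fixture(scope="session")
def scene_features(default_scene):
    """Feature table (20 VIs + 24 TFs) of the default scene, truth mask."""
    cube, truth = default_scene
    mask = truth.vegetation_mask_true
    vi_imgs, vi_sidecar = vi_images(cube, mask)
    pca = pca_transform(cube, mask)
    tf_imgs, tf_prov = texture_feature_images(pca, mask)
    provenance = {**{n: "VI" for n in vi_imgs}, **tf_prov}
    table = roi_feature_means({**vi_imgs, **tf_imgs}, truth.points_frame(),
                              mask, size=50, provenance=provenance)
    return {
        "cube": cube, "truth": truth, "mask": mask, "pca": pca,
        "vi_images": vi_imgs, "tf_images": tf_imgs, "table": table,
        "provenance": provenance,
    }


@pytest.fixture(scope="session")
def vi_tf_groups(scene_features):
    prov = scene_features["provenance"]
    vis = [n for n, p in prov.items() if p == "VI"]
    tfs_pc1 = [n for n, p in prov.items() if p == "TF-PC1"]
    return (FeatureGroup("All VIs", vis),
            FeatureGroup("All VIs+TFs-PC1", vis + tfs_pc1))
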