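import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import camquant as cq


@pytest.fixture(scope="session")
def marker_scene():
    """Noise-free scene with a cytoplasmic and a fibre marker plus ground truth."""
    specs = (
        cq.MarkerSpec("CD44", "human", 0.5, "cytoplasmic_ring", 0.6),
        cq.MarkerSpec("ACTA2", "human", 0.3, "elongated_fibre", 0.7),
    )
    params = cq.SceneParams(
        n_human=60, n_chicken_rim=40, n_chicken_infiltrating=0,
        noise_sd=0.0, touching_pair_fraction=0.0, marker_specs=specs, seed=5,
    )
    scene, truth = cq.generate_scene(params)
    return params, scene, truth


@pytest.fixture(scope="session")
def recovery_params():
    """200 non-touching nuclei, 40-180 px, noise-free."""
    return cq.SceneParams(
        n_human=200, n_chicken_rim=0, n_chicken_infiltrating=0,
        human_area_range=(40.0, 180.0), human_ecc_range=(0.1, 0.5),
        noise_sd=0.0, touching_pair_fraction=0.0, seed=1,
    )


@pytest.fixture(scope="session")
def recovery_scene(recovery_params):
    return cq.generate_scene(recovery_params)


def match_truth_to_labels(truth: cq.GroundTruth, features: pd.DataFrame) -> dict[int, int]:
    """Map ground-truth nucleus ids to segmentation labels by nearest centroid."""
    tree = cKDTree(features[["centroid_row", "centroid_col"]].to_numpy())
    _, idx = tree.query(truth.nuclei[["row", "col"]].to_numpy())
    return dict(zip(truth.nuclei["id"].astype(int), features["label"].to_numpy()[idx]))


@pytest.fixture(scope="session")
def quantified_marker_scene(marker_scene):
    """Segmentation + regions + per-marker calls for the marker scene."""
    params, scene, truth = marker_scene
    label_map = cq.segment_nuclei(scene)
    features = cq.compute_features(label_map)
    regions = cq.assign_cytoplasm(label_map, expansion_radius=params.marker_radius)
    truth_to_label = match_truth_to_labels(truth, features)
    return {
        "params": params, "scene": scene, "truth": truth,
        "label_map": label_map, "features": features, "regions": regions,
        "truth_to_label": truth_to_label,
    }
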