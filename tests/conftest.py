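"""Shared fixtures: synthetic label volumes, random graphs, small datasets."""

import nibabel as nib
import numpy as np
import pytest

from modnet import (
    SyntheticConfig,
    assign_brodmann,
    build_module_hierarchy,
    compute_parcel_centroids,
    generate_dataset,
    load_language_hierarchy,
    split_anterior_posterior,
)


@pytest.fixture(scope="session")
def hierarchy():
    return load_language_hierarchy()


def make_img(data, affine=None):
    if affine is None:
        affine = np.eye(4)
    return nib.Nifti1Image(np.asarray(data, dtype=np.int16), np.asarray(affine, float))


@pytest.fixture(scope="session")
def synthetic_atlas(hierarchy):
    """A small two-hemisphere parcellation plus a BA map covering every
    hierarchy member, built on a 20x20x8 grid with x in [-10, 9] mm.

    One parcel per (hemisphere, BA, y-slab) cell; BA21/BA22 occupy two
    y-slabs each so the anterior/posterior split has members on both sides
    of the median.
    """
    shape = (20, 20, 8)
    affine = np.array([[1.0, 0, 0, -10.0],  # voxel i -> x-10: i<10 left, i>=10 right
                       [0, 1.0, 0, -10.0],
                       [0, 0, 1.0, 0.0],
                       [0, 0, 0, 1.0]])
    bas = sorted(hierarchy.language_bas)
    parc = np.zeros(shape, dtype=int)
    ba_map = np.zeros(shape, dtype=int)
    label = 0
    for x0 in (2, 14):                               # left block / right block
        for bi, ba in enumerate(bas):
            parts = 2 if ba in hierarchy.split_bas else 1
            for part in range(parts):                # one 2x2x2 parcel each
                label += 1
                y0 = (bi % 5) * 4 + part * 2
                z0 = (bi // 5) * 3
                parc[x0:x0 + 2, y0:y0 + 2, z0:z0 + 2] = label
                ba_map[x0:x0 + 2, y0:y0 + 2, z0:z0 + 2] = ba
    return make_img(parc, affine), make_img(ba_map, affine)


@pytest.fixture(scope="session")
def assigned_nodes(synthetic_atlas, hierarchy):
    parc, ba_img = synthetic_atlas
    nodes = compute_parcel_centroids(parc)
    labeling = assign_brodmann(nodes, ba_img, hierarchy.language_bas)
    for ba in sorted(hierarchy.split_bas):
        labeling = split_anterior_posterior(labeling, nodes, ba,
                                            reference="map_voxels", ba_img=ba_img)
    assignment = build_module_hierarchy(labeling, nodes, hierarchy)
    return nodes, labeling, assignment


def random_graph(rng, n, p=0.4):
    """Seeded Erdos-Renyi adjacency matrix."""
    A = (rng.random((n, n)) < p).astype(np.uint8)
    A = np.triu(A, 1)
    return A + A.T


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 6-subject dataset reused by pipeline-level tests."""
    cfg = SyntheticConfig(n_subjects=6, n_volumes=120, seed=7)
    return generate_dataset(cfg)
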