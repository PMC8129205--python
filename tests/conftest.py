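import numpy as np
import pytest

from tracemap import synth
from tracemap.boundary import LabeledPoints
from tracemap.swc import DENDRITE_TYPE, SOMA_TYPE, NeuronMorphology


@pytest.fixture(scope="session")
def section_fixture():
    """Default synthetic section image plus its ground-truth blob mask."""
    spec = synth.SectionSpec(seed=3)
    img, mask = synth.gen_section_image(spec)
    return spec, img, mask


@pytest.fixture(scope="session")
def small_cloud():
    """Small three-domain point cloud for fast boundary tests."""
    spec = synth.DomainCloudSpec.default("L1", seed=5, n_points_per_domain=120)
    return synth.gen_domain_points(spec)


@pytest.fixture(scope="session")
def separable_points():
    """Linearly separable two-class training set."""
    rng = np.random.default_rng(0)
    a = rng.normal([20.0, 20.0], 2.0, (60, 2))
    b = rng.normal([80.0, 80.0], 2.0, (60, 2))
    return LabeledPoints(
        level_id="L0",
        points=np.vstack([a, b]),
        labels=np.array(["medial"] * 60 + ["lateral"] * 60, dtype=object),
    )


def path_neuron(offsets, radius=1.0):
    """Unbranched neuron from successive 3D offsets starting at the soma."""
    pts = np.cumsum(np.asarray(offsets, dtype=float), axis=0)
    n = len(pts)
    return NeuronMorphology(
        ids=np.arange(1, n + 2),
        types=np.array([SOMA_TYPE] + [DENDRITE_TYPE] * n),
        xyz=np.vstack([np.zeros(3), pts]),
        radius=np.full(n + 1, radius),
        parent=np.concatenate([[-1], np.arange(1, n + 1)]),
    )


def binary_tree_neuron(depth=3, seg_len=10.0, radius=1.0):
    """Symmetric full binary tree; each branch is a single straight segment.

    The stem leaves the soma along +x and each bifurcation splits in the
    y-dimension, so all geometry is exact for hand counting.
    """
    ids = [1]
    types = [SOMA_TYPE]
    xyz = [np.zeros(3)]
    radius_list = [radius]
    parent = [-1]

    def add(pos, par):
        nid = len(ids) + 1
        ids.append(nid)
        types.append(DENDRITE_TYPE)
        xyz.append(np.asarray(pos, dtype=float))
        radius_list.append(radius)
        parent.append(par)
        return nid

    stem_end = add([seg_len, 0.0, 0.0], 1)
    frontier = [(stem_end, np.array([seg_len, 0.0, 0.0]), seg_len)]
    for level in range(depth):
        nxt = []
        for par, pos, spread in frontier:
            for sign in (+1, -1):
                child_pos = pos + [seg_len, sign * spread / 2.0, 0.0]
                cid = add(child_pos, par)
                nxt.append((cid, child_pos, spread / 2.0))
        frontier = nxt
    return NeuronMorphology(
        ids=np.array(ids),
        types=np.array(types),
        xyz=np.vstack(xyz),
        radius=np.array(radius_list),
        parent=np.array(parent),
    )


@pytest.fixture(scope="session")
def default_neuron():
    return synth.gen_neuron(synth.NeuronSpec(seed=1))
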