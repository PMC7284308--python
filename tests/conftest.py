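"""Shared fixtures: moderately sized synthetic stacks reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from mtphen import reconstruction as rec
from mtphen import segmentation as seg
from mtphen.synthgen import StackRecipe, generate_stack


@pytest.fixture(scope="session")
def small_stack():
    """A 40-nucleus spheroid stack with ground truth (seed-fixed)."""
    recipe = StackRecipe(n_nuclei=40, shape_zyx=(40, 200, 200), seed=1)
    stack, truth = generate_stack(recipe)
    return recipe, stack, truth


@pytest.fixture(scope="session")
def small_stack_segmented(small_stack):
    """The same stack segmented and reconstructed (KZ=12)."""
    _, stack, truth = small_stack
    per_slice = seg.segment_stack(stack, "dapi", seg.SegmentationParams(kr=5))
    nuclei = rec.reconstruct(
        per_slice,
        rec.ReconstructionParams(kz=12),
        stack.um_per_px,
        stack.z_step_um,
    )
    return stack, truth, per_slice, nuclei


def match_to_truth(nuclei, truth, max_dist_um=5.0):
    """Index of the nearest ground-truth nucleus for each reconstruction,
    with a matched mask."""
    from scipy.spatial import cKDTree

    cent = np.array([n.centroid_um for n in nuclei])
    tru = truth[["center_z_um", "center_y_um", "center_x_um"]].to_numpy()
    d, j = cKDTree(tru).query(cent)
    return j, d < max_dist_um, d
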