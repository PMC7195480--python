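"""Shared fixtures: synthetic stacks and truth-matching helpers."""

from dataclasses import replace

import numpy as np
import pytest
import scipy.ndimage as ndi

from mitocal.preprocess import segment_mitochondria, smooth, subtract_background
from mitocal.synthetic import StackSpec, generate_stack

NOISE_FREE = dict(background_offset=0.0, poisson_noise=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_noisy_stack():
    """Default spec (50 objects, shot + read noise + background), seed 42."""
    return generate_stack(StackSpec(), seed=42)


@pytest.fixture(scope="session")
def clean_stack():
    """Noise-free variant of the default spec, seed 42."""
    return generate_stack(replace(StackSpec(), **NOISE_FREE), seed=42)


@pytest.fixture(scope="session")
def segmented_noisy(default_noisy_stack):
    stack, truth = default_noisy_stack
    bsub, _ = subtract_background(stack)
    return segment_mitochondria(smooth(bsub)), truth


@pytest.fixture(scope="session")
def segmented_clean(clean_stack):
    stack, truth = clean_stack
    bsub, _ = subtract_background(stack)
    return segment_mitochondria(smooth(bsub)), truth


def match_objects(truth_labels, seg_labels, voxel_size):
    """Per-truth-object best-overlap match: (iou, centroid_error_um) arrays."""
    vs = np.asarray(voxel_size, float)
    n = int(truth_labels.max())
    ious = np.zeros(n)
    cerr = np.full(n, np.nan)
    for k in range(1, n + 1):
        tm = truth_labels == k
        labs, counts = np.unique(seg_labels[tm], return_counts=True)
        labs, counts = labs[labs > 0], counts[labs > 0]
        if len(labs) == 0:
            continue
        j = labs[np.argmax(counts)]
        sm = seg_labels == j
        ious[k - 1] = np.logical_and(tm, sm).sum() / np.logical_or(tm, sm).sum()
        ct = np.array(ndi.center_of_mass(tm)) * vs
        cs = np.array(ndi.center_of_mass(sm)) * vs
        cerr[k - 1] = np.linalg.norm(ct - cs)
    return ious, cerr


def flood_fill_component(mask, start, connectivity):
    """Brute-force BFS connected component of ``start`` in a boolean mask."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                order = abs(dz) + abs(dy) + abs(dx)
                if 0 < order <= connectivity:
                    offsets.append((dz, dy, dx))
    seen = {tuple(start)}
    frontier = [tuple(start)]
    shape = mask.shape
    while frontier:
        z, y, x = frontier.pop()
        for dz, dy, dx in offsets:
            p = (z + dz, y + dy, x + dx)
            if (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1] and 0 <= p[2] < shape[2]
                    and p not in seen and mask[p]):
                seen.add(p)
                frontier.append(p)
    return seen
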