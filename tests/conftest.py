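"""Shared fixtures: deterministic backend, saccade law, and worked scanpaths."""

import numpy as np
import pytest

import refixate as rf
from refixate.scanpath import Fixation, Scanpath


def make_scanpath(points, extent=(30.0, 30.0), **kw):
    """Scanpath from bare (x, y) dva points with synthetic timing."""
    return Scanpath(
        fixations=tuple(
            Fixation(x=float(x), y=float(y), onset=i * 250.0, duration=200.0)
            for i, (x, y) in enumerate(points)
        ),
        extent=extent,
        **kw,
    )


def brute_force_annotation(points, threshold):
    """Independent all-pairs reference for return labeling (pure loops).

    Returns (labels, events) with events as (return_index, source_index,
    offset) 1-based tuples, pairing each return with the most recent
    qualifying earlier fixation.
    """
    n = len(points)
    labels = ["non_return"] * n
    events = []
    for i in range(n):
        match = None
        for j in range(i):
            dx = points[i][0] - points[j][0]
            dy = points[i][1] - points[j][1]
            if (dx * dx + dy * dy) ** 0.5 <= threshold:
                match = j  # keep scanning: most recent wins
        if match is not None:
            labels[i] = "return"
            events.append((i + 1, match + 1, i - match - 1))
    for _, src, _ in events:
        if labels[src - 1] == "non_return":
            labels[src - 1] = "to_be_revisited"
    return labels, events


@pytest.fixture(scope="session")
def backend():
    return rf.synthetic_backend(seed=0)


@pytest.fixture(scope="session")
def saccade_dist():
    return rf.sample_saccade_distribution(seed=0)


@pytest.fixture()
def fig_style_scanpath():
    """Eight fixations where #6 revisits #3 and #7 revisits #5.

    All other pairs are far apart, so the expected labels are: returns
    {6, 7}, to-be-revisited {3, 5}, non-return {1, 2, 4, 8}.
    """
    points = [
        (2.0, 2.0),    # 1
        (12.0, 2.0),   # 2
        (22.0, 3.0),   # 3
        (6.0, 12.0),   # 4
        (16.0, 20.0),  # 5
        (22.4, 3.3),   # 6  near 3
        (16.5, 20.2),  # 7  near 5
        (5.0, 26.0),   # 8
    ]
    return make_scanpath(points)


def random_scanpath(rng, n=50, extent=(30.0, 30.0)):
    pts = np.column_stack(
        [rng.uniform(0, extent[0], n), rng.uniform(0, extent[1], n)]
    )
    return make_scanpath([tuple(p) for p in pts], extent=extent)
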