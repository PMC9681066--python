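"""Seeded generators for every input the analysis and model need.

Everything here is deterministic given a seed: grayscale stimuli with
planted salient objects (emulating object-array and naturalistic scene
classes), scanpaths with a controlled number of planted return fixations
(ground truth for oracle tests), gamma-law saccade-amplitude histograms,
and a fixed-filter convolutional feature backend so the model runs fully
offline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal
from skimage.measure import block_reduce

from .model import FeatureBackend, SaccadeSizeDistribution
from .scanpath import Fixation, Label, Scanpath

logger = logging.getLogger("refixate")

#: Default synthetic stimulus geometry: 20 x 16 dva at 8 px/dva, so the
#: two-level pooled feature lattice lands on 32 x 40 cells.
DEFAULT_EXTENT = (20.0, 16.0)
DEFAULT_PX_PER_DVA = 8

#: Gamma law for synthetic saccade amplitudes (mean 4 dva, mode 2 dva),
#: matching the small-saccade bias of primate eye movements.
GAMMA_SHAPE_DEFAULT = 2.0
GAMMA_SCALE_DEFAULT = 2.0


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Recipe for one synthetic stimulus.

    ``object_array``: isolated high-contrast shapes on a uniform background
    at jittered grid positions, one of which is the designated search
    target.  ``naturalistic``: a 1/f-noise background with planted Gaussian
    contrast blobs of graded strength, plus a pasted target shape.
    """

    kind: Literal["object_array", "naturalistic"] = "naturalistic"
    extent: tuple[float, float] = DEFAULT_EXTENT
    px_per_dva: int = DEFAULT_PX_PER_DVA
    n_objects: int = 8
    target_index: int = 0
    contrast: float = 0.5
    object_size_dva: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.target_index < self.n_objects):
            raise ValueError("target index must address one of the objects")

    @property
    def image_shape(self) -> tuple[int, int]:
        w, h = self.extent
        return (round(h * self.px_per_dva), round(w * self.px_per_dva))


@dataclass(frozen=True)
class SyntheticScene:
    """A generated stimulus: image, target template, and target region."""

    image: np.ndarray                 # (H, W) grayscale in [0, 1]
    template: np.ndarray              # crop around the target object
    target_bbox: tuple[float, float, float, float]  # (x0, y0, x1, y1) dva
    object_centers: np.ndarray        # (n_objects, 2) dva
    spec: SyntheticSceneSpec

    @property
    def target_center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.target_bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def _shape_patch(kind: int, size_px: int, contrast: float) -> np.ndarray:
    """One of five primitive shapes on a zero (background-relative) patch."""
    s = size_px
    yy, xx = np.mgrid[0:s, 0:s]
    cx = cy = (s - 1) / 2.0
    r = s / 2.0
    patch = np.zeros((s, s), dtype=float)
    if kind == 0:  # disc
        patch[(xx - cx) ** 2 + (yy - cy) ** 2 <= (0.9 * r) ** 2] = contrast
    elif kind == 1:  # square
        m = round(0.15 * s)
        patch[m:s - m, m:s - m] = contrast
    elif kind == 2:  # plus
        w = max(1, round(0.2 * s))
        patch[:, int(cx - w):int(cx + w) + 1] = contrast
        patch[int(cy - w):int(cy + w) + 1, :] = contrast
    elif kind == 3:  # ring
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        patch[(d2 <= (0.9 * r) ** 2) & (d2 >= (0.45 * r) ** 2)] = contrast
    else:  # triangle
        patch[(yy >= 0.1 * s) & (np.abs(xx - cx) <= 0.45 * (yy - 0.1 * s))] = contrast
    return patch


def _pink_noise(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """1/f spatial noise scaled to zero mean, unit-ish range."""
    h, w = shape
    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    spectrum = np.fft.fft2(white) / f
    noise = np.real(np.fft.ifft2(spectrum))
    noise -= noise.mean()
    peak = np.abs(noise).max()
    return noise / peak if peak > 0 else noise


def gen_scene(spec: SyntheticSceneSpec) -> SyntheticScene:
    """Generate a stimulus with ``n_objects`` planted items, one a target.

    Object positions sit on a jittered grid, guaranteeing disjoint objects;
    an overcrowded spec (more objects than grid slots) raises.  The returned
    template is the verbatim crop of the target's bounding box, so a matched
    filter on the image features peaks inside the target region.
    """
    rng = np.random.default_rng(spec.seed)
    h_px, w_px = spec.image_shape
    w_dva, h_dva = spec.extent
    size_px = round(spec.object_size_dva * spec.px_per_dva)

    # jittered grid placement with a one-object margin at the borders
    pitch = 2.0 * spec.object_size_dva
    nx = int((w_dva - pitch) // pitch)
    ny = int((h_dva - pitch) // pitch)
    if nx * ny < spec.n_objects:
        raise ValueError(
            f"cannot place {spec.n_objects} objects of {spec.object_size_dva} "
            f"dva on a {w_dva} x {h_dva} dva scene"
        )
    slots = [(ix, iy) for ix in range(nx) for iy in range(ny)]
    chosen = rng.choice(len(slots), size=spec.n_objects, replace=False)
    centers = []
    for k in chosen:
        ix, iy = slots[k]
        jx, jy = rng.uniform(-0.2, 0.2, 2) * spec.object_size_dva
        centers.append((pitch * (ix + 1) + jx, pitch * (iy + 1) + jy))
    centers = np.asarray(centers)

    if spec.kind == "object_array":
        image = np.full((h_px, w_px), 0.5, dtype=float)
        contrasts = np.full(spec.n_objects, spec.contrast)
    elif spec.kind == "naturalistic":
        image = 0.5 + 0.18 * _pink_noise((h_px, w_px), rng)
        # graded blob strengths so the scene has a saliency ranking
        contrasts = spec.contrast * np.linspace(1.0, 0.45, spec.n_objects)
    else:
        raise ValueError(f"unknown scene kind: {spec.kind!r}")

    # the target's shape kind is unique in the display; distractors draw
    # from the remaining primitives and are smaller, so the search item is
    # discriminable (as in object-array search displays)
    target_kind = int(rng.integers(5))
    other_kinds = [k for k in range(5) if k != target_kind]
    shape_kinds = rng.choice(other_kinds, size=spec.n_objects)
    shape_kinds[spec.target_index] = target_kind
    for i, ((cx, cy), c) in enumerate(zip(centers, contrasts)):
        # distractors are drawn smaller than the target so the display has a
        # unique, discriminable search item
        scale = 1.0 if i == spec.target_index else 0.7
        sz = max(3, round(scale * size_px))
        patch = _shape_patch(int(shape_kinds[i]), sz, c)
        r0 = round(cy * spec.px_per_dva - sz / 2)
        c0 = round(cx * spec.px_per_dva - sz / 2)
        image[r0:r0 + sz, c0:c0 + sz] += patch
    image = np.clip(image, 0.0, 1.0)

    tx, ty = centers[spec.target_index]
    half = spec.object_size_dva / 2.0
    bbox = (tx - half, ty - half, tx + half, ty + half)
    r0 = round((ty - half) * spec.px_per_dva)
    c0 = round((tx - half) * spec.px_per_dva)
    template = image[r0:r0 + size_px, c0:c0 + size_px].copy()
    return SyntheticScene(
        image=image, template=template, target_bbox=bbox,
        object_centers=centers, spec=spec,
    )


# ---------------------------------------------------------------------------
# Scanpaths with planted returns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticScanpathSpec:
    """Recipe for a scanpath with a known number of return fixations."""

    n_fixations: int = 15
    return_rate: float = 0.0
    gamma_shape: float = GAMMA_SHAPE_DEFAULT
    gamma_scale: float = GAMMA_SCALE_DEFAULT
    threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.return_rate < 1.0):
            raise ValueError("return rate must lie in [0, 1)")
        n_planted = round(self.return_rate * self.n_fixations)
        if n_planted > self.n_fixations - 2:
            raise ValueError("cannot plant that many returns")


@dataclass(frozen=True)
class GroundTruth:
    labels: tuple[Label, ...]
    return_indices: tuple[int, ...]   # 1-based
    source_indices: tuple[int, ...]   # 1-based, aligned with return_indices


def gen_scanpath(
    spec: SyntheticScanpathSpec,
    extent: tuple[float, float] = DEFAULT_EXTENT,
) -> tuple[Scanpath, GroundTruth]:
    """Gamma-amplitude wander with exactly the requested planted returns.

    Base fixations are kept at least 2.5 thresholds apart, so the only
    within-threshold pairs are the planted (source, return) pairs, placed at
    half the threshold distance.  The ground-truth labels therefore coincide
    exactly with distance-rule annotation at the planting threshold.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = extent
    n = spec.n_fixations
    sep = 2.5 * spec.threshold
    margin = spec.threshold  # keep planted points inside the extent

    points: list[np.ndarray] = []
    for i in range(n):
        for attempt in range(4000):
            if i == 0:
                cand = rng.uniform([margin, margin], [w - margin, h - margin])
            else:
                amp = rng.gamma(spec.gamma_shape, spec.gamma_scale)
                ang = rng.uniform(0, 2 * np.pi)
                cand = points[-1] + amp * np.array([np.cos(ang), np.sin(ang)])
            inside = (margin <= cand[0] <= w - margin) and (margin <= cand[1] <= h - margin)
            if inside and all(np.linalg.norm(cand - p) >= sep for p in points):
                points.append(cand)
                break
        else:
            raise ValueError(
                f"could not place fixation {i + 1}: extent too small for "
                f"{n} fixations separated by {sep:.2f} dva"
            )

    n_planted = round(spec.return_rate * n)
    labels: list[Label] = ["non_return"] * n
    return_idx: list[int] = []
    source_idx: list[int] = []
    if n_planted:
        # returns occupy the tail; sources come from the head, offset >= 1
        candidates = list(range(n - n_planted, n))
        sources = list(rng.choice(n - n_planted - 1, size=n_planted, replace=False))
        for ri, si in zip(candidates, sorted(int(s) for s in sources)):
            ang = rng.uniform(0, 2 * np.pi)
            points[ri] = points[si] + 0.5 * spec.threshold * np.array(
                [np.cos(ang), np.sin(ang)])
            labels[ri] = "return"
            labels[si] = "to_be_revisited"
            return_idx.append(ri + 1)
            source_idx.append(si + 1)

    sp = Scanpath(
        fixations=tuple(
            Fixation(x=float(p[0]), y=float(p[1]), onset=i * 250.0,
                     duration=float(rng.uniform(150, 350)))
            for i, p in enumerate(points)
        ),
        subject_id=f"synth{spec.seed}",
        trial_id="synthetic",
        task="synthetic",
        extent=extent,
    )
    gt = GroundTruth(
        labels=tuple(labels),
        return_indices=tuple(return_idx),
        source_indices=tuple(source_idx),
    )
    return sp, gt


def sample_saccade_distribution(
    shape: float = GAMMA_SHAPE_DEFAULT,
    scale: float = GAMMA_SCALE_DEFAULT,
    n: int = 100_000,
    seed: int = 0,
    bin_width: float = 0.5,
) -> SaccadeSizeDistribution:
    """Empirical saccade-size histogram from ``n`` gamma draws, 0.5-dva bins."""
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    if n < 100:
        logger.warning("sample_saccade_distribution: only %d draws; histogram noisy", n)
    rng = np.random.default_rng(seed)
    return SaccadeSizeDistribution.from_samples(
        rng.gamma(shape, scale, size=n), bin_width=bin_width)


# ---------------------------------------------------------------------------
# Deterministic feature backend
# ---------------------------------------------------------------------------

class SyntheticBackend(FeatureBackend):
    """Fixed-seed random convolutional feature extractor.

    Two stages of zero-mean random filters, half-wave rectification, and
    2x2 average pooling; fully deterministic given the seed, translation
    covariant up to the 4-pixel pooling grain, and needs no downloaded
    weights.  Zero-mean filters respond to contrast structure and not to
    uniform regions, so the channel-mean map behaves as a center-surround
    contrast proxy; average (rather than max) pooling keeps feature
    signatures stable under sub-pooling-grid shifts, which matters for the
    matched-filter similarity map.

    ``modulation_features`` and ``template_features`` share the same weights
    (the same "network" processes the search and target images, as the
    attention model requires); ``embedding`` is channel-wise mean+max
    pooling of the final stack.
    """

    def __init__(self, seed: int = 0, c1: int = 8, c2: int = 12) -> None:
        rng = np.random.default_rng(seed)
        self.seed = seed
        k1 = rng.standard_normal((c1, 5, 5))
        k1 -= k1.mean(axis=(1, 2), keepdims=True)
        k2 = rng.standard_normal((c2, c1, 3, 3))
        k2 -= k2.mean(axis=(1, 2, 3), keepdims=True)
        self._k1 = k1 / math.sqrt(25)
        self._k2 = k2 / math.sqrt(9 * c1)

    @staticmethod
    def _to_gray(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        if img.ndim != 2:
            raise ValueError("images must be 2D grayscale or 3D RGB arrays")
        return img

    def _forward(self, image: np.ndarray) -> np.ndarray:
        x = self._to_gray(image)
        h1 = np.stack([
            signal.correlate2d(x, k, mode="same", boundary="symm")
            for k in self._k1
        ])
        h1 = np.maximum(h1, 0.0)
        h1 = block_reduce(h1, (1, 2, 2), np.mean)
        h2 = np.stack([
            sum(signal.correlate2d(h1[j], self._k2[i, j], mode="same",
                                   boundary="symm")
                for j in range(h1.shape[0]))
            for i in range(self._k2.shape[0])
        ])
        h2 = np.maximum(h2, 0.0)
        return block_reduce(h2, (1, 2, 2), np.mean)

    def modulation_features(self, image: np.ndarray) -> np.ndarray:
        return self._forward(image)

    def template_features(self, image: np.ndarray) -> np.ndarray:
        return self._forward(image)

    def embedding(self, image: np.ndarray) -> np.ndarray:
        feat = self._forward(image)
        return np.concatenate([feat.mean(axis=(1, 2)), feat.max(axis=(1, 2))])


def synthetic_backend(seed: int = 0) -> SyntheticBackend:
    """Convenience constructor mirroring the other generator signatures."""
    return SyntheticBackend(seed=seed)


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def write_fixtures(
    out_dir,
    n_scenes: int = 3,
    n_scanpaths: int = 3,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Emit a small fixtures/ tree: PNG scenes, fixation TSV, YAML specs."""
    import os

    import yaml
    from skimage.io import imsave

    from .scanpath import write_fixation_tsv

    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, list[str]] = {"images": [], "tables": [], "specs": []}
    scanpaths = []
    for i in range(n_scenes):
        spec = SyntheticSceneSpec(seed=seed + i)
        scene = gen_scene(spec)
        img_path = os.path.join(out_dir, f"scene_{i:02d}.png")
        imsave(img_path, (scene.image * 255).astype(np.uint8), check_contrast=False)
        tmpl_path = os.path.join(out_dir, f"target_{i:02d}.png")
        imsave(tmpl_path, (scene.template * 255).astype(np.uint8), check_contrast=False)
        spec_path = os.path.join(out_dir, f"scene_{i:02d}.yaml")
        with open(spec_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "kind": spec.kind, "extent": list(spec.extent),
                    "px_per_dva": spec.px_per_dva, "n_objects": spec.n_objects,
                    "target_index": spec.target_index, "seed": spec.seed,
                    "target_bbox_dva": [float(v) for v in scene.target_bbox],
                },
                fh,
            )
        written["images"] += [img_path, tmpl_path]
        written["specs"].append(spec_path)
    for i in range(n_scanpaths):
        sp, _ = gen_scanpath(
            SyntheticScanpathSpec(seed=seed + i, return_rate=0.2))
        scanpaths.append(sp)
    tsv_path = os.path.join(out_dir, "fixations.tsv")
    write_fixation_tsv(scanpaths, tsv_path)
    written["tables"].append(tsv_path)
    return written
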