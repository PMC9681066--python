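"""Generative winner-take-all model of primate eye movements.

The model fixates wherever a combined attention map peaks.  Four component
maps live on a common lattice (the feature-map resolution of the backend)
and are each min-max normalized to [0, 1] before a fixed linear
combination:

    M_f,t = w_mem * M_mem,t + w_sac * M_sac,t + w_sim * M_sim + w_sal * M_sal

* ``M_sim`` — target similarity: the target's high-level feature stack
  cross-correlated over the search image's feature stack (visual search
  only, ``w_sim = 1``).
* ``M_sal`` — bottom-up saliency: the channel mean of the feature stack
  (free viewing only, ``w_sal = 1``).
* ``M_sac,t`` — saccade-size prior: a radially symmetric map around the
  current fixation built from an empirical saccade-amplitude distribution.
* ``M_mem,t`` — finite inhibition-of-return: Gaussian bumps at past
  fixations whose amplitudes decay geometrically (``alpha`` per fixation)
  down to a floor ``beta``; revisits overwrite the decayed value.  The
  negative weight ``w_mem`` turns remembered locations into inhibition.

A winner-take-all picks the lattice maximum as the next fixation.  Search
trials stop when a recognition step (cosine distance between the foveal
patch embedding and the target embedding) falls below threshold; free
viewing stops after a fixed fixation budget.

The similarity and saliency maps are static within a trial and normalized
once; the saccade and memory maps are rebuilt and normalized at every step.
Because the memory floor ``beta`` is positive, inhibition never fully
protects a visited location, which is what permits return fixations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Protocol, runtime_checkable

import numpy as np
from scipy import signal

from .scanpath import Fixation, Scanpath

logger = logging.getLogger("refixate")

# Weights fitted once on a natural-image visual-search dataset and then held
# fixed across tasks; they are model constants, not per-dataset fits.
W_MEM_DEFAULT = -0.93
W_SAC_DEFAULT = 0.2346
ALPHA_DEFAULT = 0.92
BETA_DEFAULT = 0.5
SIGMA_OBJECT_ARRAYS = 0.08   # memory Gaussian width, fraction of image width
SIGMA_DEFAULT = 0.02
RECOG_THRESHOLD_ARRAYS_WALDO = 0.5
RECOG_THRESHOLD_NATURAL = 0.3


# ---------------------------------------------------------------------------
# Feature backend contract
# ---------------------------------------------------------------------------

@runtime_checkable
class FeatureBackend(Protocol):
    """Fixed-weight convolutional feature extractor.

    The same backend instance must process both the target and the search
    image; its parameters are never fit here.  Any deep convolutional
    network exposing these three views (e.g. a pre-trained classification
    network with its two top convolutional layers and a final embedding)
    satisfies the contract; the package ships a deterministic random-filter
    backend (:class:`refixate.synth.SyntheticBackend`) used throughout the
    tests.
    """

    def modulation_features(self, image: np.ndarray) -> np.ndarray:
        """C x H x W feature stack of the search image (modulation level)."""
        ...

    def template_features(self, image: np.ndarray) -> np.ndarray:
        """C x h x w feature stack of the target image (template level)."""
        ...

    def embedding(self, image: np.ndarray) -> np.ndarray:
        """1D embedding vector used for the recognition decision."""
        ...


@dataclass(frozen=True)
class ModelConfig:
    """All model parameters with their task-independent defaults.

    ``sigma`` is the memory Gaussian width as a fraction of image width
    (0.08 for sparse object arrays, where the mask must cover a whole
    object; 0.02 otherwise).  ``w_sim``/``w_sal`` act as a task switch:
    search uses the similarity map, free viewing the saliency map, never
    both.
    """

    w_sim: float = 0.0
    w_sal: float = 1.0
    w_mem: float = W_MEM_DEFAULT
    w_sac: float = W_SAC_DEFAULT
    alpha: float = ALPHA_DEFAULT
    beta: float = BETA_DEFAULT
    sigma: float = SIGMA_DEFAULT
    recognition_threshold: float = RECOG_THRESHOLD_NATURAL
    recognition_patch: float = 1.0  # dva; the foveal crop compared to the target
    n_fixations_free: int | None = None
    max_fixations: int = 80

    def __post_init__(self) -> None:
        if self.w_sim * self.w_sal != 0:
            raise ValueError("w_sim and w_sal cannot both be active")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.beta < 1):
            raise ValueError("beta must lie in (0, 1)")

    @classmethod
    def for_search(cls, **kw) -> "ModelConfig":
        return cls(w_sim=1.0, w_sal=0.0, **kw)

    @classmethod
    def for_free_viewing(cls, n_fixations: int, **kw) -> "ModelConfig":
        return cls(w_sim=0.0, w_sal=1.0, n_fixations_free=n_fixations, **kw)


@dataclass(frozen=True)
class SaccadeSizeDistribution:
    """Empirical saccade-amplitude histogram with a continuous-radius view.

    ``bin_edges`` are in dva (len nb+1); ``probs`` sum to one.  The density
    at an arbitrary radius is linearly interpolated between bin centers and
    zero outside the histogram support; the 2D prior map assumes radial
    symmetry around the current fixation.
    """

    bin_edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if edges.ndim != 1 or p.ndim != 1 or len(edges) != len(p) + 1:
            raise ValueError("need len(bin_edges) == len(probs) + 1")
        if len(p) == 0:
            raise ValueError("empty saccade distribution")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        total = p.sum()
        if total <= 0:
            raise ValueError("saccade distribution has no mass")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probs", p / total)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def density(self, radius: np.ndarray | float) -> np.ndarray:
        """Interpolated probability mass at the given radial distance(s).

        Piecewise linear between bin centers, constant across the two outer
        half-bins, zero outside the histogram support (so a single-bin
        point-mass histogram yields an indicator on its bin).
        """
        knots = np.concatenate(([self.bin_edges[0]], self.bin_centers,
                                [self.bin_edges[-1]]))
        vals = np.concatenate(([self.probs[0]], self.probs, [self.probs[-1]]))
        return np.interp(np.asarray(radius, dtype=float),
                         knots, vals, left=0.0, right=0.0)

    def sample(self, rng: np.random.Generator, size: int | tuple = 1) -> np.ndarray:
        """Draw amplitudes: a bin by probability, then uniform within it."""
        bins = rng.choice(len(self.probs), size=size, p=self.probs)
        lo = self.bin_edges[bins]
        hi = self.bin_edges[bins + 1]
        return rng.uniform(lo, hi)

    @classmethod
    def from_samples(
        cls, amplitudes: np.ndarray, bin_width: float = 0.5
    ) -> "SaccadeSizeDistribution":
        amps = np.asarray(amplitudes, dtype=float)
        edges = np.arange(0.0, amps.max() + bin_width, bin_width)
        if len(edges) < 2:
            edges = np.array([0.0, bin_width])
        counts, edges = np.histogram(amps, bins=edges)
        return cls(bin_edges=edges, probs=counts.astype(float) / max(counts.sum(), 1))


# ---------------------------------------------------------------------------
# Lattice geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lattice:
    """Common map lattice: ``shape`` (rows, cols) covering ``extent`` dva."""

    shape: tuple[int, int]
    extent: tuple[float, float]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) dva coordinates of every cell center, each shaped (rows, cols)."""
        rows, cols = self.shape
        w, h = self.extent
        xs = (np.arange(cols) + 0.5) * w / cols
        ys = (np.arange(rows) + 0.5) * h / rows
        return np.meshgrid(xs, ys)

    def to_dva(self, row: int, col: int) -> tuple[float, float]:
        rows, cols = self.shape
        w, h = self.extent
        return ((col + 0.5) * w / cols, (row + 0.5) * h / rows)

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        rows, cols = self.shape
        w, h = self.extent
        col = int(np.clip(math.floor(x / w * cols), 0, cols - 1))
        row = int(np.clip(math.floor(y / h * rows), 0, rows - 1))
        return row, col


@dataclass
class AttentionMapStack:
    """The four component maps plus the integrated map at one fixation step."""

    m_sim: np.ndarray | None
    m_sal: np.ndarray | None
    m_sac: np.ndarray
    m_mem: np.ndarray
    m_f: np.ndarray
    step: int


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant map collapses to all zeros."""
    m = np.asarray(m, dtype=float)
    lo, hi = float(m.min()), float(m.max())
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Component maps
# ---------------------------------------------------------------------------

def compute_similarity_map(
    backend: FeatureBackend,
    target_image: np.ndarray,
    search_image: np.ndarray,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Target-similarity map: template features cross-correlated over search.

    Channel-wise product summed over channels and kernel support (a matched
    filter for the target in feature space), evaluated with zero padding at
    the borders.  ``out_shape`` optionally bilinearly resamples the result
    (e.g. to the image pixel lattice).
    """
    search = np.asarray(backend.modulation_features(search_image), dtype=float)
    tmpl = np.asarray(backend.template_features(target_image), dtype=float)
    if search.ndim != 3 or tmpl.ndim != 3:
        raise ValueError("feature stacks must be C x H x W")
    if tmpl.shape[0] != search.shape[0]:
        raise ValueError("channel counts differ between template and search")
    if tmpl.shape[1] > search.shape[1] or tmpl.shape[2] > search.shape[2]:
        raise ValueError("template feature map larger than search feature map")
    out = np.zeros(search.shape[1:], dtype=float)
    for c in range(search.shape[0]):
        out += signal.correlate(search[c], tmpl[c], mode="same", method="auto")
    return _maybe_resample(out, out_shape)


def compute_saliency_map(
    backend: FeatureBackend,
    search_image: np.ndarray,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Bottom-up saliency: channel mean of the modulation-level stack.

    Equivalent to modulation by an all-ones 1x1 kernel across channels.
    """
    stack = np.asarray(backend.modulation_features(search_image), dtype=float)
    if stack.ndim != 3:
        raise ValueError("feature stack must be C x H x W")
    return _maybe_resample(stack.mean(axis=0), out_shape)


def _maybe_resample(m: np.ndarray, out_shape: tuple[int, int] | None) -> np.ndarray:
    if out_shape is None or tuple(out_shape) == m.shape:
        return m
    from skimage.transform import resize

    return resize(m, out_shape, order=1, mode="edge", anti_aliasing=False)


def saccade_prior_map(
    current_fixation: tuple[float, float],
    dist: SaccadeSizeDistribution,
    lattice: Lattice,
) -> np.ndarray:
    """Radially symmetric saccade prior around the current fixation (dva)."""
    X, Y = lattice.cell_centers()
    r = np.hypot(X - current_fixation[0], Y - current_fixation[1])
    return normalize_map(dist.density(r))


def memory_value(t_tilde: int, t: int, alpha: float = ALPHA_DEFAULT,
                 beta: float = BETA_DEFAULT) -> float:
    """Memory decay a_t = alpha^(t~ - t), clipped below at beta.

    ``t_tilde`` is the current (most recent) fixation number, ``t`` the
    fixation whose memory trace is queried; the most recent location keeps
    full strength 1, and inhibition never decays past the floor ``beta``.
    """
    if t > t_tilde:
        raise ValueError("t must not exceed t_tilde")
    if t < 1:
        raise ValueError("fixation numbers are 1-based")
    return max(alpha ** (t_tilde - t), beta)


@dataclass
class MemoryState:
    """History of fixated lattice locations (dva) for the memory map."""

    history: list[tuple[float, float]] = field(default_factory=list)

    def push(self, xy: tuple[float, float]) -> None:
        self.history.append(xy)


def memory_map(
    state: MemoryState,
    lattice: Lattice,
    alpha: float = ALPHA_DEFAULT,
    beta: float = BETA_DEFAULT,
    sigma: float = SIGMA_DEFAULT,
) -> np.ndarray:
    """Finite-IOR memory map: pointwise max over decayed Gaussian bumps.

    Each past fixation t contributes a Gaussian of amplitude a_t (decay
    clipped at ``beta``) and width ``sigma`` (fraction of image width,
    converted to dva).  Taking the maximum rather than the sum means a
    revisit overwrites the decayed trace at a to-be-revisited location.
    Empty history yields an all-zero map.
    """
    rows, cols = lattice.shape
    if not state.history:
        return np.zeros((rows, cols), dtype=float)
    X, Y = lattice.cell_centers()
    sigma_dva = sigma * lattice.extent[0]
    t_tilde = len(state.history)
    out = np.zeros((rows, cols), dtype=float)
    for t, (fx, fy) in enumerate(state.history, start=1):
        a_t = memory_value(t_tilde, t, alpha, beta)
        bump = a_t * np.exp(-((X - fx) ** 2 + (Y - fy) ** 2) / (2.0 * sigma_dva ** 2))
        np.maximum(out, bump, out=out)
    return out


def integrate_maps(stack: AttentionMapStack, config: ModelConfig) -> np.ndarray:
    """Weighted linear combination of the four normalized component maps."""
    shape = stack.m_sac.shape
    parts = [
        (config.w_mem, stack.m_mem),
        (config.w_sac, stack.m_sac),
        (config.w_sim, stack.m_sim),
        (config.w_sal, stack.m_sal),
    ]
    out = np.zeros(shape, dtype=float)
    for w, m in parts:
        if w == 0 or m is None:
            continue
        if m.shape != shape:
            raise ValueError(f"map shape mismatch: {m.shape} vs {shape}")
        out += w * m
    return out


def select_next_fixation(m_f: np.ndarray) -> tuple[int, int]:
    """Winner-take-all: argmax cell, ties broken at the lowest row-major index."""
    m = np.asarray(m_f, dtype=float)
    if np.isnan(m).all():
        raise ValueError("attention map is all-NaN")
    flat = int(np.nanargmax(m))
    return np.unravel_index(flat, m.shape)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Recognition
# ---------------------------------------------------------------------------

def _crop_patch(
    image: np.ndarray, x: float, y: float, extent: tuple[float, float],
    patch: float,
) -> np.ndarray:
    """Square ``patch``-dva crop centered at (x, y), zero-padded at borders."""
    img = np.asarray(image, dtype=float)
    h_px, w_px = img.shape[:2]
    w_dva, h_dva = extent
    half_w = patch / 2.0 * w_px / w_dva
    half_h = patch / 2.0 * h_px / h_dva
    cx, cy = x * w_px / w_dva, y * h_px / h_dva
    c0, c1 = int(round(cx - half_w)), int(round(cx + half_w))
    r0, r1 = int(round(cy - half_h)), int(round(cy + half_h))
    c1, r1 = max(c1, c0 + 1), max(r1, r0 + 1)
    out_shape = (r1 - r0, c1 - c0) + img.shape[2:]
    out = np.zeros(out_shape, dtype=float)
    rs, re = max(r0, 0), min(r1, h_px)
    cs, ce = max(c0, 0), min(c1, w_px)
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = img[rs:re, cs:ce]
    return out


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float | None:
    """1 - cosine similarity; ``None`` when an embedding is all-zero."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    return float(1.0 - np.dot(a, b) / (na * nb))


def recognize_at_fixation(
    backend: FeatureBackend,
    search_image: np.ndarray,
    fixation: tuple[float, float],
    target_image: np.ndarray,
    extent: tuple[float, float],
    threshold: float,
    patch: float = 1.0,
    target_embedding: np.ndarray | None = None,
    use_raw_similarity: bool = False,
) -> tuple[bool, float | None]:
    """Decide whether the target sits at the fixated location.

    Crops a ``patch``-dva square at the fixation, embeds it, and compares
    with the target embedding.  Default decision: cosine distance
    (1 - cosine similarity) below ``threshold`` means found.  With
    ``use_raw_similarity`` the raw cosine similarity is thresholded instead
    (found iff similarity > threshold).  A degenerate all-zero embedding
    yields not-found with a warning.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    crop = _crop_patch(search_image, fixation[0], fixation[1], extent, patch)
    emb = backend.embedding(crop)
    temb = target_embedding if target_embedding is not None \
        else backend.embedding(target_image)
    d = cosine_distance(emb, temb)
    if d is None:
        warnings.warn("degenerate zero embedding at fixation; target not found")
        return False, None
    if use_raw_similarity:
        return (1.0 - d) > threshold, d
    return d < threshold, d


def recognition_map(
    backend: FeatureBackend,
    search_image: np.ndarray,
    target_image: np.ndarray,
    extent: tuple[float, float],
    lattice: Lattice,
    stride: int = 1,
    patch: float = 1.0,
) -> np.ndarray:
    """Cosine-distance map sampled on the lattice every ``stride`` cells.

    Unsampled cells carry NaN; degenerate embeddings carry +inf (never
    recognized).
    """
    rows, cols = lattice.shape
    temb = backend.embedding(target_image)
    out = np.full((rows, cols), np.nan)
    for r in range(0, rows, stride):
        for c in range(0, cols, stride):
            x, y = lattice.to_dva(r, c)
            crop = _crop_patch(search_image, x, y, extent, patch)
            d = cosine_distance(backend.embedding(crop), temb)
            out[r, c] = np.inf if d is None else d
    return out


# ---------------------------------------------------------------------------
# Trial loop
# ---------------------------------------------------------------------------

Mode = Literal["search", "free_viewing"]

#: Nominal fixation timing used when emitting model scanpaths (the model has
#: no notion of duration; these keep the Scanpath invariants satisfied).
MODEL_FIXATION_PERIOD_MS = 250.0
MODEL_FIXATION_DURATION_MS = 200.0


def run_trial(
    backend: FeatureBackend,
    config: ModelConfig,
    search_image: np.ndarray,
    saccade_dist: SaccadeSizeDistribution,
    extent: tuple[float, float],
    target_image: np.ndarray | None = None,
    mode: Mode = "free_viewing",
    seed: int | np.random.Generator | None = 0,
    selection: Literal["argmax", "sample"] = "argmax",
    start: tuple[float, float] | None = None,
    subject_id: str = "model",
    trial_id: str = "t0",
    record_stacks: bool = False,
) -> Scanpath | tuple[Scanpath, list[AttentionMapStack]]:
    """Generate one scanpath.

    The first fixation is at the image center (human trials started on a
    central cross) unless ``start`` is given.  At each step the saccade and
    memory maps are rebuilt (the similarity and saliency maps are static and
    normalized once), the weighted combination is formed, and the next
    fixation is the argmax — or, with ``selection="sample"``, drawn from the
    map treated as a probability mass (shifted to min 0; used by the
    stochastic ablations).  Search trials stop as soon as the fixated patch
    is recognized as the target or after ``max_fixations``; free-viewing
    trials run for exactly ``n_fixations_free`` fixations.
    """
    rng = np.random.default_rng(seed)
    if mode == "search":
        if target_image is None:
            raise ValueError("search mode requires a target image")
        if config.w_sim == 0:
            logger.debug("search trial with w_sim = 0 (ablated similarity)")
        n_budget = config.max_fixations
    elif mode == "free_viewing":
        if config.n_fixations_free is None:
            raise ValueError("free viewing requires n_fixations_free")
        n_budget = config.n_fixations_free
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    feat = np.asarray(backend.modulation_features(search_image), dtype=float)
    lattice = Lattice(shape=feat.shape[1:], extent=extent)

    m_sim = m_sal = None
    if config.w_sim != 0:
        m_sim = normalize_map(
            compute_similarity_map(backend, target_image, search_image))
    if config.w_sal != 0:
        m_sal = normalize_map(compute_saliency_map(backend, search_image))

    target_emb = None
    if mode == "search":
        target_emb = backend.embedding(target_image)

    w_dva, h_dva = extent
    current = start if start is not None else (w_dva / 2.0, h_dva / 2.0)
    # snap the start onto the lattice so all fixations share one geometry
    current = lattice.to_dva(*lattice.nearest_cell(*current))
    memory = MemoryState()
    fixations: list[tuple[float, float]] = [current]
    stacks: list[AttentionMapStack] = []

    for step in range(1, n_budget + 1):
        if mode == "search":
            found, _ = recognize_at_fixation(
                backend, search_image, current, target_image, extent,
                config.recognition_threshold, patch=config.recognition_patch,
                target_embedding=target_emb,
            )
            if found:
                logger.info("target recognized at fixation %d", step)
                break
        if step == n_budget:
            break
        memory.push(current)
        m_sac = saccade_prior_map(current, saccade_dist, lattice)
        m_mem = normalize_map(
            memory_map(memory, lattice, config.alpha, config.beta, config.sigma))
        stack = AttentionMapStack(
            m_sim=m_sim, m_sal=m_sal, m_sac=m_sac, m_mem=m_mem,
            m_f=np.empty(0), step=step,
        )
        m_f = integrate_maps(stack, config)
        stack.m_f = m_f
        if record_stacks:
            stacks.append(stack)
        logger.debug("step %d: M_f range [%.4f, %.4f]", step, m_f.min(), m_f.max())
        if selection == "argmax":
            r, c = select_next_fixation(m_f)
        else:
            p = m_f - m_f.min()
            total = p.sum()
            if total <= 0:
                p = np.ones_like(p)
                total = p.sum()
            flat = rng.choice(p.size, p=(p / total).ravel())
            r, c = np.unravel_index(flat, p.shape)
        current = lattice.to_dva(int(r), int(c))
        fixations.append(current)

    sp = Scanpath(
        fixations=tuple(
            Fixation(
                x=x, y=y,
                onset=i * MODEL_FIXATION_PERIOD_MS,
                duration=MODEL_FIXATION_DURATION_MS,
            )
            for i, (x, y) in enumerate(fixations)
        ),
        subject_id=subject_id,
        trial_id=trial_id,
        task=mode,
        extent=extent,
    )
    if record_stacks:
        return sp, stacks
    return sp
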