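"""Chance-level and ablated variants of the eye-movement model.

The null model is memoryless and image-blind: each next fixation is drawn
at a random direction with an amplitude sampled from the empirical saccade
size distribution, so it respects oculomotor constraints but nothing else.
Its return-fixation proportion is the chance level the full model is
compared against.

The ablations each remove one component of the full model: the target
similarity map (search), the saliency map (free viewing), the saccade-size
prior, or the memory map.  Removing similarity or saliency leaves an
image-agnostic map, so the winner-take-all is replaced by sampling from the
attention map to avoid producing the identical scanpath for every image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .model import (
    FeatureBackend,
    Mode,
    ModelConfig,
    SaccadeSizeDistribution,
    run_trial,
)
from .scanpath import Scanpath


@dataclass(frozen=True)
class NullModelConfig:
    """Parameters of the memoryless random-walk null model.

    ``length`` should equal the dataset's mean fixations per trial and
    ``n_sequences`` at least 25,000 so the chance proportion is stable.
    """

    saccade_dist: SaccadeSizeDistribution
    length: int
    n_sequences: int = 25_000
    seed: int = 0
    start: Literal["uniform", "center"] = "uniform"
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("sequence length must be >= 2")
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")


def run_null_model(
    config: NullModelConfig, extent: tuple[float, float]
) -> np.ndarray:
    """Simulate null scanpaths; returns positions of shape (n, length, 2).

    Each sequence starts uniformly within the extent (or at the center) and
    every subsequent fixation displaces the current one by a sampled
    amplitude at a uniformly random direction.  Off-extent draws are
    rejected and resampled so the radial amplitude law is preserved within
    bounds; if a position cannot be continued within ``max_retries`` draws
    the simulation aborts (the extent cannot accommodate the distribution).

    Returned as a bare coordinate array rather than ``Scanpath`` objects to
    keep 25k-sequence simulations cheap; ``null_scanpaths`` wraps them when
    object form is needed.
    """
    rng = np.random.default_rng(config.seed)
    w, h = extent
    n = config.n_sequences
    pos = np.empty((n, config.length, 2), dtype=float)
    if config.start == "uniform":
        pos[:, 0, 0] = rng.uniform(0, w, n)
        pos[:, 0, 1] = rng.uniform(0, h, n)
    else:
        pos[:, 0, 0] = w / 2.0
        pos[:, 0, 1] = h / 2.0
    for t in range(1, config.length):
        cur = pos[:, t - 1, :].copy()
        nxt = np.empty_like(cur)
        todo = np.arange(n)
        for attempt in range(config.max_retries):
            amp = config.saccade_dist.sample(rng, size=todo.size)
            ang = rng.uniform(0.0, 2.0 * np.pi, todo.size)
            cand = cur[todo] + np.stack(
                [amp * np.cos(ang), amp * np.sin(ang)], axis=1)
            ok = (
                (cand[:, 0] >= 0) & (cand[:, 0] <= w)
                & (cand[:, 1] >= 0) & (cand[:, 1] <= h)
            )
            nxt[todo[ok]] = cand[ok]
            todo = todo[~ok]
            if todo.size == 0:
                break
        else:
            raise RuntimeError(
                f"null model: {todo.size} sequences could not place fixation "
                f"{t + 1} within {config.max_retries} retries; the extent is "
                "too small for the saccade distribution"
            )
        pos[:, t, :] = nxt
    return pos


def null_scanpaths(
    config: NullModelConfig, extent: tuple[float, float]
) -> list[Scanpath]:
    """Null-model simulations wrapped as ``Scanpath`` objects."""
    from .scanpath import Fixation

    pos = run_null_model(config, extent)
    out = []
    for i in range(pos.shape[0]):
        out.append(
            Scanpath(
                fixations=tuple(
                    Fixation(x=float(x), y=float(y), onset=t * 250.0, duration=200.0)
                    for t, (x, y) in enumerate(pos[i])
                ),
                subject_id="null",
                trial_id=f"null{i}",
                task="null",
                extent=extent,
            )
        )
    return out


def chance_proportion(
    null_positions: np.ndarray, threshold: float = 1.0
) -> float:
    """Mean return-fixation proportion over null sequences.

    Accepts the (n, length, 2) array from :func:`run_null_model`.  A
    fixation is a return iff it lies within ``threshold`` of any earlier
    fixation in its sequence, exactly as in the empirical annotation.
    """
    pos = np.asarray(null_positions, dtype=float)
    n, length, _ = pos.shape
    d = np.linalg.norm(pos[:, :, None, :] - pos[:, None, :, :], axis=-1)
    earlier = np.tril(np.ones((length, length), dtype=bool), k=-1)
    is_return = (d <= threshold) & earlier[None, :, :]
    return float(is_return.any(axis=2).sum(axis=1).mean() / length)


AblationVariant = Literal[
    "ablate_similarity", "ablate_saliency", "ablate_saccade_prior", "ablate_memory"
]


@dataclass(frozen=True)
class AblationSpec:
    """One ablated model variant with its sampling mode and seed."""

    variant: AblationVariant
    seed: int = 0

    def __post_init__(self) -> None:
        allowed = ("ablate_similarity", "ablate_saliency",
                   "ablate_saccade_prior", "ablate_memory")
        if self.variant not in allowed:
            raise ValueError(f"unknown ablation variant: {self.variant!r}")

    @property
    def selection(self) -> Literal["argmax", "sample"]:
        # similarity/saliency ablations leave an image-agnostic map; the
        # stochastic winner-take-all keeps scanpaths image-dependent
        if self.variant in ("ablate_similarity", "ablate_saliency"):
            return "sample"
        return "argmax"


def run_ablated_trial(
    spec: AblationSpec,
    backend: FeatureBackend,
    config: ModelConfig,
    search_image: np.ndarray,
    saccade_dist: SaccadeSizeDistribution,
    extent: tuple[float, float],
    target_image: np.ndarray | None = None,
    mode: Mode = "free_viewing",
    **run_kwargs,
) -> Scanpath:
    """Run one trial of an ablated model variant.

    * ``ablate_similarity`` (search only): w_sim = 0, stochastic sampling.
    * ``ablate_saliency`` (free viewing only): w_sal = 0, stochastic sampling.
    * ``ablate_saccade_prior``: w_sac = 0, argmax winner-take-all.
    * ``ablate_memory``: w_mem drawn uniformly from [-1, 0] once per trial
      (a defective memory write), argmax winner-take-all.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.variant == "ablate_similarity":
        if mode != "search":
            raise ValueError("similarity ablation applies to search trials only")
        cfg = replace(config, w_sim=0.0)
    elif spec.variant == "ablate_saliency":
        if mode != "free_viewing":
            raise ValueError("saliency ablation applies to free-viewing trials only")
        cfg = replace(config, w_sal=0.0)
    elif spec.variant == "ablate_saccade_prior":
        cfg = replace(config, w_sac=0.0)
    elif spec.variant == "ablate_memory":
        cfg = replace(config, w_mem=float(rng.uniform(-1.0, 0.0)))
    else:
        raise ValueError(f"unknown ablation variant: {spec.variant!r}")
    return run_trial(
        backend, cfg, search_image, saccade_dist, extent,
        target_image=target_image, mode=mode, seed=rng,
        selection=spec.selection, **run_kwargs,
    )


def alternative_null_trial(
    backend: FeatureBackend,
    config: ModelConfig,
    search_image: np.ndarray,
    saccade_dist: SaccadeSizeDistribution,
    extent: tuple[float, float],
    target_image: np.ndarray | None = None,
    mode: Mode = "free_viewing",
    **run_kwargs,
) -> Scanpath:
    """Diagnostic memoryless variant: the full model with the memory map off.

    Without inhibition the static map dominates and the scanpath oscillates
    between the two strongest peaks (strong exploitation, no exploration);
    this variant is provided for inspection and is not used as the chance
    level.
    """
    cfg = replace(config, w_mem=0.0)
    return run_trial(
        backend, cfg, search_image, saccade_dist, extent,
        target_image=target_image, mode=mode, **run_kwargs,
    )
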