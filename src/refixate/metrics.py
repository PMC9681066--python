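"""Population-level statistics of return fixations.

Covers between-subject consistency (entropy of the return-location
distribution on a coarse grid, against a shuffled chance level), the spatial
divergence between return and non-return fixations, saliency sampling at
fixation patches, fixation-duration summaries by category, the
subject-vs-model similarity index, recognition error rates during visual
search, and a bootstrap for proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import sem as _sem

from .scanpath import Label, ReturnAnnotation, Scanpath

#: Probability floor replacing exact zeros before taking logs.
PROBABILITY_FLOOR = 1e-10


@dataclass(frozen=True)
class GridSpec:
    """Uniform 2D grid used to quantize fixation locations (rows x cols)."""

    rows: int = 32
    cols: int = 40

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cell_of(self, x: float, y: float, extent: tuple[float, float]) -> tuple[int, int]:
        """(row, col) of a dva location; border points clip into the grid."""
        w, h = extent
        col = min(int(x / w * self.cols), self.cols - 1)
        row = min(int(y / h * self.rows), self.rows - 1)
        return row, col


@dataclass(frozen=True)
class ConsistencyResult:
    """Observed consistency entropy with its chance distribution."""

    entropy: float
    chance_entropies: tuple[float, ...]
    n_return_fixations: int

    @property
    def below_chance(self) -> bool:
        """Lower entropy than every chance replicate (more consistent)."""
        return self.entropy < min(self.chance_entropies)


@dataclass(frozen=True)
class SaliencyMap:
    """A non-negative 2D map co-registered to the stimulus extent."""

    values: np.ndarray
    extent: tuple[float, float]
    source: str = "external"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("saliency map must be 2D")
        if not np.all(np.isfinite(v)):
            raise ValueError("saliency map must be finite")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# Between-subject consistency entropy
# ---------------------------------------------------------------------------

def _finalize_distribution(
    hist: np.ndarray,
    blur_sigma: float,
    floor: float,
    log_base: float | None,
) -> tuple[np.ndarray, float]:
    """Blur, floor, renormalize a non-negative table; return (p, entropy)."""
    p = np.asarray(hist, dtype=float)
    if blur_sigma > 0:
        p = ndimage.gaussian_filter(p, sigma=blur_sigma, truncate=4.0)
    if floor > 0:
        p = np.maximum(p, floor)
    total = p.sum()
    if total <= 0:
        raise ValueError("distribution has no mass")
    p = p / total
    pos = p[p > 0]
    logp = np.log(pos) if log_base is None else np.log(pos) / math.log(log_base)
    h = float(-(pos * logp).sum())
    return p, h


def consistency_entropy(
    return_locations: Mapping[str, Sequence[tuple[float, float]]],
    extent: tuple[float, float],
    grid: GridSpec = GridSpec(),
    blur_sigma: float = 1.0,
    floor: float = PROBABILITY_FLOOR,
    log_base: float | None = None,
    chance_reps: int = 100,
    rng: np.random.Generator | int | None = 0,
) -> ConsistencyResult:
    """Entropy of the across-subject return-fixation location distribution.

    ``return_locations`` maps subject id to that subject's return-fixation
    coordinates (dva) on one image.  Each grid cell receives the proportion
    of subjects with at least one return there; the table is Gaussian-blurred
    (``blur_sigma`` in cells, truncated at 4 sigma) to soften sparsity,
    floored at ``floor`` to avoid log singularities, renormalized to a
    distribution, and summarized as H = -sum p log p (natural log unless
    ``log_base`` is given).  Low entropy means subjects agree on where they
    return.

    The chance level redistributes the same total number of return fixations
    uniformly over the image, ``chance_reps`` times with the same blur/floor
    treatment.
    """
    locs = {s: list(v) for s, v in return_locations.items() if len(v) > 0}
    n_total = sum(len(v) for v in locs.values())
    if n_total == 0:
        raise ValueError("no returns to evaluate")
    n_subjects = len(locs)
    hist = np.zeros((grid.rows, grid.cols), dtype=float)
    for positions in locs.values():
        seen: set[tuple[int, int]] = set()
        for x, y in positions:
            seen.add(grid.cell_of(x, y, extent))
        for r, c in seen:
            hist[r, c] += 1.0 / n_subjects
    _, h = _finalize_distribution(hist, blur_sigma, floor, log_base)
    chance = entropy_chance(
        n_total, extent, grid,
        reps=chance_reps, blur_sigma=blur_sigma, floor=floor,
        log_base=log_base, rng=rng,
    )
    return ConsistencyResult(
        entropy=h, chance_entropies=tuple(chance), n_return_fixations=n_total
    )


def entropy_chance(
    n_returns: int,
    extent: tuple[float, float],
    grid: GridSpec = GridSpec(),
    reps: int = 100,
    blur_sigma: float = 1.0,
    floor: float = PROBABILITY_FLOOR,
    log_base: float | None = None,
    rng: np.random.Generator | int | None = 0,
) -> list[float]:
    """Entropies of ``reps`` uniform redistributions of ``n_returns`` points."""
    if n_returns < 1:
        raise ValueError("need at least one return fixation")
    gen = np.random.default_rng(rng)
    w, h = extent
    out = []
    for _ in range(reps):
        xs = gen.uniform(0, w, n_returns)
        ys = gen.uniform(0, h, n_returns)
        hist = np.zeros((grid.rows, grid.cols), dtype=float)
        for x, y in zip(xs, ys):
            r, c = grid.cell_of(x, y, extent)
            hist[r, c] += 1.0
        _, ent = _finalize_distribution(hist, blur_sigma, floor, log_base)
        out.append(ent)
    return out


# ---------------------------------------------------------------------------
# Spatial divergence of return vs non-return fixations
# ---------------------------------------------------------------------------

def spatial_kld(
    return_locs: Sequence[tuple[float, float]],
    nonreturn_locs: Sequence[tuple[float, float]],
    extent: tuple[float, float],
    cell_size: float = 1.0,
    eps: float = PROBABILITY_FLOOR,
) -> float:
    """KL divergence (nats) between return and non-return location histograms.

    Both sets are quantized on a grid of ``cell_size`` dva resolution
    (matching the eye-tracker resolution), smoothed with an additive
    ``eps`` per cell, normalized, and compared as KLD(return || nonreturn).
    Zero iff the smoothed histograms coincide.
    """
    if len(return_locs) == 0 or len(nonreturn_locs) == 0:
        raise ValueError("both location sets must be non-empty")
    w, h = extent
    cols = max(1, math.ceil(w / cell_size))
    rows = max(1, math.ceil(h / cell_size))
    grid = GridSpec(rows=rows, cols=cols)

    def histo(locs) -> np.ndarray:
        out = np.zeros((rows, cols), dtype=float)
        for x, y in locs:
            r, c = grid.cell_of(x, y, extent)
            out[r, c] += 1.0
        out += eps
        return out / out.sum()

    p = histo(return_locs)
    q = histo(nonreturn_locs)
    return float(np.sum(p * (np.log(p) - np.log(q))))


# ---------------------------------------------------------------------------
# Saliency at fixation patches
# ---------------------------------------------------------------------------

def saliency_at_fixation(
    saliency: SaliencyMap, x: float, y: float, patch: float = 1.0
) -> float | None:
    """Mean map value over a ``patch``-dva square centered at (x, y).

    The patch is clipped at the map borders; the mean runs over pixels whose
    centers fall inside the square (even pixel spans stay centered on the
    continuous fixation coordinate).  ``None`` when the patch misses the map
    entirely.
    """
    vals = saliency.values
    h_px, w_px = vals.shape
    w_dva, h_dva = saliency.extent
    sx, sy = w_px / w_dva, h_px / h_dva
    x0, x1 = (x - patch / 2) * sx, (x + patch / 2) * sx
    y0, y1 = (y - patch / 2) * sy, (y + patch / 2) * sy
    c0, c1 = max(0, math.ceil(x0 - 0.5)), min(w_px, math.floor(x1 - 0.5) + 1)
    r0, r1 = max(0, math.ceil(y0 - 0.5)), min(h_px, math.floor(y1 - 0.5) + 1)
    if c0 >= c1 or r0 >= r1:
        return None
    return float(vals[r0:r1, c0:c1].mean())


def saliency_by_category(
    saliency: SaliencyMap,
    scanpath: Scanpath,
    annotation: ReturnAnnotation,
    patch: float = 1.0,
) -> dict[Label, float]:
    """Mean patch saliency per fixation category; empty categories are NaN.

    Fixations whose patch falls fully outside the map are excluded with a
    warning.  For egocentric clips, project all clip fixations onto the last
    frame's map before calling (the clip-filtering step guarantees small
    head motion).
    """
    import logging

    acc: dict[Label, list[float]] = {"return": [], "to_be_revisited": [], "non_return": []}
    for f, label in zip(scanpath.fixations, annotation.labels):
        v = saliency_at_fixation(saliency, f.x, f.y, patch)
        if v is None:
            logging.getLogger("refixate").warning(
                "fixation at (%.2f, %.2f) outside saliency map; excluded", f.x, f.y
            )
            continue
        acc[label].append(v)
    return {k: (float(np.mean(v)) if v else float("nan")) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# Durations, similarity index, search-specific rates
# ---------------------------------------------------------------------------

def duration_by_category(
    pairs: Iterable[tuple[Scanpath, ReturnAnnotation]],
) -> dict[Label, dict[str, float]]:
    """Across-subject mean and SEM of fixation duration per category.

    Durations are first averaged within subject per category (subjects with
    no fixation in a category are omitted for that category), then averaged
    across subjects.  SEM is NaN with fewer than two contributing subjects.
    """
    per_subject: dict[str, dict[Label, list[float]]] = {}
    for sp, ann in pairs:
        subj = per_subject.setdefault(
            sp.subject_id, {"return": [], "to_be_revisited": [], "non_return": []}
        )
        for f, label in zip(sp.fixations, ann.labels):
            subj[label].append(f.duration)
    out: dict[Label, dict[str, float]] = {}
    for label in ("return", "to_be_revisited", "non_return"):
        means = [
            float(np.mean(v[label])) for v in per_subject.values() if v[label]
        ]
        out[label] = {
            "mean": float(np.mean(means)) if means else float("nan"),
            "sem": float(_sem(means)) if len(means) > 1 else float("nan"),
            "n_subjects": float(len(means)),
        }
    return out


def similarity_index(subject_value: float, model_value: float) -> float:
    """Similarity index SI = 1 - (S - M) / (S + M) for non-negative S, M.

    SI = 1 when model and subjects agree exactly; 0 when the model value is
    zero and the subject value positive; bounded in [0, 2].
    """
    s, m = float(subject_value), float(model_value)
    if s < 0 or m < 0:
        raise ValueError("similarity index requires non-negative values")
    if s + m == 0:
        raise ValueError("undefined SI: S + M = 0")
    return 1.0 - (s - m) / (s + m)


def target_split_proportions(
    pairs: Iterable[tuple[Scanpath, ReturnAnnotation]],
) -> tuple[float, float]:
    """Return-fixation proportion at target vs non-target locations.

    Per trial, the target proportion is on-target returns over on-target
    fixations (trial excluded when it has no on-target fixation), and
    likewise for non-target locations; trial values are averaged within
    subject, then across subjects.
    """
    per_subject: dict[str, dict[str, list[float]]] = {}
    any_flags = False
    for sp, ann in pairs:
        flags = [f.on_target for f in sp.fixations]
        if all(fl is None for fl in flags):
            continue
        any_flags = True
        rec = per_subject.setdefault(sp.subject_id, {"target": [], "nontarget": []})
        on = [lab for fl, lab in zip(flags, ann.labels) if fl]
        off = [lab for fl, lab in zip(flags, ann.labels) if fl is not None and not fl]
        if on:
            rec["target"].append(sum(l == "return" for l in on) / len(on))
        if off:
            rec["nontarget"].append(sum(l == "return" for l in off) / len(off))
    if not any_flags:
        raise ValueError("no on_target flags present")

    def across(key: str) -> float:
        subj_means = [
            float(np.mean(r[key])) for r in per_subject.values() if r[key]
        ]
        return float(np.mean(subj_means)) if subj_means else float("nan")

    return across("target"), across("nontarget")


@dataclass(frozen=True)
class SearchTrialOutcome:
    """Recognition bookkeeping for one visual-search trial.

    ``n_on_target_no_click``: fixations that landed on the target but were
    not followed by a click (missed recognitions).  ``had_false_click``:
    whether the subject (or model) clicked a non-target location.
    """

    n_fixations: int
    n_on_target_no_click: int = 0
    had_false_click: bool = False


def recognition_error_rates(
    trials: Sequence[SearchTrialOutcome],
) -> tuple[float, float]:
    """(false_negative_rate, false_positive_rate) over search trials.

    FN: total on-target fixations without clicks over total fixations.
    FP: trials containing a false click over total trials.
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    total_fix = sum(t.n_fixations for t in trials)
    if total_fix == 0:
        raise ValueError("no fixations in trials")
    fn = sum(t.n_on_target_no_click for t in trials) / total_fix
    fp = sum(t.had_false_click for t in trials) / len(trials)
    return float(fn), float(fp)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    mean: float
    ci_low: float
    ci_high: float
    p_vs_chance: float | None
    samples: np.ndarray = field(repr=False, default=None)


def bootstrap_proportion(
    values: Sequence[float],
    reps: int = 1000,
    rng: np.random.Generator | int | None = 0,
    chance: float | None = None,
    ci: float = 0.95,
) -> BootstrapResult:
    """Bootstrap (resampling trials with replacement) of a mean proportion.

    ``values`` are per-trial proportions or 0/1 indicators.  Returns the
    observed mean, a percentile confidence interval over ``reps`` resamples,
    and, when ``chance`` is supplied, a two-sided exceedance p-value for the
    bootstrap distribution against that chance level (floored at 1/reps).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    gen = np.random.default_rng(rng)
    idx = gen.integers(0, vals.size, size=(reps, vals.size))
    boots = vals[idx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    p = None
    if chance is not None:
        below = float(np.mean(boots <= chance))
        above = float(np.mean(boots >= chance))
        p = max(2.0 * min(below, above), 1.0 / reps)
        p = min(p, 1.0)
    return BootstrapResult(
        mean=float(vals.mean()), ci_low=float(lo), ci_high=float(hi),
        p_vs_chance=p, samples=boots,
    )
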