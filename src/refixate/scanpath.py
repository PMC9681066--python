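"""Fixation sequences, return-fixation annotation, and kinematic descriptors.

A scanpath is the ordered sequence of fixations one observer makes on one
stimulus.  A *return fixation* lands within a distance threshold (default
1 degree of visual angle, dva; 1.5 dva for egocentric video, where head
motion blurs the alignment) of any earlier fixation in the same trial.  The
earlier fixation it matches is a *to-be-revisited* fixation; everything else
is a *non-return* fixation.  The three labels are mutually exclusive: a
fixation that is both a return and later revisited keeps the label
``return``.

Coordinates are continuous dva with the origin at the image top-left corner,
x rightward and y downward.  :func:`from_screen_centered` converts data
recorded in screen-centered coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("refixate")

Label = Literal["return", "to_be_revisited", "non_return"]

#: Return-distance threshold (dva) for static-image experiments.
DEFAULT_RETURN_THRESHOLD = 1.0
#: Relaxed threshold (dva) for egocentric video.
EGOCENTRIC_RETURN_THRESHOLD = 1.5
#: Maximum run of consecutive missing gaze frames tolerated in a clip.
DEFAULT_MAX_GAZE_GAP = 14
#: Head-motion score above which an egocentric clip is discarded.
DEFAULT_MOTION_SCORE_LIMIT = 0.4


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixation:
    """One fixation: position in dva, onset and duration in ms."""

    x: float
    y: float
    onset: float = 0.0
    duration: float = 1.0
    on_target: bool | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("fixation coordinates must be finite")
        if not self.duration > 0:
            raise ValueError("fixation duration must be positive")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Scanpath:
    """Ordered fixations of one trial with stimulus geometry and identifiers.

    ``extent`` is the stimulus size ``(width, height)`` in dva.  All
    fixations must lie inside the extent; onsets must strictly increase.
    """

    fixations: tuple[Fixation, ...]
    subject_id: str = "s0"
    trial_id: str = "t0"
    task: str = "free_viewing"
    extent: tuple[float, float] = (25.0, 30.0)
    coordinate_origin: str = "top_left"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixations", tuple(self.fixations))
        if len(self.fixations) == 0:
            raise ValueError("empty sequence")
        w, h = self.extent
        onsets = [f.onset for f in self.fixations]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("fixation onsets must be strictly increasing")
        for i, f in enumerate(self.fixations):
            if not (0.0 <= f.x <= w and 0.0 <= f.y <= h):
                raise ValueError(
                    f"fixation {i + 1} at ({f.x:.3g}, {f.y:.3g}) lies outside "
                    f"the {w} x {h} dva extent"
                )

    def __len__(self) -> int:
        return len(self.fixations)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of fixation coordinates in dva."""
        return np.array([(f.x, f.y) for f in self.fixations], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations], dtype=float)


@dataclass(frozen=True)
class ReturnEvent:
    """A return fixation paired with the earlier fixation it revisits.

    Indices are 1-based, matching the numbering used on scanpath figures.
    ``offset`` counts intervening fixations: ``return_index - source_index - 1``.
    """

    return_index: int
    source_index: int
    offset: int
    distance: float

    def __post_init__(self) -> None:
        if self.source_index >= self.return_index:
            raise ValueError("source index must precede return index")
        if self.offset != self.return_index - self.source_index - 1:
            raise ValueError("offset inconsistent with indices")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


@dataclass(frozen=True)
class ReturnAnnotation:
    """Per-fixation labels plus the list of return events for one scanpath."""

    labels: tuple[Label, ...]
    events: tuple[ReturnEvent, ...]
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "events", tuple(self.events))
        n_ret = sum(1 for l in self.labels if l == "return")
        if n_ret != len(self.events):
            raise ValueError("one event required per return fixation")
        for ev in self.events:
            if ev.distance > self.threshold:
                raise ValueError("event distance exceeds threshold")

    @property
    def n_fixations(self) -> int:
        return len(self.labels)

    def indices(self, label: Label) -> list[int]:
        """1-based fixation indices carrying ``label``."""
        return [i + 1 for i, l in enumerate(self.labels) if l == label]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_returns(
    scanpath: Scanpath,
    threshold: float = DEFAULT_RETURN_THRESHOLD,
    pairing: Literal["recent", "nearest"] = "recent",
) -> ReturnAnnotation:
    """Label every fixation as return / to-be-revisited / non-return.

    Fixation *i* is a return iff its distance to some earlier fixation is at
    most ``threshold`` (dva).  Each return is paired with one earlier
    fixation: the most recent qualifying one by default, or the spatially
    nearest with ``pairing="nearest"``.  Matched earlier fixations that are
    not themselves returns are labeled ``to_be_revisited``.

    Consecutive refixations (offset 0) satisfy the distance rule and are
    counted as returns; upstream fixation extraction normally merges such
    pairs, so they are rare in practice but not silently dropped here.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    xy = scanpath.xy
    n = len(xy)
    # pairwise distances; row i vs all earlier rows
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)

    labels: list[Label] = ["non_return"] * n
    events: list[ReturnEvent] = []
    for i in range(1, n):
        earlier = d[i, :i]
        hits = np.nonzero(earlier <= threshold)[0]
        if hits.size == 0:
            continue
        if pairing == "recent":
            j = int(hits[-1])
        elif pairing == "nearest":
            j = int(hits[np.argmin(earlier[hits])])
        else:
            raise ValueError(f"unknown pairing rule: {pairing!r}")
        labels[i] = "return"
        events.append(
            ReturnEvent(
                return_index=i + 1,
                source_index=j + 1,
                offset=i - j - 1,
                distance=float(earlier[j]),
            )
        )
    # sources keep "return" if they are themselves returns
    for ev in events:
        if labels[ev.source_index - 1] == "non_return":
            labels[ev.source_index - 1] = "to_be_revisited"
    return ReturnAnnotation(labels=tuple(labels), events=tuple(events), threshold=threshold)


def return_offsets(annotation: ReturnAnnotation) -> list[int]:
    """Number of intervening fixations for each return event, in event order."""
    return [ev.offset for ev in annotation.events]


def proportion_return(annotation: ReturnAnnotation) -> float:
    """Fraction of all fixations that are return fixations."""
    return len(annotation.events) / annotation.n_fixations


def twice_revisited_proportion(annotation: ReturnAnnotation) -> float:
    """Fraction of fixations that return to an already-revisited location.

    A return counts when its source fixation (or, transitively, the location
    that source itself revisited) was already the source of an earlier return
    event — i.e. the location is being revisited for at least the second
    time.
    """
    seen_sources: set[int] = set()
    # map each return back to the root location of its revisit chain
    root = {ev.return_index: ev.source_index for ev in annotation.events}

    def root_of(idx: int) -> int:
        while idx in root:
            idx = root[idx]
        return idx

    n_multi = 0
    for ev in annotation.events:
        r = root_of(ev.source_index)
        if r in seen_sources:
            n_multi += 1
        seen_sources.add(r)
    return n_multi / annotation.n_fixations


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def turning_angles(scanpath: Scanpath) -> list[float]:
    """Turning angle (degrees, [0, 180]) at each interior fixation.

    For consecutive fixations A -> B -> C the angle is between the incoming
    saccade direction (A to B) and the outgoing direction (B to C): 0 means
    the gaze continues straight, 180 a full reversal.  A zero-length saccade
    leaves the angle undefined; NaN is emitted and counted in the log.
    """
    xy = scanpath.xy
    if len(xy) < 3:
        return []
    v = np.diff(xy, axis=0)
    angles: list[float] = []
    n_undefined = 0
    for a, b in zip(v[:-1], v[1:]):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            angles.append(float("nan"))
            n_undefined += 1
            continue
        cosang = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
        angles.append(math.degrees(math.acos(cosang)))
    if n_undefined:
        logger.info("turning_angles: %d undefined angles (zero-length saccades)", n_undefined)
    return angles


def turning_angles_by_category(
    scanpath: Scanpath, annotation: ReturnAnnotation
) -> tuple[list[float], list[float]]:
    """Split turning angles by whether the landing fixation C is a return.

    Returns ``(angles_before_returns, angles_before_non_returns)``; undefined
    (NaN) angles are excluded from both, matching histogram usage.
    """
    angles = turning_angles(scanpath)
    ret, non = [], []
    for i, ang in enumerate(angles):
        if math.isnan(ang):
            continue
        # angle i belongs to the triple (i, i+1, i+2); C is fixation i+2 (0-based)
        c_label = annotation.labels[i + 2]
        (ret if c_label == "return" else non).append(ang)
    return ret, non


def saccade_sizes(scanpath: Scanpath) -> list[float]:
    """Euclidean amplitude (dva) of each saccade, in order."""
    xy = scanpath.xy
    return [float(d) for d in np.linalg.norm(np.diff(xy, axis=0), axis=1)]


def saccade_sizes_by_category(
    scanpath: Scanpath, annotation: ReturnAnnotation
) -> dict[Label, list[float]]:
    """Group saccade amplitudes by the category of the landing fixation."""
    out: dict[Label, list[float]] = {"return": [], "to_be_revisited": [], "non_return": []}
    for size, label in zip(saccade_sizes(scanpath), annotation.labels[1:]):
        out[label].append(size)
    return out


def truncate_first_k(scanpath: Scanpath, k: int) -> Scanpath:
    """First ``min(k, n)`` fixations with all metadata preserved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return replace(scanpath, fixations=scanpath.fixations[: min(k, len(scanpath))])


def from_screen_centered(
    xy: np.ndarray, extent: tuple[float, float]
) -> np.ndarray:
    """Convert screen-centered coordinates (x right, y up) to top-left origin."""
    xy = np.asarray(xy, dtype=float)
    w, h = extent
    out = np.empty_like(xy)
    out[..., 0] = xy[..., 0] + w / 2.0
    out[..., 1] = h / 2.0 - xy[..., 1]
    return out


# ---------------------------------------------------------------------------
# Egocentric preprocessing
# ---------------------------------------------------------------------------

def egocentric_motion_score(first_frame: np.ndarray, last_frame: np.ndarray) -> float:
    """Head-motion proxy for a 5-s egocentric clip.

    Euclidean distance between the first and last frame at the pixel level,
    normalized by the number of pixels.  Frames must share a shape and be
    scaled to [0, 1] intensity.  Clips with a score above
    :data:`DEFAULT_MOTION_SCORE_LIMIT` are discarded from analyses.
    """
    a = np.asarray(first_frame, dtype=float)
    b = np.asarray(last_frame, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    n_pixels = int(np.prod(a.shape[:2])) if a.ndim >= 2 else a.size
    return float(np.sqrt(np.sum((a - b) ** 2)) / n_pixels)


@dataclass(frozen=True)
class GazeTrace:
    """Per-frame gaze samples of one clip; NaN rows mark missing frames."""

    xy: np.ndarray  # (n_frames, 2); NaN where missing

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(np.asarray(self.xy, dtype=float)).any(axis=1)


def filter_and_interpolate_gaze(
    trace: GazeTrace | np.ndarray, max_gap: int = DEFAULT_MAX_GAZE_GAP
) -> np.ndarray | None:
    """Accept and gap-fill a gaze trace, or reject it.

    A clip is rejected (``None``) when any run of consecutive missing frames
    exceeds ``max_gap`` (default 14 frames, about three fixations at 24 fps)
    or when every frame is missing.  Interior gaps are linearly interpolated;
    leading and trailing gaps are padded with the nearest valid sample.
    """
    xy = np.asarray(trace.xy if isinstance(trace, GazeTrace) else trace, dtype=float)
    missing = np.isnan(xy).any(axis=1)
    if missing.all():
        return None
    # longest missing run
    run = best = 0
    for m in missing:
        run = run + 1 if m else 0
        best = max(best, run)
    if best > max_gap:
        return None
    idx = np.arange(len(xy))
    valid = ~missing
    out = xy.copy()
    for c in range(xy.shape[1]):
        out[missing, c] = np.interp(idx[missing], idx[valid], xy[valid, c])
    return out


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "subject_id", "trial_id", "fix_index", "x_dva", "y_dva",
    "onset_ms", "duration_ms", "on_target",
]


def scanpaths_to_frame(scanpaths: Iterable[Scanpath]) -> pd.DataFrame:
    rows = []
    for sp in scanpaths:
        for i, f in enumerate(sp.fixations):
            rows.append(
                {
                    "subject_id": sp.subject_id,
                    "trial_id": sp.trial_id,
                    "fix_index": i + 1,
                    "x_dva": f.x,
                    "y_dva": f.y,
                    "onset_ms": f.onset,
                    "duration_ms": f.duration,
                    "on_target": "NA" if f.on_target is None else int(f.on_target),
                }
            )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_fixation_tsv(scanpaths: Iterable[Scanpath], path) -> None:
    """Write scanpaths to the standard UTF-8 fixation TSV."""
    scanpaths_to_frame(scanpaths).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_fixation_tsv(
    path,
    extent: tuple[float, float],
    task: str = "free_viewing",
) -> list[Scanpath]:
    """Read the standard fixation TSV into per-(subject, trial) scanpaths.

    Validates strictly increasing onsets within every trial; a malformed row
    raises with its position.
    """
    df = pd.read_csv(path, sep="\t", encoding="utf-8", na_values=["NA"])
    missing_cols = [c for c in _TSV_COLUMNS[:-1] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"fixation table missing columns: {missing_cols}")
    if len(df) == 0:
        raise ValueError("empty fixation table")
    scanpaths: list[Scanpath] = []
    for (subj, trial), g in df.groupby(["subject_id", "trial_id"], sort=True):
        g = g.sort_values("fix_index")
        fixations = []
        for row_pos, row in enumerate(g.itertuples(index=False)):
            try:
                on_target = None if pd.isna(row.on_target) else bool(int(row.on_target))
                fixations.append(
                    Fixation(
                        x=float(row.x_dva),
                        y=float(row.y_dva),
                        onset=float(row.onset_ms),
                        duration=float(row.duration_ms),
                        on_target=on_target,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"malformed row {row_pos + 1} of trial {subj}/{trial}: {exc}"
                ) from exc
        scanpaths.append(
            Scanpath(
                fixations=tuple(fixations),
                subject_id=str(subj),
                trial_id=str(trial),
                task=task,
                extent=extent,
            )
        )
    return scanpaths


def annotation_to_frame(scanpath: Scanpath, annotation: ReturnAnnotation) -> pd.DataFrame:
    """Annotation export: one row per fixation with label and event columns."""
    by_return = {ev.return_index: ev for ev in annotation.events}
    rows = []
    for i in range(annotation.n_fixations):
        ev = by_return.get(i + 1)
        rows.append(
            {
                "subject_id": scanpath.subject_id,
                "trial_id": scanpath.trial_id,
                "fix_index": i + 1,
                "label": annotation.labels[i],
                "source_index": ev.source_index if ev else "NA",
                "offset": ev.offset if ev else "NA",
                "distance_dva": round(ev.distance, 6) if ev else "NA",
            }
        )
    return pd.DataFrame(rows)
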