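"""Overlapping data slices and the duration <-> rows <-> frequency calculus.

A *data slice* is an 8 x n contiguous window of samples; its time span
T = n * sampling_interval bounds from below the period of any wave whose
full cycle it contains, so the lowest frequency a slice can resolve is
f = 1/T.  Slices are also the augmentation unit: consecutive windows
overlap by a configurable ratio, advancing by stride = n * (1 - ratio).

Train/test splitting is done at the *subject* level: windows that overlap
by 90% are nearly duplicates, so any split that lets one subject straddle
both sides leaks test data into training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .synth import Recording

logger = logging.getLogger(__name__)

#: slice lengths (seconds) studied in the window-length sweep
STANDARD_SLICE_SECONDS = (0.1, 0.5, 1.0, 1.6, 5.0)
#: overlap ratios studied in the sweep; 0.9 is the reporting default
STANDARD_OVERLAPS = (0.75, 0.9, 0.95)
DEFAULT_OVERLAP = 0.9

#: acceptable positive:negative ratio band after class balancing
BALANCE_BAND = (1 / 1.5, 1.5)


@dataclass
class DataSlice:
    """An 8 x n window cut from one recording, with provenance."""

    subject_id: str
    label: int
    data: np.ndarray  # (8, n_rows)
    origin_row: int   # 0-based index of the first row in the source recording
    sampling_interval: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ValueError(f"slice data must be channels x n with n >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"slice from {self.subject_id} at row {self.origin_row} has non-finite data")

    @property
    def n_rows(self) -> int:
        return self.data.shape[1]

    @property
    def time_span(self) -> float:
        return self.n_rows * self.sampling_interval


def rows_for_duration(time_span: float, sampling_interval: float) -> int:
    """Number of sample rows spanning ``time_span`` seconds.

    (1 s, 4 ms) -> 250 rows; (5 s, 4 ms) -> 1250 rows.  A span that is not
    an integer multiple of the interval is rounded down (logged).
    """
    if time_span <= 0 or sampling_interval <= 0:
        raise ValueError(f"time_span and sampling_interval must be > 0, got ({time_span}, {sampling_interval})")
    exact = time_span / sampling_interval
    rows = int(math.floor(exact + 1e-9))
    if abs(exact - rows) > 1e-9:
        logger.info("time span %.6gs is not a multiple of %.6gs; using %d rows", time_span, sampling_interval, rows)
    if rows < 1:
        raise ValueError(f"time_span {time_span}s is shorter than one sample ({sampling_interval}s)")
    return rows


def min_detectable_frequency(time_span: float) -> float:
    """Lowest frequency whose full cycle fits in a slice of ``time_span`` s: 1/T.

    A 0.1 s slice resolves only >= 10 Hz; a 5 s slice reaches down to 0.2 Hz.
    """
    if time_span <= 0:
        raise ValueError(f"time_span must be > 0, got {time_span}")
    return 1.0 / time_span


def stride_for_overlap(n_rows: int, overlap_ratio: float) -> int:
    """Start-row advance between consecutive slices.

    stride = round(n * (1 - overlap)), rounded half away from zero and
    floored at 1; consecutive slices then share n - stride rows.
    """
    if n_rows < 1:
        raise ValueError(f"n_rows must be >= 1, got {n_rows}")
    if not (0 <= overlap_ratio < 1):
        raise ValueError(f"overlap_ratio must be in [0, 1), got {overlap_ratio}")
    # half-away-from-zero rounding; epsilon guards binary artefacts like
    # 25 * (1 - 0.9) -> 2.4999999999999996
    return max(1, int(math.floor(n_rows * (1 - overlap_ratio) + 0.5 + 1e-9)))


def make_slices(rec: Recording, n_rows: int, overlap_ratio: float) -> list[DataSlice]:
    """Cut a recording into overlapping 8 x n_rows slices.

    Windows are half-open [origin, origin + n) starting at 0, s, 2s, ...
    while a full window fits; count = floor((N - n) / s) + 1.
    """
    n_samples = rec.n_samples
    if n_rows > n_samples:
        raise ValueError(
            f"slice length {n_rows} rows exceeds recording {rec.subject_id} "
            f"({n_samples} samples)"
        )
    stride = stride_for_overlap(n_rows, overlap_ratio)
    starts = range(0, n_samples - n_rows + 1, stride)
    return [
        DataSlice(rec.subject_id, rec.label, rec.data[:, s:s + n_rows], s, rec.sampling_interval)
        for s in starts
    ]


@dataclass
class SplitAssignment:
    """A subject-grouped train/test partition of a slice collection."""

    train_subjects: frozenset[str]
    test_subjects: frozenset[str]
    train_slices: list[DataSlice]
    test_slices: list[DataSlice]
    seed: int

    def __post_init__(self) -> None:
        if self.train_subjects & self.test_subjects:
            raise ValueError(f"subjects straddle the split: {sorted(self.train_subjects & self.test_subjects)}")
        for side, slices, subjects in (
            ("train", self.train_slices, self.train_subjects),
            ("test", self.test_slices, self.test_subjects),
        ):
            stray = {s.subject_id for s in slices} - subjects
            if stray:
                raise ValueError(f"{side} slices from subjects outside the {side} set: {sorted(stray)}")


def split_by_subject(slices: list[DataSlice], test_fraction: float, seed: int) -> SplitAssignment:
    """Randomly assign whole subjects to train/test sides.

    The test side receives round(test_fraction * n_subjects) subjects, with
    both classes represented on both sides; all of a subject's slices travel
    with the subject.  Deterministic given ``seed``.
    """
    if not (0 < test_fraction < 1):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    by_label: dict[int, list[str]] = {0: [], 1: []}
    seen: dict[str, int] = {}
    for s in slices:
        if s.subject_id not in seen:
            seen[s.subject_id] = s.label
            by_label[s.label].append(s.subject_id)
        elif seen[s.subject_id] != s.label:
            raise ValueError(f"subject {s.subject_id} carries inconsistent labels")
    n_subjects = len(seen)
    if n_subjects < 2:
        raise ValueError(f"need >= 2 subjects to split, got {n_subjects}")
    if not by_label[0] or not by_label[1]:
        raise ValueError("both classes must be present among subjects")
    for label in (0, 1):
        if len(by_label[label]) < 2:
            raise ValueError(
                f"class {label} has a single subject ({by_label[label][0]}); it cannot "
                "appear on both sides of a grouped split — add subjects or drop the class"
            )

    n_test = int(round(test_fraction * n_subjects))
    n_test = min(max(n_test, 2), n_subjects - 2)  # room for both classes on both sides

    # proportional per-class allocation by largest remainder, then clamp so
    # each class keeps >= 1 subject on each side
    rng = np.random.default_rng(seed)
    quota = {lab: test_fraction * len(subs) for lab, subs in by_label.items()}
    take = {lab: int(math.floor(q)) for lab, q in quota.items()}
    remainders = sorted(quota, key=lambda lab: quota[lab] - take[lab], reverse=True)
    for lab in remainders:
        if sum(take.values()) >= n_test:
            break
        take[lab] += 1
    for lab in (0, 1):
        take[lab] = min(max(take[lab], 1), len(by_label[lab]) - 1)

    test_subjects: set[str] = set()
    for lab, subs in by_label.items():
        order = sorted(subs)
        rng.shuffle(order)
        test_subjects.update(order[: take[lab]])
    train_subjects = frozenset(seen) - test_subjects

    assignment = SplitAssignment(
        train_subjects=frozenset(train_subjects),
        test_subjects=frozenset(test_subjects),
        train_slices=[s for s in slices if s.subject_id in train_subjects],
        test_slices=[s for s in slices if s.subject_id in test_subjects],
        seed=seed,
    )
    logger.info(
        "split seed=%d: %d train / %d test subjects (%d / %d slices)",
        seed, len(assignment.train_subjects), len(assignment.test_subjects),
        len(assignment.train_slices), len(assignment.test_slices),
    )
    return assignment


def balance_classes(slices: list[DataSlice], seed: int) -> list[DataSlice]:
    """Down-sample the majority class so positives:negatives is ~1.

    The majority class is sampled without replacement down to the minority
    count; no slice is duplicated.  Order of survivors follows the input.
    """
    pos = [i for i, s in enumerate(slices) if s.label == 1]
    neg = [i for i, s in enumerate(slices) if s.label == 0]
    if not pos or not neg:
        raise ValueError("class balancing requires both classes to be present")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        keep_major = rng.choice(pos, size=len(neg), replace=False)
        kept = set(keep_major) | set(neg)
    elif len(neg) > len(pos):
        keep_major = rng.choice(neg, size=len(pos), replace=False)
        kept = set(keep_major) | set(pos)
    else:
        return list(slices)
    return [s for i, s in enumerate(slices) if i in kept]


def class_ratio(slices: list[DataSlice]) -> float:
    """Positive:negative slice count ratio (inf if no negatives)."""
    n_pos = sum(1 for s in slices if s.label == 1)
    n_neg = len(slices) - n_pos
    return math.inf if n_neg == 0 else n_pos / n_neg


def subsample_slices(slices: list[DataSlice], max_per_recording: int | None, seed: int) -> list[DataSlice]:
    """Cap the number of slices kept per recording (desk-scale control).

    Short windows at high overlap produce thousands of nearly redundant
    slices per recording; a uniform random cap keeps experiment sizes
    comparable across window lengths.  ``None`` keeps everything.
    """
    if max_per_recording is None:
        return list(slices)
    if max_per_recording < 1:
        raise ValueError(f"max_per_recording must be >= 1, got {max_per_recording}")
    rng = np.random.default_rng(seed)
    by_subject: dict[str, list[int]] = {}
    for i, s in enumerate(slices):
        by_subject.setdefault(s.subject_id, []).append(i)
    kept: set[int] = set()
    for subject in sorted(by_subject):
        idx = by_subject[subject]
        if len(idx) <= max_per_recording:
            kept.update(idx)
        else:
            kept.update(rng.choice(idx, size=max_per_recording, replace=False))
    return [s for i, s in enumerate(slices) if i in kept]


def slice_manifest(assignment: SplitAssignment):
    """Audit table: one row per slice with its split side. Returns a DataFrame."""
    import pandas as pd

    rows = []
    for side, slices in (("train", assignment.train_slices), ("test", assignment.test_slices)):
        for s in slices:
            rows.append({
                "subject_id": s.subject_id, "label": s.label,
                "origin_row": s.origin_row, "n_rows": s.n_rows, "split": side,
            })
    return pd.DataFrame(rows)
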