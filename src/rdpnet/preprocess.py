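"""Segmentation and Gaussian-perturbation augmentation.

Each recording is cut into consecutive non-overlapping windows (512
samples by default, so a 4097-sample Bonn record yields 8 windows with
the trailing sample dropped).  Training data are augmented by adding
scaled Gaussian noise, ``x = S + alpha * sigma * n``, where ``sigma`` is
the (population) standard deviation of the segment itself, ``n`` is
i.i.d. standard normal, and ``alpha`` defaults to 0.01.  Two augmented
copies per original are generated by default, tripling the training set;
test data are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_bonn import EEGRecord, TaskSpec

DEFAULT_WINDOW = 512


class SegmentationError(ValueError):
    """Record too short to produce a single window."""


class LeakageError(ValueError):
    """Train and test id sets overlap."""


@dataclass
class LabeledSegment:
    """A fixed-length window cut from one record.

    ``values`` has shape (n_channels, window); coordinates are 0-based
    half-open, segment i covering samples [i*window, (i+1)*window).
    """

    values: np.ndarray
    label: int
    origin_id: str
    segment_index: int
    is_augmented: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] < 1:
            raise ValueError("segment window must be positive")


@dataclass(frozen=True)
class AugmentConfig:
    """Noise-perturbation settings.

    ``alpha`` scales the noise relative to each segment's standard
    deviation; ``copies_per_original`` augmented copies are added per
    original training segment (2 reproduces the published tripling).
    """

    alpha: float = 0.01
    copies_per_original: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.copies_per_original < 0:
            raise ValueError("copies_per_original must be non-negative")


def segment_record(record: EEGRecord, window: int = DEFAULT_WINDOW,
                   label: int = 0) -> list[LabeledSegment]:
    """Cut a record into floor(L/window) non-overlapping segments.

    Remainder samples beyond the last full window are dropped (a
    4097-sample record yields 8 windows of 512 plus 1 dropped sample).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = record.n_samples
    n_seg = L // window
    if n_seg == 0:
        raise SegmentationError(
            f"record {record.record_id!r} has {L} samples, shorter than "
            f"window {window}")
    return [
        LabeledSegment(
            values=record.samples[:, i * window:(i + 1) * window].copy(),
            label=label, origin_id=record.record_id, segment_index=i)
        for i in range(n_seg)
    ]


def augment_gaussian(segment: LabeledSegment, cfg: AugmentConfig,
                     rng: np.random.Generator | None = None,
                     ) -> list[LabeledSegment]:
    """Gaussian-perturbed copies of one segment.

    Each copy is ``S + alpha * sigma * n`` with ``sigma`` the population
    standard deviation of the segment (a constant segment yields exact
    copies).  Reproducible via ``cfg.seed`` when no generator is given.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigma = float(segment.values.std())  # population (N) denominator
    copies = []
    for _ in range(cfg.copies_per_original):
        noise = rng.standard_normal(segment.values.shape)
        copies.append(LabeledSegment(
            values=segment.values + cfg.alpha * sigma * noise,
            label=segment.label, origin_id=segment.origin_id,
            segment_index=segment.segment_index, is_augmented=True))
    return copies


def augment_segments(segments: list[LabeledSegment], cfg: AugmentConfig,
                     ) -> list[LabeledSegment]:
    """Originals plus ``copies_per_original`` augmented copies of each,
    drawn from a single generator seeded with ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    out = list(segments)
    for seg in segments:
        out.extend(augment_gaussian(seg, cfg, rng=rng))
    return out


def build_fold_data(records: list[EEGRecord], task: TaskSpec,
                    train_ids: set[str] | list[str],
                    test_ids: set[str] | list[str],
                    window: int = DEFAULT_WINDOW,
                    cfg: AugmentConfig | None = None,
                    ) -> tuple[list[LabeledSegment], list[LabeledSegment]]:
    """Segment and label one cross-validation fold at the record level.

    Training segments receive augmented copies; the test side contains
    only original segments.  Records whose set is not part of the task
    are ignored.
    """
    train_ids, test_ids = set(train_ids), set(test_ids)
    overlap = train_ids & test_ids
    if overlap:
        raise LeakageError(
            f"train/test id sets overlap: {sorted(overlap)[:5]}")
    cfg = cfg or AugmentConfig()
    train, test = [], []
    for record in records:
        if record.set_label not in task.class_map:
            continue
        label = task.class_map[record.set_label]
        if record.record_id in train_ids:
            train.extend(segment_record(record, window, label=label))
        elif record.record_id in test_ids:
            test.extend(segment_record(record, window, label=label))
    train = augment_segments(train, cfg)
    assert not any(s.is_augmented for s in test)
    return train, test


def segments_to_arrays(segments: list[LabeledSegment],
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Stack segments into (N, n_channels, window) values and (N,) labels."""
    x = np.stack([s.values for s in segments]).astype(np.float32)
    y = np.array([s.label for s in segments], dtype=np.int64)
    return x, y
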