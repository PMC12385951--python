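"""Synthetic single-channel EEG-like records with controllable class
separability.

Each class mixes three components:

* an AR(2) baseline with a 1/f-like spectrum shared by all classes,
* a class-specific band-limited oscillation (distinct center frequency
  per class within 1-40 Hz) whose amplitude also differs per class, and
* for the last ("ictal-like") class, high-amplitude spike-wave bursts at
  random onsets, emulating the large rhythmic discharges of seizure EEG.

In ``easy`` mode the class band-power means are separated by several
within-class standard deviations (small amplitude jitter), so a linear
classifier on band-power features alone is nearly perfect; ``hard`` mode
uses heavy amplitude jitter so the classes overlap at roughly one
standard deviation.  The generator exists to make the whole pipeline
testable without downloading clinical data; it makes no claim of
physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_bonn import BONN_SETS, EEGRecord, write_bonn_record

#: class center frequencies (Hz), spread across the physiological band
CENTER_FREQS = (3.0, 8.0, 14.0, 22.0, 32.0)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults mirror the Bonn corpus geometry
    (5 classes x 100 records x 4097 samples at 173.61 Hz)."""

    n_classes: int = 5
    records_per_class: int = 100
    length: int = 4097
    fs: float = 173.61
    difficulty: str = "easy"
    seed: int = 0
    ar_coeffs: tuple[float, float] = (1.5, -0.56)
    burst_amplitude: float = 5.0  # multiples of the baseline std

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.length < 512:
            raise ValueError("length must be >= 512")
        if self.records_per_class < 1:
            raise ValueError("records_per_class must be >= 1")
        if self.difficulty not in ("easy", "hard"):
            raise ValueError("difficulty must be 'easy' or 'hard'")


def class_labels(n_classes: int) -> list[str]:
    """Set labels for synthetic classes: Bonn letters when they fit."""
    if n_classes <= len(BONN_SETS):
        return list(BONN_SETS[:n_classes])
    return [f"C{i}" for i in range(n_classes)]


def _ar2_baseline(rng: np.random.Generator, length: int,
                  coeffs: tuple[float, float]) -> np.ndarray:
    from scipy.signal import lfilter
    a1, a2 = coeffs
    burn = 200
    w = rng.standard_normal(length + burn)
    x = lfilter([1.0], [1.0, -a1, -a2], w)
    return x[burn:]


def _one_record(rng: np.random.Generator, cfg: SynthConfig, cls: int,
                ) -> np.ndarray:
    baseline = _ar2_baseline(rng, cfg.length, cfg.ar_coeffs)
    base_std = baseline.std()
    freq = CENTER_FREQS[cls % len(CENTER_FREQS)] * (1 + 0.4 * (cls // len(CENTER_FREQS)))
    # class-dependent oscillation amplitude; jitter sets separability
    jitter = 0.05 if cfg.difficulty == "easy" else 0.60
    amp = base_std * (1.0 + 1.2 * cls) * (1.0 + jitter * rng.standard_normal())
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(cfg.length) / cfg.fs
    signal = baseline + amp * np.sin(2 * np.pi * freq * t + phase)
    if cls == cfg.n_classes - 1:  # ictal-like class: spike-wave bursts
        n_bursts = rng.integers(3, 7)
        burst_len = int(0.5 * cfg.fs)
        spike_freq = 5.0
        for _ in range(n_bursts):
            onset = rng.integers(0, cfg.length - burst_len)
            tb = np.arange(burst_len) / cfg.fs
            burst = np.abs(np.sin(2 * np.pi * spike_freq * tb)) ** 0.3 \
                * np.sin(2 * np.pi * spike_freq * tb)
            window = np.hanning(burst_len)
            signal[onset:onset + burst_len] += \
                cfg.burst_amplitude * base_std * burst * window
    return signal


def generate_dataset(cfg: SynthConfig) -> list[EEGRecord]:
    """All records of all classes, fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    labels = class_labels(cfg.n_classes)
    records = []
    for cls, label in enumerate(labels):
        for idx in range(cfg.records_per_class):
            samples = _one_record(rng, cfg, cls)
            records.append(EEGRecord(
                samples=samples, fs=cfg.fs, set_label=label,
                record_id=f"{label}/synth{idx:03d}.txt"))
    return records


def write_bonn_dirs(records: list[EEGRecord], root: str | Path,
                    quantize: bool = True) -> Path:
    """Write records as a Bonn-layout ASCII tree (one folder per class).

    ``quantize`` rounds samples to integers, matching the integer ASCII
    convention of the real corpus (scaled so rounding noise is
    negligible relative to signal amplitude).
    """
    root = Path(root)
    for record in records:
        set_dir = root / record.set_label
        set_dir.mkdir(parents=True, exist_ok=True)
        samples = record.samples
        if quantize:
            scaled = np.round(samples * 100.0)
            record = EEGRecord(samples=scaled, fs=record.fs,
                               set_label=record.set_label,
                               record_id=record.record_id)
        name = Path(record.record_id).name
        write_bonn_record(record, set_dir / name)
    return root


def band_power_features(records: list[EEGRecord],
                        bands: tuple[tuple[float, float], ...] = (
                            (1, 6), (6, 11), (11, 18), (18, 27), (27, 40)),
                        ) -> np.ndarray:
    """Closed-form per-record features: log band powers plus log variance.

    Serves as an independent separability oracle — in easy mode a linear
    model on these features alone should classify nearly perfectly.
    """
    from scipy.signal import periodogram
    feats = []
    for r in records:
        f, pxx = periodogram(r.samples[0], fs=r.fs)
        row = [np.log(pxx[(f >= lo) & (f < hi)].sum() + 1e-12)
               for lo, hi in bands]
        row.append(np.log(r.samples[0].var() + 1e-12))
        feats.append(row)
    return np.asarray(feats)
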