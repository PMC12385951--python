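"""Reading Bonn-format EEG records and task-string parsing.

The Bonn epilepsy corpus consists of five sets (A-E) of 100 plain-text
single-channel recordings, one integer sample per line, 4097 samples at
173.61 Hz.  Sets A/B are surface EEG from healthy volunteers (eyes open/
closed), C/D interictal intracranial EEG (contralateral / epileptogenic
zone), and E ictal activity.  Both directory naming conventions in
circulation — letters A-E and the original folder names Z, O, N, F, S —
are accepted.

Classification tasks are written as hyphen-separated letter groups,
e.g. ``"A-E"`` (healthy vs ictal), ``"AB-CD-E"`` (healthy vs interictal
vs ictal) or ``"A-B-C-D-E"``; each group becomes one class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BONN_FS = 173.61
BONN_SETS = ("A", "B", "C", "D", "E")

#: original Bonn folder names for each set letter
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "A": ("A", "Z"), "B": ("B", "O"), "C": ("C", "N"),
    "D": ("D", "F"), "E": ("E", "S"),
}


class BonnFormatError(ValueError):
    """A record file violates the one-numeric-token-per-line format."""


class TaskParseError(ValueError):
    """A task string is malformed."""


@dataclass
class EEGRecord:
    """One labeled recording.

    ``samples`` holds the signal in µV (documented, not enforced) as a
    float array of shape (n_channels, length); single-channel data may
    be passed 1-D and is promoted.
    """

    samples: np.ndarray
    fs: float
    set_label: str
    record_id: str
    n_channels: int = 1

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.size == 0:
            raise ValueError("record has no samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.n_channels = self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class TaskSpec:
    """A classification task: mapping from set labels to class indices."""

    name: str
    class_map: dict[str, int]
    n_classes: int

    @property
    def sets(self) -> tuple[str, ...]:
        return tuple(self.class_map)


def parse_task(name: str) -> TaskSpec:
    """Translate a task string like ``"AB-CD-E"`` into a label map.

    Group i maps all of its letters to class index i; every letter may
    appear at most once across the whole string.
    """
    groups = name.split("-")
    if not groups or any(not g for g in groups):
        raise TaskParseError(f"malformed task string {name!r}")
    class_map: dict[str, int] = {}
    for i, group in enumerate(groups):
        for letter in group:
            if letter not in BONN_SETS:
                raise TaskParseError(
                    f"unknown set letter {letter!r} in task {name!r}")
            if letter in class_map:
                raise TaskParseError(
                    f"set letter {letter!r} repeated in task {name!r}")
            class_map[letter] = i
    return TaskSpec(name=name, class_map=class_map, n_classes=len(groups))


def read_bonn_record(path: str | Path, fs: float = BONN_FS,
                     set_label: str = "", record_id: str = "") -> EEGRecord:
    """Parse one plain-text record (one numeric token per line)."""
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise BonnFormatError(
                    f"{path}: non-numeric value {token!r} on line {lineno}") \
                    from None
    if not values:
        raise BonnFormatError(f"{path}: empty record file")
    rid = record_id or path.stem
    return EEGRecord(samples=np.asarray(values), fs=fs,
                     set_label=set_label, record_id=rid)


def write_bonn_record(record: EEGRecord, path: str | Path) -> None:
    """Write a single-channel record, one sample per line.

    Integer-valued samples are written as integers so that an integer
    file round-trips bit-for-bit through read -> write -> read.
    """
    if record.n_channels != 1:
        raise ValueError("Bonn format holds single-channel records")
    with open(path, "w") as fh:
        for v in record.samples[0]:
            fh.write(f"{int(v)}\n" if float(v).is_integer() else f"{v!r}\n")


def load_bonn_sets(root: str | Path, sets: list[str] | tuple[str, ...],
                   fs: float = BONN_FS,
                   aliases: dict[str, tuple[str, ...]] | None = None,
                   ) -> list[EEGRecord]:
    """Load all records of the requested sets from a Bonn-layout tree.

    Each set lives in a subdirectory named by its letter (or one of its
    aliases); files are read in lexicographic order so record ids are
    deterministic (``<set>/<filename>``).
    """
    root = Path(root)
    aliases = aliases or DEFAULT_ALIASES
    records: list[EEGRecord] = []
    for set_label in sets:
        names = aliases.get(set_label, (set_label,))
        set_dir = next((root / n for n in names if (root / n).is_dir()), None)
        if set_dir is None:
            raise FileNotFoundError(
                f"no directory for set {set_label!r} under {root} "
                f"(tried {', '.join(names)})")
        files = sorted(p for p in set_dir.iterdir() if p.is_file())
        if not files:
            raise FileNotFoundError(f"set directory {set_dir} is empty")
        for p in files:
            records.append(read_bonn_record(
                p, fs=fs, set_label=set_label,
                record_id=f"{set_label}/{p.name}"))
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in dataset")
    return records


def dataset_manifest(records: list[EEGRecord]) -> pd.DataFrame:
    """Summary table (record_id, set, n_samples, fs), one row per record."""
    return pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "set": [r.set_label for r in records],
        "n_samples": [r.n_samples for r in records],
        "fs": [r.fs for r in records],
    })


#: the thirteen published Bonn task strings
BONN_TASKS = (
    "A-E", "B-E", "C-E", "D-E", "AB-E", "CD-E", "ABCD-E",
    "A-C-E", "A-D-E", "B-C-E", "B-D-E", "AB-CD-E",
    "A-B-C-D-E",
)
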