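import numpy as np
import pytest

from rdpnet import (AugmentConfig, EEGRecord, LabeledSegment, ModelConfig,
                    SynthConfig, TrainConfig, generate_dataset, parse_task,
                    run_cv)

#: width-reduced variant of the complete architecture used for the
#: multi-seed end-to-end smoke (identical wiring, 16/32 channels)
SMOKE_WIDTH = dict(rcm_channels=(16, 32), dcpm_channels=32)


@pytest.fixture(scope="session")
def easy_dataset():
    """The easy five-class dataset at full Bonn geometry
    (500 records x 4097 samples)."""
    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def smoke_cv_runs(easy_dataset):
    """3-fold CV on the easy 500-record five-class dataset, for three
    seeds: the complete (width-reduced) model and its w/o-pyramid
    ablation on identical splits.  Shared by the end-to-end smoke
    checks; this is the expensive fixture of the suite."""
    records = easy_dataset
    task = parse_task("A-B-C-D-E")
    runs = {}
    for seed in (1, 2, 3):
        tc = TrainConfig(max_epochs=8, seed=seed)
        aug = AugmentConfig(copies_per_original=0, seed=seed)
        full = run_cv(records, task, ModelConfig(**SMOKE_WIDTH), tc,
                      k=3, seed=seed, augment=aug)
        ablated = run_cv(records, task,
                         ModelConfig(use_dcpm=False, **SMOKE_WIDTH), tc,
                         k=3, seed=seed, augment=aug)
        runs[seed] = (full, ablated)
    return runs


@pytest.fixture(scope="session")
def tiny_dataset():
    """30 easy synthetic records (3 classes x 10), Bonn geometry."""
    cfg = SynthConfig(n_classes=3, records_per_class=10, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_five_class():
    """5 classes x 12 records, enough for quick 2-3 fold protocols."""
    cfg = SynthConfig(n_classes=5, records_per_class=12, seed=5)
    return generate_dataset(cfg)


@pytest.fixture()
def default_cfg():
    return ModelConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_record(samples, set_label="A", record_id="A/r0", fs=173.61):
    return EEGRecord(samples=np.asarray(samples, dtype=float), fs=fs,
                     set_label=set_label, record_id=record_id)


def make_segments(n, window=512, n_classes=5, seed=0, channels=1):
    gen = np.random.default_rng(seed)
    return [
        LabeledSegment(values=gen.standard_normal((channels, window)),
                       label=i % n_classes, origin_id=f"r{i}",
                       segment_index=0)
        for i in range(n)
    ]
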