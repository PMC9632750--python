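import numpy as np
import pytest

from dermofuse.dataio import ImageRecord, LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(counts: dict[str, int], h: int = 4, w: int = 4,
                 seed: int = 0) -> LabeledDataset:
    """In-memory dataset with tiny random images and exact per-class counts."""
    gen = np.random.default_rng(seed)
    records = []
    for cls, n in counts.items():
        for i in range(n):
            px = gen.random((h, w, 3)).astype(np.float32)
            records.append(ImageRecord(id=f"{cls}_{i:05d}", pixels=px,
                                       label=cls))
    return LabeledDataset(records, tuple(counts))


@pytest.fixture
def small_dataset():
    return make_dataset({"a": 12, "b": 7, "c": 5}, h=6, w=6, seed=1)


# the archive's per-class training-split counts used throughout the
# augmentation arithmetic tests (order: akiec, bcc, bkl, df, nv, mel, vasc)
TRAIN_COUNTS = {"akiec": 209, "bcc": 329, "bkl": 703, "df": 74,
                "nv": 4291, "mel": 712, "vasc": 91}
AFTER_ROTATION = {"akiec": 836, "bcc": 1316, "bkl": 2812, "df": 296,
                  "nv": 4291, "mel": 2848, "vasc": 364}
NUM_ADD = {"akiec": 4, "bcc": 2, "bkl": 0, "df": 13, "nv": 0, "mel": 0,
           "vasc": 10}
FINAL_COUNTS = {"akiec": 4180, "bcc": 3948, "bkl": 4291, "df": 4144,
                "nv": 4291, "mel": 4291, "vasc": 4004}
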