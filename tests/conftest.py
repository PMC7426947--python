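import numpy as np
import pytest

from auxrad.manifest import DatasetManifest
from auxrad.synth import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory) -> DatasetManifest:
    """A small paired dataset shared by training-protocol tests."""
    counts = {
        "train": {"normal": 8, "A1": 8, "A2": 8, "A3": 8,
                  "B1": 8, "B2": 8, "B3": 8},
        "val": {"normal": 2, "A1": 2, "A2": 2, "A3": 2,
                "B1": 2, "B2": 2, "B3": 2},
        "test": {"normal": 4, "A1": 4, "A2": 4, "A3": 4,
                 "B1": 4, "B2": 4, "B3": 4},
    }
    out = tmp_path_factory.mktemp("smalldata")
    return generate_dataset(counts, PhantomSpec(image_size=64), seed=101,
                            out_dir=out)
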