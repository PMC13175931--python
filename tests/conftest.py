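import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from octnss.phantom import PhantomDatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """Default-scale phantom dataset (8 classes x 23/4/4), generated once."""
    root = tmp_path_factory.mktemp("phantoms")
    return generate_dataset(PhantomDatasetSpec(root=root, seed=7))
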