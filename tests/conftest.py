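import numpy as np
import pytest

from kromnet.synthgen import (
    generate_dataset,
    noiseless,
    record_seed,
    render_limb,
    sample_pose,
)


@pytest.fixture(scope="session")
def overfit16():
    """16 binarized inputs at the default 128x128 resolution, 4 per label."""
    from kromnet.imaging import preprocess_image

    xs, ys = [], []
    idx = 0
    for label in range(4):
        for _ in range(4):
            pose = sample_pose("four_class", label, record_seed(16, idx), canvas=192)
            img = render_limb(noiseless(pose), 192, 192)
            xs.append(preprocess_image(img, side=128))
            ys.append(label)
            idx += 1
    return np.stack(xs), np.array(ys)


@pytest.fixture(scope="session")
def noiseless64():
    """64 clean renders, 16 per four-class label, at 64x64 input."""
    from kromnet.imaging import preprocess_image

    xs, ys = [], []
    idx = 0
    for label in range(4):
        for _ in range(16):
            pose = sample_pose("four_class", label, record_seed(64, idx), canvas=96)
            img = render_limb(noiseless(pose), 96, 96)
            xs.append(preprocess_image(img, side=64))
            ys.append(label)
            idx += 1
    return np.stack(xs), np.array(ys)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small on-disk four-class dataset (10 per class, canvas 96)."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    manifest = generate_dataset("four_class", (10, 10, 10, 10), 96, out, global_seed=5)
    return manifest, out
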