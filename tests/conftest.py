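import numpy as np
import pytest

from flairseg import (
    ArchitectureSpec,
    PhantomSpec,
    Slice2D,
    TrainConfig,
    build_network,
    derive_labels,
    generate_dataset,
    train,
    zscore_normalize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_slice():
    """Deterministic non-constant 16x16 slice."""
    px = np.arange(256, dtype=float).reshape(16, 16)
    return Slice2D(pixels=px, volume_id="ramp", slice_index=0)


SMALL_SIDE = 32


@pytest.fixture(scope="session")
def small_phantoms():
    """60 side-32 phantoms: cheap but structurally identical to the defaults."""
    spec = PhantomSpec(
        side=SMALL_SIDE, tumor_prob=0.5, lesion_radius_range=(3, 6),
        lesion_contrast=3.0, seed=202,
    )
    data = generate_dataset(60, spec)
    data["labels"] = derive_labels(data["masks"])
    data["normed"] = [zscore_normalize(s) for s in data["slices"]]
    return data


@pytest.fixture(scope="session")
def trained_small_net(small_phantoms):
    """Scale-8 network trained on the side-32 phantoms; used by tests that
    need a realistic classifier + feature maps without the full study."""
    data = small_phantoms
    X = np.stack([s.pixels for s in data["normed"]])[:, None].astype(np.float32)
    net = build_network(
        ArchitectureSpec(input_side=SMALL_SIDE), scale=8, seed=7
    )
    cfg = TrainConfig(epochs=12, batch_size=10, alpha0=1e-3, seed=3)
    return train(net, (X, data["labels"]), cfg)
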