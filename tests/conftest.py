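import numpy as np
import pytest

from latsr import generator_models as gm
from latsr import normalizing_flow as nf


@pytest.fixture(scope="session")
def mini_gen32():
    return gm.make_style_mini(d=16, size=32, channels=16, seed=7)


@pytest.fixture(scope="session")
def mini_gen16():
    return gm.make_style_mini(d=16, size=16, channels=8, seed=7)


@pytest.fixture(scope="session")
def oracle_gen():
    return gm.make_linear_oracle(4, (1, 4, 4), seed=0)


def perturbed_flow(d: int, n_blocks: int = 2, hidden_dim: int = 16,
                   seed: int = 0, scale: float = 0.3) -> nf.FlowModel:
    """A random non-identity flow (no training): output layers get small
    random weights so the transform is a generic invertible map."""
    flow = nf.FlowModel(d=d, n_blocks=n_blocks, hidden_dim=hidden_dim, seed=seed)
    rng = np.random.default_rng(seed + 50)
    for blk in flow.params:
        blk["Wm"] = scale * rng.standard_normal(blk["Wm"].shape)
        blk["Wa"] = scale * rng.standard_normal(blk["Wa"].shape)
        blk["bm"] = scale * rng.standard_normal(blk["bm"].shape)
        blk["ba"] = scale * rng.standard_normal(blk["ba"].shape)
    return flow


@pytest.fixture(scope="session")
def flow16_trained(mini_gen32):
    """A quickly trained d=16 flow on mapped style latents (desk-scale)."""
    rng = np.random.default_rng(5)
    w = gm.map_latent(rng.standard_normal((6000, 16)), mini_gen32)
    cfg = nf.FlowTrainConfig(n_blocks=2, hidden_dim=32, n_samples=6000,
                             epochs=25, batch_size=256, learning_rate=2e-3,
                             seed=1)
    return nf.train_flow(w, cfg)
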