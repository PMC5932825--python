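import numpy as np
import pytest

from phylorigins import SimulationConfig, simulate_tree, simulate_traits


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def yule(seed: int, n_tips: int, depth: float | None = None):
    """Convenience wrapper: one Yule tree under a fixed seed."""
    cfg = SimulationConfig(seed=seed, n_tips=n_tips, tree_depth=depth)
    return simulate_tree(cfg)


def mk_trait(seed: int, n_tips: int, depth: float | None = None,
             gain: float = 0.47, loss: float = 0.47):
    """(tree, trait matrix, generating history) under the mk regime."""
    cfg = SimulationConfig(
        seed=seed, n_tips=n_tips, tree_depth=depth,
        gain_rate=gain, loss_rate=loss, trait_regime="mk",
    )
    tree = simulate_tree(cfg)
    traits, hist = simulate_traits(tree, cfg)
    return tree, traits, hist
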