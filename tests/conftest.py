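import numpy as np
import pytest

from peabrain import synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_stage1_world(tmp_path_factory):
    """A small, fast Stage-1 world: 30 genes x 300 bp promoters."""
    return sd.make_stage1_world(tmp_path_factory.mktemp("s1"), n_genes=30,
                                halfwidth=150, sigma=0.0, seed=42)


@pytest.fixture(scope="session")
def tiny_stage2_world(tmp_path_factory):
    """A small Stage-2 cohort: 24 individuals over a 2 kb window."""
    return sd.make_stage2_world(tmp_path_factory.mktemp("s2"),
                                n_individuals=24, window=2000, m_variants=12,
                                c_causal=3, beta_scale=0.8, sigma=0.05,
                                seed=42)


def promote_float64(net):
    """Cast a network's parameters to float64 for finite-difference checks."""
    stack = list(getattr(net, "layers", [])) or [net.up, net.core, net.down,
                                                 net.merge, net.out]
    for layer in stack:
        seq = getattr(layer, "seq", None)
        if seq is not None:
            promote_float64(seq)
            continue
        for attr in ("W", "b", "dW", "db"):
            if hasattr(layer, attr):
                setattr(layer, attr, getattr(layer, attr).astype(np.float64))
    return net
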