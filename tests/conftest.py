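import numpy as np
import pytest

from archenet import (
    SyntheticConfig,
    action_kernel_transform,
    build_network,
    generate,
    normalize_encodings,
    prune,
    reduce,
    run_multilevel,
)


@pytest.fixture(scope="session")
def bench_small():
    """Small planted benchmark (4 identity + 1 activity programs, 120 cells)
    run through reduction, multilevel decomposition, network and pruning."""
    cfg = SyntheticConfig(
        n_identity_programs=4,
        n_activity_programs=1,
        cells_per_type=30,
        n_genes=200,
        seed=0,
    )
    expr, truth = generate(cfg)
    Z = action_kernel_transform(expr)
    red = reduce(Z, D=20, seed=0)
    ml = run_multilevel(red, 2, 10)
    H_norm = normalize_encodings(ml.H_star)
    net = build_network(H_norm, cell_names=red.cell_names)
    states = prune(ml, seed=0)
    return dict(
        cfg=cfg, expr=expr, truth=truth, red=red, ml=ml,
        H_norm=H_norm, net=net, states=states,
    )


@pytest.fixture(scope="session")
def bench_default():
    """The default low-noise benchmark instance (13 identity + 1 activity,
    325 cells) run through the full decomposition pipeline at k = 2..30."""
    cfg = SyntheticConfig(seed=1)
    expr, truth = generate(cfg)
    Z = action_kernel_transform(expr)
    red = reduce(Z, D=50, seed=1)
    ml = run_multilevel(red, 2, 30)
    states = prune(ml, seed=1)
    H_norm = normalize_encodings(ml.H_star)
    net = build_network(H_norm, cell_names=red.cell_names)
    return dict(
        cfg=cfg, expr=expr, truth=truth, red=red, ml=ml, states=states, net=net
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
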