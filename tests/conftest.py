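import numpy as np
import pytest

from txmkit.phantoms import (
    default_xanes_phantom,
    make_shepp_logan,
    make_texture,
    make_xanes_stack,
)
from txmkit.xanes import EdgeConfig, ReferenceSet, _ols_lines

ENERGIES = np.linspace(7090.0, 7180.0, 50)


@pytest.fixture(scope="session")
def edge_cfg() -> EdgeConfig:
    return EdgeConfig(7090.0, 7110.0, 7150.0, 7180.0, 7120.0, k=3.0)


@pytest.fixture(scope="session")
def texture() -> np.ndarray:
    return make_texture((128, 128), seed=1)


@pytest.fixture(scope="session")
def shepp64() -> np.ndarray:
    return make_shepp_logan(64)


@pytest.fixture(scope="session")
def shepp128() -> np.ndarray:
    return make_shepp_logan(128)


@pytest.fixture(scope="session")
def xanes_data(edge_cfg):
    """Default noisy XANES phantom stack + truth + matching references."""
    phantom = default_xanes_phantom(seed=0)
    stack, truth = make_xanes_stack(phantom, ENERGIES)
    refs = normalized_references(truth["profiles"], ENERGIES, edge_cfg)
    return phantom, stack, truth, refs


def normalized_references(
    profiles: np.ndarray, energies: np.ndarray, cfg: EdgeConfig
) -> ReferenceSet:
    """Normalize pure-phase edge profiles through the same pre/post-edge line
    procedure the per-pixel normalization uses, as reference standards are in
    practice."""
    rows = []
    for prof in profiles:
        col = prof[:, None, None]
        sp, bp = _ols_lines(col, energies, cfg.pre_idx(energies))
        so, bo = _ols_lines(col, energies, cfg.post_idx(energies))
        l_pre = sp * energies[:, None, None] + bp
        l_post = so * energies[:, None, None] + bo
        rows.append(((col - l_pre) / (l_post - l_pre))[:, 0, 0])
    return ReferenceSet(
        [f"ref{i + 1}" for i in range(len(rows))], np.stack(rows)
    )
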