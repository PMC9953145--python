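import dataclasses

import numpy as np
import pytest

from fadf import (
    KineticParams,
    PhantomConfig,
    generate_vessel_tree,
    render_session,
)

#: detection tracer with no renal clearance: static intravascular signal, so
#: the leakage index responds to permeability alone (zero-permeability -> 1)
NO_CLEARANCE = KineticParams(k_perm=0.2, k_clear=0.0)
REFERENCE = KineticParams(k_perm=0.0, k_clear=0.0)


@pytest.fixture(scope="session")
def default_tree():
    """One 512x512 four-level phantom tree shared across tests."""
    return generate_vessel_tree(PhantomConfig(tree_seed=7))


@pytest.fixture(scope="session")
def small_tree():
    """A compact 160x160 two-level tree for fast unit tests."""
    return generate_vessel_tree(
        PhantomConfig(image_shape=(160, 160), tree_seed=5, n_branch_levels=2)
    )


def render_variant(tree, kin_det=NO_CLEARANCE, kin_ref=REFERENCE, **overrides):
    """Re-render a tree under modified imaging conditions (noise, drift, ...)."""
    cfg = dataclasses.replace(tree.config, **overrides)
    tree = dataclasses.replace(tree, config=cfg)
    return render_session(tree, kin_det, kin_ref)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
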