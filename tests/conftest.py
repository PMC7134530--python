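"""Shared fixtures: small phantoms and scaled-down training artifacts.

The expensive trained-model fixtures are session-scoped so that the
segmentation-quality, ablation-ordering and baseline-comparison tests all
reuse the same training runs.
"""

from __future__ import annotations

import numpy as np
import pytest

import atriaseg as ag


def small_spec(**kwargs) -> ag.PhantomSpec:
    """A coarse 20-voxel phantom spec for fast unit tests."""
    defaults = dict(
        grid_edge=20,
        spacing_mm=2.0,
        la_semi_axes_mm=(12.0, 10.0, 9.0),
        wall_thickness_mm=2.25,
        n_pv_tubes=2,
        pv_radius_mm=3.0,
        pv_length_mm=8.0,
    )
    defaults.update(kwargs)
    return ag.PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom() -> ag.PhantomSample:
    return ag.generate_phantom(small_spec(seed=42))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def scaled_study():
    """Train the full model and the no-attention variant on three seeds of
    the 40-phantom study; reused by the acceptance and ordering tests."""
    from study import SEEDS, run_variant

    full = {s: run_variant(s, use_attention=True, with_baselines=True) for s in SEEDS}
    no_attention = {s: run_variant(s, use_attention=False, with_baselines=False)
                    for s in SEEDS}
    return {"full": full, "no_attention": no_attention}
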