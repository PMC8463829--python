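"""Shared fixtures: small synthetic grids and the full default study.

The default study (phantom + four optimized plans + robustness reports)
is expensive, so it is computed once per session and shared between the
study-contract tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pbsplan import (
    PhantomConfig,
    StudyConfig,
    VoxelGrid,
    build_context,
    evaluate_plan,
    optimize_scheme,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water_rsp() -> VoxelGrid:
    """A uniform RSP=1 water box: 2 mm voxels, y spanning [-109, 109] mm.

    The posterior entrance plane (for a gantry-180 beam) sits at
    y = +110 mm, so a point at y = 110 - d lies at water depth d.
    """
    shape = (110, 110, 40)
    spacing = np.array([2.0, 2.0, 2.0])
    origin = -(np.array(shape) - 1) / 2.0 * spacing
    return VoxelGrid(np.ones(shape, dtype=np.float32), spacing, origin, "RSP")


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    """A compact phantom for fast unit tests (not the study default)."""
    return PhantomConfig(
        shape=(96, 96, 48),
        spacing=(2.0, 2.0, 2.0),
        body_semiaxes=(80.0, 70.0),
        gtv_center=(0.0, -20.0, 0.0),
        gtv_semiaxes=(10.0, 9.0, 8.0),
        duodenum_half_length=16.0,
        duodenum_bow=6.0,
    )


@pytest.fixture(scope="session")
def default_study():
    """The full default study: context, plans and robustness reports.

    Returns (context, plans, reports) for the four schemes at the
    default 33 Gy(RBE)/5 fx, 2 mm / 3.5% study conditions.
    """
    cfg = StudyConfig()
    ctx = build_context(cfg)
    plans, reports = {}, {}
    for scheme in cfg.schemes:
        plans[scheme] = optimize_scheme(ctx, scheme)
        reports[scheme] = evaluate_plan(ctx, plans[scheme])
    return ctx, plans, reports
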