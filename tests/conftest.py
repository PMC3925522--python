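"""Shared fixtures.

Heavy artefacts (offset shells, full phantom runs) are session-scoped and
shared between the module tests and the acceptance suite so the whole run
stays within a laptop-scale budget. Two phantom configurations are used: a
coarse "mini" phantom for integration-style checks and the default-resolution
phantom (plus its 2x refinement) for end-to-end recovery.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
import trimesh

from quadzone import (
    PhantomSpec,
    RunConfig,
    TriangleMesh,
    generate_phantom,
    make_incision,
    run_subject,
)
from quadzone.offset import offset_surface
from quadzone.phantom import analytic_truth
from quadzone.pipeline import SubjectInputs

N_VIEWPOINTS_E2E = 9


def icosphere(radius: float = 10.0, center=(0.0, 0.0, 0.0), subdivisions: int = 3) -> TriangleMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices) + np.asarray(center, dtype=float), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def sphere24() -> TriangleMesh:
    """Watertight sphere of radius 24 mm (acetabulum-scale)."""
    return icosphere(radius=24.0, subdivisions=4)


@pytest.fixture(scope="session")
def sphere24_shells(sphere24):
    """Offset surfaces of the 24 mm sphere at the two clinical clearances."""
    return {
        0.0: offset_surface(sphere24, 0.0, 0.5),
        2.95: offset_surface(sphere24, 2.95, 0.5),
        6.0: offset_surface(sphere24, 6.0, 0.5),
    }


# --- phantom configurations -------------------------------------------------


def _run(spec: PhantomSpec, pitch: float, n_viewpoints: int):
    subj = generate_phantom(spec, "phantom", n_viewpoints=n_viewpoints)
    cfg = RunConfig(voxel_pitch=pitch, n_viewpoints=n_viewpoints)
    result = run_subject(cfg, SubjectInputs.from_phantom(subj))
    aperture = make_incision(
        subj.landmarks.incision_proximal, subj.landmarks.incision_distal, n_viewpoints
    )
    truth = analytic_truth(spec, cfg.offsets, aperture=aperture)
    return subj, cfg, result, truth


@pytest.fixture(scope="session")
def mini_phantom():
    """Coarse, fast phantom (2 mm mesh, 1 mm voxels, 5 viewpoints)."""
    spec = dataclasses.replace(PhantomSpec(), mesh_resolution=2.0)
    return _run(spec, pitch=1.0, n_viewpoints=5)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-resolution phantom (1 mm mesh, 0.5 mm voxels)."""
    return _run(PhantomSpec(), pitch=0.5, n_viewpoints=N_VIEWPOINTS_E2E)


@pytest.fixture(scope="session")
def fine_phantom():
    """2x refinement of the default phantom (0.5 mm mesh, 0.25 mm voxels)."""
    spec = dataclasses.replace(PhantomSpec(), mesh_resolution=0.5)
    return _run(spec, pitch=0.25, n_viewpoints=N_VIEWPOINTS_E2E)


def landmark_errors(result, truth) -> dict[tuple[float, str], float]:
    """Euclidean E/F/G/H recovery errors (mm) per shell offset."""
    errs = {}
    for d, zl in result.landmarks.items():
        tl = truth.landmarks[d]
        for nm in "EFGH":
            errs[(d, nm)] = float(np.linalg.norm(getattr(zl, nm) - getattr(tl, nm)))
    return errs


def distance_errors(result, truth) -> dict[tuple[float, str], float]:
    """Absolute measurement errors (cm) per shell offset."""
    errs = {}
    for rec in result.records:
        tr = truth.records[rec.offset_d]
        for m in ("EK", "FK", "GM", "GN", "HP", "HQ"):
            errs[(rec.offset_d, m)] = abs(getattr(rec, m) - getattr(tr, m))
    return errs
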