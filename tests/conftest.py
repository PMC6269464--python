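"""Shared fixtures: small random stacks and the packaged phantom cohort.

The cohort-level fixtures are session-scoped because the full pipeline on
eight 128³ phantoms takes a few minutes; every test that needs cohort
curves shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import angioarch as aa

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_stack(voxels: np.ndarray, voxel_size_um: float = 0.54) -> aa.BinaryStack:
    return aa.BinaryStack(aa.GridMeta(voxel_size_um, voxels.shape), voxels.astype(bool))


def random_stack(shape, density: float, seed: int) -> aa.BinaryStack:
    rng = np.random.default_rng(seed)
    return make_stack(rng.random(shape) < density)


@pytest.fixture(scope="session")
def cohort_stacks() -> list[tuple[str, aa.BinaryStack]]:
    """The packaged 8-sample hierarchical phantom cohort (fixed seeds)."""
    return [
        (sample_id, aa.generate_phantom(spec)[0])
        for sample_id, spec in aa.default_cohort()
    ]


@pytest.fixture(scope="session")
def cohort_analysis(cohort_stacks) -> aa.AnalysisResult:
    """Full V/D pipeline on the control cohort."""
    return aa.analyze_samples({"ctrl": cohort_stacks})


@pytest.fixture(scope="session")
def depleted_analysis(cohort_stacks) -> aa.AnalysisResult:
    """Pipeline on the cohort after 10% random signal depletion."""
    depleted = [
        (sid, aa.deplete_random(s, aa.DepletionSpec(fraction=0.10, seed=9000 + i)))
        for i, (sid, s) in enumerate(cohort_stacks)
    ]
    return aa.analyze_samples({"depleted": depleted})


@pytest.fixture(scope="session")
def treatment_analysis(cohort_stacks) -> aa.AnalysisResult:
    """Control vs anti-angiogenic-transformed cohort, one shared batch."""
    treated = []
    for sid, s in cohort_stacks:
        prepared = aa.prepare_stack(s)
        classified = aa.classify_voxels(prepared)
        treated.append(
            (sid, aa.deplete_classes(prepared, classified, (1, 6, 7), 0.5, seed=777))
        )
    return aa.analyze_samples({"ctrl": cohort_stacks, "treated": treated})
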