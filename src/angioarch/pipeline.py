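"""End-to-end analysis: classify → cumulate → V/D → median → fit → compare.

This is the library counterpart of the ``fingerprint`` CLI command and the
single entry point the acceptance machinery uses: it takes binary stacks
grouped by treatment, resolves the batch normalization reference (the
greatest initial V% over every cumulated tree of every sample of every
group), and returns per-sample curves, per-group median curves, fingerprint
parameters and — with at least two groups — the statistical comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .caliber import CaliberClassScheme, classify_voxels, prepare_stack
from .dispersion import DilationScheme, HaloConfig
from .errors import ConfigurationError
from .fingerprint import (
    FingerprintParams,
    GroupComparison,
    MedianCurve,
    VDCurve,
    batch_reference_volume,
    compare_groups,
    compute_vd_curve,
    cumulate_classes,
    extract_parameters,
    median_curve,
)
from .grid import BinaryStack


@dataclass
class GroupResult:
    """Per-group analysis products."""

    curves: list[VDCurve]
    median: MedianCurve
    sample_params: list[FingerprintParams]
    #: Fit of the median curve itself (endpoints/slope of the median points).
    median_fit_params: FingerprintParams
    #: Same, but with projected lengths taken as medians of per-sample lengths
    #: and the slope replaced by the median of per-sample slopes.
    median_of_samples: dict


@dataclass
class AnalysisResult:
    reference_volume_percent: float
    groups: dict[str, GroupResult]
    comparison: GroupComparison | None


def analyze_samples(
    samples_by_group: dict[str, list[tuple[str, BinaryStack]]],
    scheme: CaliberClassScheme | None = None,
    dilation: DilationScheme | None = None,
    target_fill_fraction: float = 0.95,
    reference_volume_percent: float | None = None,
    fill_hollow: bool = True,
    speck_min_voxels: int = 0,
) -> AnalysisResult:
    """Run the full fingerprint pipeline on grouped binary stacks.

    ``reference_volume_percent=None`` resolves the normalization reference
    automatically as the batch maximum before any dispersion index is
    computed.  All stacks must share one voxel size.
    """
    voxel_sizes = {
        stack.meta.voxel_size_um
        for samples in samples_by_group.values()
        for _, stack in samples
    }
    if len(voxel_sizes) > 1:
        raise ConfigurationError(f"mixed voxel sizes in one batch: {sorted(voxel_sizes)}")
    dilation = dilation if dilation is not None else DilationScheme()

    # classify and cumulate everything first: the normalization reference is
    # a maximum over every tree entering the comparison
    trees_by_group: dict[str, list[tuple[str, list[BinaryStack]]]] = {}
    for group, samples in samples_by_group.items():
        entries = []
        for sample_id, stack in samples:
            prepared = prepare_stack(stack, fill_hollow=fill_hollow, speck_min_voxels=speck_min_voxels)
            classified = classify_voxels(prepared, scheme)
            entries.append((sample_id, cumulate_classes(classified)))
        trees_by_group[group] = entries

    if reference_volume_percent is None:
        all_trees = [trees for entries in trees_by_group.values() for _, trees in entries]
        reference_volume_percent = batch_reference_volume(all_trees)
    config = HaloConfig(
        target_fill_fraction=target_fill_fraction,
        reference_volume_percent=reference_volume_percent,
    )

    groups: dict[str, GroupResult] = {}
    for group, entries in trees_by_group.items():
        curves = [
            compute_vd_curve(trees, scheme=dilation, config=config, sample_id=sid)
            for sid, trees in entries
        ]
        med = median_curve(curves)
        sample_params = [extract_parameters(c) for c in curves]
        lengths = [(c.x_length, c.y_length) for c in curves]
        median_fit = extract_parameters(med, per_sample_lengths=lengths)
        median_of_samples = {
            "slope": float(np.median([p.slope for p in sample_params])),
            "r_squared": float(np.median([p.r_squared for p in sample_params])),
            "x_length": float(np.median([p.x_length for p in sample_params])),
            "y_length": float(np.median([p.y_length for p in sample_params])),
        }
        groups[group] = GroupResult(
            curves=curves,
            median=med,
            sample_params=sample_params,
            median_fit_params=median_fit,
            median_of_samples=median_of_samples,
        )

    comparison = None
    eligible = {g: r.sample_params for g, r in groups.items() if len(r.sample_params) >= 2}
    if len(eligible) >= 2:
        comparison = compare_groups(eligible)
    return AnalysisResult(
        reference_volume_percent=reference_volume_percent,
        groups=groups,
        comparison=comparison,
    )
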