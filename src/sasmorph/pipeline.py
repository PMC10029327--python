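"""End-to-end convenience wrappers: phantom -> enhance -> segment -> report.

These functions fix the cross-module defaults that make the stages work
together at desk scale (filter passband bracketing the structure scales,
morphology radii tied to the largest expected trabecular radius) and are the
entry points used by the command-line interface and the acceptance runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enhance import CurveletBank, enhance_volume
from .grids import BinaryMask, VoxelGrid
from .phantom import PhantomSpec, PhantomTruth, generate_phantom
from .report import MorphometryReport, ReportConfig, compile_report
from .segment import SegmentSet, build_segments, threshold_segment

__all__ = [
    "default_bank",
    "radius_recovery_spec",
    "segment_enhanced",
    "run_phantom_pipeline",
]


def default_bank(octaves: int = 7, directions: int = 11) -> CurveletBank:
    """Directional band-pass bank for desk-scale volumes.

    Seven octaves stretch the passband low enough that the nerve trunk and
    dura (tens of voxels across at 1 um voxels) keep their interior signal
    and threshold as solid bodies; smooth background is handled by the
    quadratic detrend plus the sub-passband cutoff, and the quarter-gain
    highest ring damps filament-scale artifacts.
    """
    gains = np.ones(octaves)
    gains[0] = 0.25
    return CurveletBank(octaves=octaves, directions=directions, octave_gains=gains)


def radius_recovery_spec(radius_um: float, rng_seed: int = 0,
                         trabecula_count: int = 12) -> PhantomSpec:
    """Phantom with a single fixed trabecular radius (parameter recovery)."""
    return PhantomSpec(
        trabecula_count=trabecula_count,
        trabecula_radius_um_range=(radius_um, radius_um),
        septum_count=0,
        artifact_count=0,
        rng_seed=rng_seed,
    )


def segment_enhanced(
    enhanced: VoxelGrid,
    max_trabecula_radius_um: float,
    threshold: float | None = None,
) -> SegmentSet:
    """Threshold the enhanced volume and build the compartments.

    The CSF-envelope closing radius is three times the largest expected
    trabecular radius; the macro opening radius is 1.25 times it, enough to
    strip trabeculae off the nerve and dura without destroying them.
    """
    raw = threshold_segment(enhanced, threshold)
    return build_segments(
        raw,
        closing_radius_um=3.0 * max_trabecula_radius_um,
        macro_opening_radius_um=1.25 * max_trabecula_radius_um,
        exclude_boundary_csf=True,
    )


def run_phantom_pipeline(
    spec: PhantomSpec,
    bank: CurveletBank | None = None,
    report_config: ReportConfig | None = None,
    threshold: float | None = None,
) -> dict:
    """Generate a phantom and push it through enhancement, segmentation and
    reporting. Returns the intermediate products keyed by stage."""
    volume, truth = generate_phantom(spec)
    bank = bank or default_bank()
    enhanced = enhance_volume(volume, bank)
    segs = segment_enhanced(enhanced, spec.trabecula_radius_um_range[1], threshold)
    cfg = report_config or ReportConfig(sector_angle_deg=0.0)
    rep = compile_report(segs, cfg)
    return {
        "volume": volume,
        "truth": truth,
        "enhanced": enhanced,
        "segments": segs,
        "report": rep,
    }
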