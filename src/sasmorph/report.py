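"""Table-style morphometry summaries of the ON SAS.

Assembles, for a segmented volume, the quantities that characterize the
subarachnoid space: CSF volume (mollified level-set integration), CSF
interface area (zero level-set mesh), the same pair after digital removal of
the microstructure, the surface amplification factor and microstructure
volume fraction derived from them, thickness/separation density functions
and the fluid-space census. A damaged angular sector can be excluded before
measurement, with areas and volumes renormalized by 360/(360 - angle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import geometry, morphometry
from .segment import SegmentSet, apply_sector_exclusion, remove_microstructure

__all__ = [
    "ReportConfig",
    "MorphometryReport",
    "compile_report",
    "volume_fraction",
    "amplification_factor",
    "component_areas",
    "REFERENCE_MEASUREMENTS",
    "round_half_away",
]

#: Published reference morphometry of two SRuCT-imaged human ON segments
#: (bulbar and intraorbital), used as arithmetic inputs for consistency
#: checks: section length (mm), CSF volume (mm^3) and SAS/CSF interface
#: area (mm^2), each measured and with the microstructure digitally removed.
REFERENCE_MEASUREMENTS = {
    "bulbar": {
        "on_length_mm": 0.75,
        "csf_volume_mm3": {"measured": 2.61, "no_microstructure": 4.11},
        "interface_area_mm2": {"measured": 114.89, "no_microstructure": 23.65},
    },
    "intraorbital": {
        "on_length_mm": 0.73,
        "csf_volume_mm3": {"measured": 1.68, "no_microstructure": 2.64},
        "interface_area_mm2": {"measured": 68.20, "no_microstructure": 21.03},
    },
}


def round_half_away(x: float, decimals: int = 2) -> float:
    """Presentation rounding, half away from zero (as printed tables use)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def amplification_factor(measured_area: float, no_micro_area: float) -> float:
    """Measured interface area over the microstructure-free interface area."""
    if no_micro_area <= 0:
        raise ValueError("no-microstructure area must be positive")
    return measured_area / no_micro_area


def volume_fraction(measured_csf: float, no_micro_csf: float) -> float:
    """Fraction of the SAS volume occupied by the microstructure:
    (no_micro - measured) / no_micro."""
    if not (no_micro_csf >= measured_csf > 0):
        raise ValueError(
            "expected no_micro >= measured > 0, got "
            f"measured={measured_csf}, no_micro={no_micro_csf}"
        )
    return (no_micro_csf - measured_csf) / no_micro_csf


def component_areas(mesh: geometry.TriangleMesh) -> np.ndarray:
    """Surface area of each connected component of a triangle mesh."""
    if len(mesh.triangles) == 0:
        return np.zeros(0)
    t = mesh.triangles
    n = len(mesh.vertices)
    rows = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
    cols = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    tri_label = labels[t[:, 0]]
    areas = mesh.triangle_areas()
    return np.bincount(tri_label, weights=areas, minlength=n_comp)


@dataclass
class ReportConfig:
    epsilon_um: float | None = None          # mollifier half-width; default 1 voxel
    bin_width_um: float = 2.0                # thickness/separation PDF bin
    census_threshold_um: float = 130.0       # fluid-space diameter threshold
    census_h_depth_um: float | None = None   # h-maxima depth; default 2 voxels
    sector_angle_deg: float = 0.0            # damaged sector to discard
    sector_reference_dir: tuple = (0.0, 0.0, 1.0)
    sector_start_deg: float = 0.0


@dataclass
class MorphometryReport:
    section_length_mm: float
    csf_volume_mm3: dict            # measured / no_microstructure
    interface_area_mm2: dict        # measured / no_microstructure
    interface_area_no_dura_mm2: dict
    amplification_factor: float
    microstructure_volume_fraction: float
    renormalization_factor: float
    thickness_pdf: tuple | None
    separation_pdf: tuple
    space_census: morphometry.SpaceCensus
    params: dict = field(default_factory=dict)

    def table(self) -> dict:
        """Two-decimal presentation of the headline quantities."""
        r2 = lambda x: round_half_away(x, 2)
        return {
            "section_length_mm": r2(self.section_length_mm),
            "csf_volume_mm3": {k: r2(v) for k, v in self.csf_volume_mm3.items()},
            "interface_area_mm2": {k: r2(v) for k, v in self.interface_area_mm2.items()},
            "amplification_factor": r2(self.amplification_factor),
            "microstructure_volume_fraction": r2(self.microstructure_volume_fraction),
        }

    def to_dict(self) -> dict:
        d = {
            "section_length_mm": self.section_length_mm,
            "csf_volume_mm3": self.csf_volume_mm3,
            "interface_area_mm2": self.interface_area_mm2,
            "interface_area_no_dura_mm2": self.interface_area_no_dura_mm2,
            "amplification_factor": self.amplification_factor,
            "microstructure_volume_fraction": self.microstructure_volume_fraction,
            "renormalization_factor": self.renormalization_factor,
            "n_spaces": len(self.space_census),
            "census_threshold_um": self.space_census.diameter_threshold_um,
            "params": self.params,
        }
        return d


def _dura_facing_area_mm2(mesh: geometry.TriangleMesh, segs: SegmentSet) -> float:
    """Area of mesh triangles whose nearest non-CSF voxel is dura (macro
    anatomy that is not the ON) - the outer, dura-facing boundary."""
    if len(mesh.triangles) == 0 or segs.macro_mask is None:
        return 0.0
    dura = segs.macro_mask.data & ~segs.on_mask.data
    if not dura.any():
        return 0.0
    non_csf = ~segs.csf_mask.data
    idx = ndimage.distance_transform_edt(~non_csf, return_distances=False,
                                         return_indices=True)
    centroids = mesh.vertices[mesh.triangles].mean(axis=1) / segs.voxel_size_um
    vox = np.clip(np.round(centroids).astype(int), 0,
                  np.array(segs.csf_mask.shape) - 1)
    nz = idx[0][vox[:, 0], vox[:, 1], vox[:, 2]]
    ny = idx[1][vox[:, 0], vox[:, 1], vox[:, 2]]
    nx = idx[2][vox[:, 0], vox[:, 1], vox[:, 2]]
    facing_dura = dura[nz, ny, nx]
    areas = mesh.triangle_areas()
    return float(areas[facing_dura].sum()) * 1e-6


def _measure(segs: SegmentSet, cfg: ReportConfig) -> dict:
    sdf = geometry.signed_distance(segs.csf_mask)
    vol = geometry.volume_mollified(sdf, cfg.epsilon_um)
    mesh = geometry.extract_zero_levelset(sdf)
    area = geometry.mesh_area(mesh)
    return {"volume_mm3": vol["mm3"], "area_mm2": area["mm2"],
            "mesh": mesh, "sdf": sdf}


def compile_report(segs: SegmentSet, config: ReportConfig | None = None) -> MorphometryReport:
    """Run volumetry and morphometry on the measured and microstructure-free
    segmentations and assemble the summary table.

    Sector exclusion (if configured) is applied before any measurement;
    areas and volumes are then multiplied by the angular renormalization
    factor. Thickness and separation density functions and the fluid-space
    census are computed on the measured segmentation only.
    """
    cfg = config or ReportConfig()
    if cfg.sector_angle_deg > 0:
        segs = apply_sector_exclusion(segs, cfg.sector_angle_deg,
                                      cfg.sector_reference_dir, cfg.sector_start_deg)
    renorm = segs.renormalization_factor

    measured = _measure(segs, cfg)
    counterfactual = remove_microstructure(segs)
    no_micro = _measure(counterfactual, cfg)

    dura_area = _dura_facing_area_mm2(measured["mesh"], segs)
    dura_area_nm = _dura_facing_area_mm2(no_micro["mesh"], counterfactual)

    if segs.sas_mask.data.any():
        tmap = morphometry.local_thickness(segs.sas_mask)
        t_pdf = morphometry.thickness_pdf(tmap, cfg.bin_width_um)
    else:
        t_pdf = None
    sep = morphometry.separation(segs.csf_mask)
    s_pdf = morphometry.thickness_pdf(sep, cfg.bin_width_um)
    census = morphometry.count_intertrabecular_spaces(
        sep, cfg.census_threshold_um, cfg.census_h_depth_um)

    nz = segs.csf_mask.shape[0]
    report = MorphometryReport(
        section_length_mm=nz * segs.voxel_size_um * 1e-3,
        csf_volume_mm3={
            "measured": measured["volume_mm3"] * renorm,
            "no_microstructure": no_micro["volume_mm3"] * renorm,
        },
        interface_area_mm2={
            "measured": measured["area_mm2"] * renorm,
            "no_microstructure": no_micro["area_mm2"] * renorm,
        },
        interface_area_no_dura_mm2={
            "measured": (measured["area_mm2"] - dura_area) * renorm,
            "no_microstructure": (no_micro["area_mm2"] - dura_area_nm) * renorm,
        },
        amplification_factor=amplification_factor(
            measured["area_mm2"], no_micro["area_mm2"]),
        microstructure_volume_fraction=volume_fraction(
            measured["volume_mm3"], no_micro["volume_mm3"]),
        renormalization_factor=renorm,
        thickness_pdf=t_pdf,
        separation_pdf=s_pdf,
        space_census=census,
        params={
            "epsilon_um": cfg.epsilon_um,
            "bin_width_um": cfg.bin_width_um,
            "census_threshold_um": cfg.census_threshold_um,
            "sector_angle_deg": cfg.sector_angle_deg,
            "segmentation": segs.params,
        },
    )
    return report
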