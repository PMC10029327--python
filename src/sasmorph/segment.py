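"""Compartment segmentation: ON, SAS microstructure and CSF foregrounds.

A hard threshold on the enhanced volume gives a raw solid foreground; the
compartments are then carved out with connected-component logic and
morphology (Euclidean-ball structuring elements realized through distance
transforms, so large radii stay cheap):

1. enclosed cavities in the raw foreground are filled;
2. the macroscopic anatomy (nerve trunk, dura shell) is isolated by a
   closing followed by an opening wide enough to erase trabecular-scale
   structure; the optic nerve is its largest connected component;
3. CSF is the largest 26-connected component of the complement;
4. the SAS microstructure is the raw foreground inside the morphological
   closing of the CSF, minus the macroscopic anatomy.

Foreground connectivity is 26, background 6 (the standard dual pair).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grids import BinaryMask, VoxelGrid

__all__ = [
    "SegmentSet",
    "threshold_segment",
    "otsu_threshold",
    "build_segments",
    "remove_microstructure",
    "apply_sector_exclusion",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentSet:
    """Mutually disjoint ON / SAS-microstructure / CSF foregrounds."""

    on_mask: BinaryMask
    sas_mask: BinaryMask
    csf_mask: BinaryMask
    macro_mask: BinaryMask | None = None
    excluded_sector: tuple | None = None  # (axis_point, axis_dir, ref_dir, angle_deg)
    voxel_size_um: float = 1.0
    params: dict | None = None

    def validate(self) -> None:
        on, sas, csf = self.on_mask.data, self.sas_mask.data, self.csf_mask.data
        if (on & sas).any() or (on & csf).any() or (sas & csf).any():
            raise ValueError("segment foregrounds are not pairwise disjoint")
        if csf.any():
            _, n = ndimage.label(csf, structure=_CONN26)
            if n != 1:
                raise ValueError(f"csf_mask has {n} 26-connected components, expected 1")

    @property
    def renormalization_factor(self) -> float:
        if self.excluded_sector is None:
            return 1.0
        angle = self.excluded_sector[3]
        return 360.0 / (360.0 - angle) if angle else 1.0


def otsu_threshold(volume: VoxelGrid) -> float:
    """Default hard-threshold choice: Otsu on the enhanced histogram."""
    return float(threshold_otsu(np.asarray(volume.data, dtype=np.float64)))


def threshold_segment(enhanced: VoxelGrid, threshold: float | None = None) -> BinaryMask:
    """Hard threshold: foreground = voxels >= threshold. No smoothing."""
    data = np.asarray(enhanced.data, dtype=np.float64)
    if threshold is None:
        threshold = otsu_threshold(enhanced)
    lo, hi = float(data.min()), float(data.max())
    tol = 1e-9 + 1e-6 * (hi - lo)
    if not (lo - tol <= threshold <= hi + tol):
        raise ValueError(
            f"threshold {threshold} outside the intensity range [{lo}, {hi}]"
        )
    return BinaryMask(data >= threshold, voxel_size_um=enhanced.voxel_size_um,
                      label="raw foreground")


def _edt_vox(mask: np.ndarray) -> np.ndarray:
    return ndimage.distance_transform_edt(mask)


def _ball_dilate(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    if radius_vox <= 0:
        return mask.copy()
    return _edt_vox(~mask) <= radius_vox


def _ball_erode(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    if radius_vox <= 0:
        return mask.copy()
    return _edt_vox(mask) > radius_vox


def _ball_close(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    return _ball_erode(_ball_dilate(mask, radius_vox), radius_vox)


def _ball_open(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    return _ball_dilate(_ball_erode(mask, radius_vox), radius_vox)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        raise ValueError("empty main component: nothing to segment")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(sizes.argmax())


def _thickest_component(mask: np.ndarray) -> np.ndarray:
    """Component holding the largest inscribed ball (the nerve trunk is the
    thickest macroscopic structure, even when the dura shell has more voxels)."""
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        raise ValueError("empty main component: nothing to segment")
    if n == 1:
        return mask.copy()
    dt = _edt_vox(mask)
    best = int(np.argmax(ndimage.labeled_comprehension(
        dt, labels, np.arange(1, n + 1), np.max, float, 0.0))) + 1
    return labels == best


def _fill_cavities(mask: np.ndarray) -> np.ndarray:
    """Merge background components not reaching the domain boundary into the
    foreground (6-connected background)."""
    return ndimage.binary_fill_holes(mask)


def build_segments(
    raw_fg: BinaryMask,
    closing_radius_um: float,
    macro_closing_radius_um: float | None = None,
    macro_opening_radius_um: float | None = None,
    exclude_boundary_csf: bool = False,
) -> SegmentSet:
    """Derive the ON / SAS / CSF compartments from the raw solid foreground.

    ``closing_radius_um`` sizes the CSF envelope used to collect the
    microstructure (a good default is three times the largest expected
    trabecular radius). The macroscopic anatomy is isolated with its own
    closing (consolidation, default 2 voxels) and opening (default half the
    CSF closing radius, which must exceed the largest trabecular radius).
    With ``exclude_boundary_csf`` components of the complement touching the
    lateral (y, x) domain faces are not eligible as CSF.
    """
    if not raw_fg.data.any():
        raise ValueError("raw foreground is empty")
    vs = raw_fg.voxel_size_um
    if closing_radius_um < vs:
        raise ValueError("closing radius must be at least one voxel")
    r_close = closing_radius_um / vs
    r_mclose = (macro_closing_radius_um / vs) if macro_closing_radius_um is not None else 2.0
    r_mopen = (macro_opening_radius_um / vs) if macro_opening_radius_um is not None \
        else 0.5 * r_close

    work = _fill_cavities(raw_fg.data)

    # macroscopic anatomy: closing consolidates, opening erases thin structure
    macro = _ball_open(_ball_close(work, r_mclose), r_mopen)
    on = _thickest_component(macro) if macro.any() else macro

    complement = ~work
    if exclude_boundary_csf:
        labels, n = ndimage.label(complement, structure=_CONN26)
        edge_labels = np.unique(np.concatenate([
            labels[:, 0, :].ravel(), labels[:, -1, :].ravel(),
            labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
        for el in edge_labels:
            if el:
                complement = complement & (labels != el)
        if not complement.any():
            raise ValueError("no interior CSF candidate component")
    csf = _largest_component(complement)

    # microstructure: solid material inside the closed-CSF envelope. The
    # envelope takes precedence over the opened macro mask at trabecula
    # attachment fillets, where the blunt opening spills onto true
    # microstructure; wall voxels stay out because the closing hugs convex
    # walls tightly.
    envelope = _ball_close(csf, r_close)
    sas = envelope & work & ~csf
    on = on & ~sas
    macro = macro & ~sas

    params = {
        "closing_radius_um": closing_radius_um,
        "macro_closing_radius_um": r_mclose * vs,
        "macro_opening_radius_um": r_mopen * vs,
    }
    mk = lambda m, lbl: BinaryMask(m, voxel_size_um=vs, label=lbl)
    segs = SegmentSet(
        on_mask=mk(on & ~csf, "on"),
        sas_mask=mk(sas, "sas microstructure"),
        csf_mask=mk(csf, "csf"),
        macro_mask=mk(macro & ~csf, "macro anatomy"),
        voxel_size_um=vs,
        params=params,
    )
    segs.validate()
    return segs


def remove_microstructure(segs: SegmentSet) -> SegmentSet:
    """Digitally remove the SAS microstructure: the counterfactual CSF
    absorbs every former microstructure voxel; the ON is unchanged.

    Conserves the total CSF + SAS voxel count exactly.
    """
    csf = segs.csf_mask.data | segs.sas_mask.data
    out = replace(
        segs,
        csf_mask=segs.csf_mask.copy_with(csf),
        sas_mask=segs.sas_mask.copy_with(np.zeros_like(csf)),
    )
    out.validate()
    return out


def principal_axis(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and dominant second-moment axis (unit vector) of a mask."""
    pts = np.argwhere(mask.data).astype(np.float64)
    if len(pts) == 0:
        raise ValueError("cannot compute the axis of an empty mask")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, int(np.argmax(w))]
    if axis[0] < 0:
        axis = -axis
    return centroid, axis


def apply_sector_exclusion(
    segs: SegmentSet,
    angle_deg: float,
    reference_dir=(0.0, 0.0, 1.0),
    start_deg: float = 0.0,
) -> SegmentSet:
    """Zero all masks inside an angular sector about the nerve axis.

    The axis is the principal second-moment axis of the ON mask; azimuths are
    measured from ``reference_dir`` projected perpendicular to it. The sector
    spans ``[start_deg, start_deg + angle_deg)`` and is recorded so report
    quantities can be renormalized by ``360 / (360 - angle)``.
    """
    if not (0.0 <= angle_deg <= 360.0):
        raise ValueError("sector angle must lie in [0, 360]")
    if angle_deg == 0.0:
        return replace(segs, excluded_sector=None)

    src = segs.on_mask if segs.on_mask.data.any() else segs.csf_mask
    centroid, axis = principal_axis(src)
    ref = np.asarray(reference_dir, dtype=float)
    ref = ref - (ref @ axis) * axis
    if np.linalg.norm(ref) < 1e-12:
        ref = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ axis) * axis
    ref /= np.linalg.norm(ref)
    perp = np.cross(axis, ref)

    shape = segs.csf_mask.shape
    idx = np.indices(shape, dtype=np.float64)
    rel = np.stack([idx[i] - centroid[i] for i in range(3)])
    u = np.tensordot(ref, rel, axes=1)
    v = np.tensordot(perp, rel, axes=1)
    az = np.degrees(np.arctan2(v, u)) % 360.0
    inside = ((az - start_deg) % 360.0) < angle_deg

    def cut(m: BinaryMask, lbl: str) -> BinaryMask:
        return m.copy_with(m.data & ~inside, lbl)

    out = replace(
        segs,
        on_mask=cut(segs.on_mask, "on"),
        sas_mask=cut(segs.sas_mask, "sas microstructure"),
        csf_mask=cut(segs.csf_mask, "csf"),
        macro_mask=cut(segs.macro_mask, "macro anatomy") if segs.macro_mask else None,
        excluded_sector=(tuple(centroid), tuple(axis), tuple(ref), float(angle_deg)),
    )
    return out
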