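"""Tile registration by phase correlation and seamless stitching.

Overlapping tiles from a mosaic acquisition carry smooth per-tile background
fields (in-axis acquisition gradients) that make naive averaging show seams.
This module (i) estimates pairwise sub-voxel shifts by windowed phase
correlation on band-passed tiles, (ii) reconciles them into global offsets by
least squares on the shift-difference equations, and (iii) blends
background-corrected tiles with cosine feathering so the result is seam-free.

Translation-only: the tile grid geometry justifies it; no rotation or
deformation is modelled.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .grids import VoxelGrid

__all__ = [
    "OffsetGraph",
    "register_pair",
    "build_offset_graph",
    "resolve_offsets",
    "stitch",
    "max_gradient_jump",
    "write_tiles",
    "read_tiles",
]

_MIN_OVERLAP = 10  # voxels per axis


@dataclass
class OffsetGraph:
    """Pairwise shift measurements between tiles.

    ``edges`` holds ``(tile_a, tile_b, shift, confidence)`` where ``shift``
    is the estimated global offset of ``tile_b`` minus that of ``tile_a``.
    """

    n_tiles: int
    edges: list[tuple[int, int, np.ndarray, float]] = field(default_factory=list)

    def add(self, a: int, b: int, shift, confidence: float) -> None:
        self.edges.append((a, b, np.asarray(shift, dtype=float), float(confidence)))


def _band_pass(vol: np.ndarray) -> np.ndarray:
    """Suppress the lowest-frequency octave (smooth backgrounds) and taper.

    Registration must not lock onto per-tile background gradients; removing
    a heavily smoothed version of the signal leaves the structural content
    that is common between overlapping tiles.
    """
    v = vol.astype(np.float64)
    sigma = max(2.0, min(v.shape) / 8.0)
    v = v - ndimage.gaussian_filter(v, sigma, mode="nearest")
    for ax, n in enumerate(v.shape):
        win = np.hanning(n) if n > 1 else np.ones(1)
        shape = [1, 1, 1]
        shape[ax] = n
        v = v * win.reshape(shape)
    return v


def _parabolic_offset(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if denom >= -1e-12:  # flat or non-concave: no refinement
        return 0.0
    off = 0.5 * (ym - yp) / denom
    return float(np.clip(off, -0.5, 0.5))


def register_pair(
    tile_a: VoxelGrid,
    tile_b: VoxelGrid,
    nominal_shift,
    search_halfwidth: int = 8,
) -> tuple[np.ndarray, float]:
    """Estimate the shift of ``tile_b`` relative to ``tile_a``.

    ``nominal_shift`` is the expected offset of b minus offset of a (voxels).
    The residual from the nominal is found as the phase-correlation peak
    within ``+-search_halfwidth`` voxels, then refined to sub-voxel accuracy
    by a separable 3-point parabolic fit. Ties between equal integer peaks
    break toward the smaller shift magnitude, then lexicographically.

    Returns ``(shift, confidence)`` with confidence the normalized
    correlation peak height in [0, 1].
    """
    nominal = np.asarray(np.round(nominal_shift), dtype=int)
    a = np.asarray(tile_a.data, dtype=np.float64)
    b = np.asarray(tile_b.data, dtype=np.float64)

    # overlap of b placed at `nominal` inside a's frame
    lo = np.maximum(nominal, 0)
    hi = np.minimum(np.array(a.shape), nominal + np.array(b.shape))
    if np.any(hi - lo < _MIN_OVERLAP):
        raise ValueError(
            f"overlap {tuple(hi - lo)} under the nominal shift is below the "
            f"{_MIN_OVERLAP}-voxel minimum"
        )
    sub_a = a[tuple(slice(l, h) for l, h in zip(lo, hi))]
    sub_b = b[tuple(slice(l - n, h - n) for l, h, n in zip(lo, hi, nominal))]
    if sub_a.std() == 0 or sub_b.std() == 0:
        raise ValueError("flat overlap region: content is unregistrable")

    fa = sp_fft.fftn(_band_pass(sub_a))
    fb = sp_fft.fftn(_band_pass(sub_b))
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    cross /= np.maximum(mag, 1e-12 * mag.max() + 1e-300)
    corr = sp_fft.ifftn(cross).real

    # residual r satisfies sub_b(x) ~ sub_a(x + r): peak of corr at +r (wrapped)
    shape = np.array(corr.shape)
    hw = np.minimum(search_halfwidth, (shape - 1) // 2)
    offsets = [np.arange(-h, h + 1) for h in hw]
    idx = np.ix_(*[off % n for off, n in zip(offsets, shape)])
    window = corr[idx]
    peak_val = window.max()
    cand = np.argwhere(window == peak_val)
    residuals = np.array([[offsets[ax][c[ax]] for ax in range(3)] for c in cand])
    order = np.lexsort((residuals[:, 2], residuals[:, 1], residuals[:, 0],
                        (residuals**2).sum(axis=1)))
    res_int = residuals[order[0]]

    # separable parabolic sub-voxel refinement around the integer peak
    res = res_int.astype(float)
    centre = tuple(res_int % shape)
    for ax in range(3):
        if shape[ax] < 3:
            continue
        im = list(centre)
        ip = list(centre)
        im[ax] = (centre[ax] - 1) % shape[ax]
        ip[ax] = (centre[ax] + 1) % shape[ax]
        delta = _parabolic_offset(corr[tuple(im)], corr[tuple(centre)], corr[tuple(ip)])
        res[ax] += delta

    confidence = float(np.clip(peak_val, 0.0, 1.0))
    return nominal.astype(float) + res, confidence


def build_offset_graph(
    tiles: list[tuple[VoxelGrid, tuple[int, int, int]]],
    search_halfwidth: int = 8,
) -> OffsetGraph:
    """Register every overlapping tile pair using nominal offsets as priors."""
    graph = OffsetGraph(n_tiles=len(tiles))
    for i in range(len(tiles)):
        ti, oi = tiles[i]
        for j in range(i + 1, len(tiles)):
            tj, oj = tiles[j]
            nominal = np.subtract(oj, oi)
            lo = np.maximum(nominal, 0)
            hi = np.minimum(np.array(ti.shape), nominal + np.array(tj.shape))
            if np.any(hi - lo < _MIN_OVERLAP):
                continue
            shift, conf = register_pair(ti, tj, nominal, search_halfwidth)
            graph.add(i, j, shift, conf)
    return graph


def resolve_offsets(graph: OffsetGraph, weight_by_confidence: bool = True) -> np.ndarray:
    """Global per-tile offsets from pairwise shifts, tile 0 pinned at origin.

    Solves the overdetermined system ``offset[b] - offset[a] = shift_ab`` in
    the least-squares sense, per axis, optionally weighting rows by edge
    confidence.
    """
    n = graph.n_tiles
    if n == 0:
        return np.zeros((0, 3))
    adj = [[] for _ in range(n)]
    for a, b, _, _ in graph.edges:
        adj[a].append(b)
        adj[b].append(a)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) < n:
        missing = sorted(set(range(n)) - seen)
        raise ValueError(f"offset graph is disconnected; unreachable tiles: {missing}")

    rows = len(graph.edges) + 1
    A = np.zeros((rows, n))
    rhs = np.zeros((rows, 3))
    w = np.ones(rows)
    for k, (a, b, shift, conf) in enumerate(graph.edges):
        A[k, a] = -1.0
        A[k, b] = 1.0
        rhs[k] = shift
        if weight_by_confidence:
            w[k] = max(conf, 1e-3)
    A[-1, 0] = 1.0  # pin tile 0
    w[-1] = 1e3
    Aw = A * w[:, None]
    sol, *_ = np.linalg.lstsq(Aw, rhs * w[:, None], rcond=None)
    return sol


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

_N_BG_TERMS = 10  # quadratic polynomial in 3 variables


def _bg_basis(zz: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Quadratic polynomial basis evaluated at (normalized) coordinates."""
    one = np.ones_like(zz)
    return np.stack([one, zz, yy, xx, zz * yy, zz * xx, yy * xx,
                     zz**2, yy**2, xx**2], axis=-1)


def _fit_backgrounds(
    tiles: list[VoxelGrid],
    offsets: np.ndarray,
    out_shape: tuple[int, int, int],
    max_samples_per_pair: int = 8192,
) -> list[np.ndarray]:
    """Jointly fit per-tile low-order backgrounds from overlap differences.

    In overlap regions the structural signal cancels, so the difference of
    two tiles observes the difference of their backgrounds exactly. A single
    least squares over all pairs recovers per-tile quadratic coefficients up
    to a volume-wide common field, which no local measurement can identify;
    the gauge is fixed by pinning tile 0 and then re-centring on the
    across-tile mean, i.e. the estimated backgrounds are unbiased relative
    to their ensemble average.
    """
    n = len(tiles)
    scale = np.maximum(np.array(out_shape, dtype=float), 1.0)
    rows_A = []
    rows_y = []
    ioff = np.round(offsets).astype(int)
    for i in range(n):
        for j in range(i + 1, n):
            lo = np.maximum(ioff[i], ioff[j])
            hi = np.minimum(ioff[i] + np.array(tiles[i].shape),
                            ioff[j] + np.array(tiles[j].shape))
            if np.any(hi - lo <= 0):
                continue
            zz, yy, xx = [np.arange(l, h) for l, h in zip(lo, hi)]
            step = max(1, int(round((zz.size * yy.size * xx.size
                                     / max_samples_per_pair) ** (1 / 3))))
            zz, yy, xx = zz[::step], yy[::step], xx[::step]
            Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
            di = tiles[i].data[Z - ioff[i][0], Y - ioff[i][1], X - ioff[i][2]]
            dj = tiles[j].data[Z - ioff[j][0], Y - ioff[j][1], X - ioff[j][2]]
            basis = _bg_basis(Z / scale[0], Y / scale[1], X / scale[2]).reshape(-1, _N_BG_TERMS)
            block = np.zeros((basis.shape[0], n * _N_BG_TERMS))
            block[:, i * _N_BG_TERMS:(i + 1) * _N_BG_TERMS] = basis
            block[:, j * _N_BG_TERMS:(j + 1) * _N_BG_TERMS] = -basis
            rows_A.append(block)
            rows_y.append((di - dj).ravel())
    if not rows_A:
        return [np.zeros(_N_BG_TERMS) for _ in range(n)]
    # gauge rows: pin tile 0's background to zero
    gauge = np.zeros((_N_BG_TERMS, n * _N_BG_TERMS))
    gauge[:, :_N_BG_TERMS] = np.eye(_N_BG_TERMS)
    A = np.vstack(rows_A + [gauge])
    y = np.concatenate(rows_y + [np.zeros(_N_BG_TERMS)])
    coeffs, *_ = np.linalg.lstsq(A, y, rcond=None)
    per_tile = coeffs.reshape(n, _N_BG_TERMS)
    per_tile = per_tile - per_tile.mean(axis=0)  # re-centre the common gauge
    return [per_tile[i] for i in range(n)]


def _feather_weight(shape: tuple[int, int, int], ramp: int) -> np.ndarray:
    """Separable cosine ramp: 1 in the interior, smooth decay to the edges."""
    ws = []
    for n in shape:
        d = np.minimum(np.arange(n) + 0.5, n - 0.5 - np.arange(n))
        t = np.clip(d / max(ramp, 1), 0.0, 1.0)
        ws.append(np.sin(0.5 * math.pi * t) ** 2 + 1e-6)
    return ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]


def stitch(
    tiles: list[tuple[VoxelGrid, tuple[int, int, int]]] | list[VoxelGrid],
    resolved_offsets: np.ndarray | None = None,
    correct_background: bool = True,
    target_voxel_size_um: float | None = None,
) -> VoxelGrid:
    """Blend tiles into one seamless volume at their resolved offsets.

    Per-tile quadratic backgrounds are jointly estimated from overlap
    differences and subtracted; background-corrected tiles are then combined
    with cosine-feathered weights sized to the overlap, so the blend is
    continuous across seams. Tiles with a coarser voxel size than
    ``target_voxel_size_um`` are resampled trilinearly onto the fine grid
    first. Fractional offsets are honoured by trilinear resampling.
    """
    if resolved_offsets is None:
        grids = [t[0] if isinstance(t, tuple) else t for t in tiles]
        resolved_offsets = np.array(
            [t[1] if isinstance(t, tuple) else t.origin for t in tiles], dtype=float
        )
    else:
        grids = [t[0] if isinstance(t, tuple) else t for t in tiles]
        resolved_offsets = np.asarray(resolved_offsets, dtype=float)
    if not grids:
        raise ValueError("no tiles to stitch")

    vs = target_voxel_size_um or min(g.voxel_size_um for g in grids)
    resampled: list[VoxelGrid] = []
    for g in grids:
        if abs(g.voxel_size_um - vs) > 1e-9:
            factor = g.voxel_size_um / vs
            data = ndimage.zoom(g.data.astype(np.float64), factor, order=1)
            resampled.append(VoxelGrid(data, voxel_size_um=vs, origin=g.origin))
        else:
            resampled.append(g)
    grids = resampled

    ioff = np.round(resolved_offsets).astype(int)
    frac = resolved_offsets - ioff  # in [-0.5, 0.5)
    shifted = []
    for g, f in zip(grids, frac):
        if np.any(np.abs(f) > 1e-6):
            shifted.append(ndimage.shift(g.data.astype(np.float64), f, order=1,
                                         mode="nearest"))
        else:
            shifted.append(np.asarray(g.data, dtype=np.float64))
    ioff = ioff - ioff.min(axis=0)

    out_shape = tuple((ioff + [g.shape for g in grids]).max(axis=0))
    cover = np.zeros(out_shape, dtype=bool)
    for g, o in zip(grids, ioff):
        cover[o[0]:o[0] + g.shape[0], o[1]:o[1] + g.shape[1], o[2]:o[2] + g.shape[2]] = True
    if not cover.all():
        missing = np.argwhere(~cover)
        raise ValueError(
            f"tiles leave {len(missing)} voxels uncovered, e.g. near "
            f"{tuple(missing[0])}..{tuple(missing[-1])}"
        )

    vgrids = [VoxelGrid(d, voxel_size_um=vs) for d in shifted]
    if correct_background and len(vgrids) > 1:
        bg_coeffs = _fit_backgrounds(vgrids, ioff.astype(float), out_shape)
    else:
        bg_coeffs = [np.zeros(_N_BG_TERMS)] * len(vgrids)

    # ramp length from the observed overlaps
    ramps = []
    for i in range(len(vgrids)):
        for j in range(i + 1, len(vgrids)):
            lo = np.maximum(ioff[i], ioff[j])
            hi = np.minimum(ioff[i] + np.array(vgrids[i].shape),
                            ioff[j] + np.array(vgrids[j].shape))
            if np.all(hi - lo > 0):
                ramps.append(int((hi - lo).min()))
    ramp = max(2, min(ramps) // 2) if ramps else 2

    scale = np.maximum(np.array(out_shape, dtype=float), 1.0)
    acc = np.zeros(out_shape, dtype=np.float64)
    wacc = np.zeros(out_shape, dtype=np.float64)
    for g, o, c in zip(vgrids, ioff, bg_coeffs):
        sl = tuple(slice(o[ax], o[ax] + g.shape[ax]) for ax in range(3))
        zz = np.arange(o[0], o[0] + g.shape[0]) / scale[0]
        yy = np.arange(o[1], o[1] + g.shape[1]) / scale[1]
        xx = np.arange(o[2], o[2] + g.shape[2]) / scale[2]
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        bg = _bg_basis(Z, Y, X) @ c
        w = _feather_weight(g.shape, ramp)
        acc[sl] += w * (g.data - bg)
        wacc[sl] += w
    return VoxelGrid(acc / wacc, voxel_size_um=vs)


def max_gradient_jump(volume: VoxelGrid, reference: VoxelGrid | None = None) -> float:
    """Largest voxel-to-voxel jump, optionally in excess of a reference signal.

    With a reference (e.g. the gradient-free source volume), structure edges
    cancel and the metric isolates seam and background discontinuities.
    """
    d = np.asarray(volume.data, dtype=np.float64)
    if reference is not None:
        d = d - np.asarray(reference.data, dtype=np.float64)
    jump = 0.0
    for ax in range(3):
        jump = max(jump, float(np.abs(np.diff(d, axis=ax)).max()))
    return jump


def write_tiles(tiles, directory) -> None:
    """Per-tile TIFFs plus a plain-text layout file (id, z, y, x)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "layout.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tile_id", "z", "y", "x"])
        for k, (tile, off) in enumerate(tiles):
            name = f"tile_{k:04d}.tif"
            tile.write_tiff(directory / name)
            writer.writerow([name, *off])


def read_tiles(directory) -> list[tuple[VoxelGrid, tuple[int, int, int]]]:
    directory = Path(directory)
    tiles = []
    with open(directory / "layout.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            grid = VoxelGrid.read_tiff(directory / row["tile_id"])
            tiles.append((grid, (int(row["z"]), int(row["y"]), int(row["x"]))))
    return tiles
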