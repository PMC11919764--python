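"""Voxel-space operations: filtering, normalization, model-to-map
synthesis, difference mapping, pose-driven subvolume averaging with
FSC, and template map-back.

All grids are ZYX-ordered float arrays carried by
:class:`~coatlattice.pose_io.DensityMap`; rotations follow the pose
convention of :mod:`coatlattice.rotations` (R maps particle-local to
world coordinates) and act about the geometric box center with
trilinear interpolation, which is adequate at the 12-25 A scales these
analyses run at.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .particles import ParticleSet
from .pose_io import AtomSet, DensityMap

__all__ = [
    "FscCurve",
    "lowpass",
    "normalize_map",
    "model_to_map",
    "difference_map",
    "average_subvolumes",
    "fsc",
    "map_back",
    "rotate_grid",
]

_FLIP = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)  # xyz <-> zyx


def rotate_grid(grid, matrix_xyz, offset_xyz=None, order=1, output_shape=None):
    """Resample ``out(v) = grid(M v + t)`` about the box center.

    ``matrix_xyz`` and ``offset_xyz`` are expressed in (x, y, z)
    coordinates; the ZYX storage order is handled here.  Values
    sampled outside the source grid are 0.
    """
    m_idx = _FLIP @ np.asarray(matrix_xyz, float) @ _FLIP
    out_shape = grid.shape if output_shape is None else tuple(output_shape)
    c_out = (np.array(out_shape) - 1) / 2.0
    c_in = (np.array(grid.shape) - 1) / 2.0
    t = np.zeros(3) if offset_xyz is None else _FLIP @ np.asarray(offset_xyz, float)
    shift = c_in + t - m_idx @ c_out
    return ndimage.affine_transform(
        grid, m_idx, offset=shift, output_shape=out_shape, order=order,
        mode="constant", cval=0.0, prefilter=order > 1,
    ).astype(np.float32)


def lowpass(dmap: DensityMap, resolution: float, soft_edge: int = 3) -> DensityMap:
    """Fourier low-pass to ``resolution`` (A) with a raised-cosine
    edge of ``soft_edge`` Fourier pixels ending at the cutoff.

    The DC term is untouched, so the map mean is preserved.
    """
    if resolution < 2 * dmap.voxel_size:
        raise ValueError(
            f"resolution {resolution} A is beyond Nyquist ({2 * dmap.voxel_size} A)"
        )
    g = dmap.grid
    freqs = [np.fft.fftfreq(s, d=dmap.voxel_size) for s in g.shape[:-1]]
    freqs.append(np.fft.rfftfreq(g.shape[-1], d=dmap.voxel_size))
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    k = np.sqrt(kz**2 + ky**2 + kx**2)
    f_cut = 1.0 / resolution
    width = soft_edge / (g.shape[0] * dmap.voxel_size)
    if width <= 0:
        filt = (k <= f_cut).astype(float)
    else:
        lo = f_cut - width
        filt = 0.5 * (1 + np.cos(np.pi * np.clip((k - lo) / width, 0.0, 1.0)))
        filt[k <= lo] = 1.0
        filt[k >= f_cut] = 0.0
    out = np.fft.irfftn(np.fft.rfftn(g) * filt, s=g.shape, axes=(0, 1, 2))
    return DensityMap(out.astype(np.float32), dmap.voxel_size, dmap.origin.copy())


def normalize_map(dmap: DensityMap) -> DensityMap:
    """Rescale to mean 0, sd 1 over the full (unmasked) box."""
    g = dmap.grid.astype(np.float64)
    sd = g.std()
    if sd == 0:
        raise ValueError("constant map cannot be normalized")
    out = (g - g.mean()) / sd
    return DensityMap(out.astype(np.float32), dmap.voxel_size, dmap.origin.copy())


def model_to_map(
    atoms: AtomSet,
    voxel_size: float,
    box,
    resolution: float = 2.0,
    origin=None,
) -> DensityMap:
    """Simulated density: one isotropic Gaussian per atom with
    sigma = 0.225 * resolution and amplitude = atom weight (the common
    simulated-map convention).

    ``box`` is (nx, ny, nz) voxels.  When ``origin`` is omitted the
    box is centered on the atom centroid.  Atoms outside the box are
    an error (their density would be clipped).
    """
    box = np.asarray(box, int)
    pos = atoms.positions
    if origin is None:
        origin = pos.mean(axis=0) - (box - 1) / 2.0 * voxel_size
    origin = np.asarray(origin, float)
    vox = (pos - origin) / voxel_size
    outside = np.any((vox < 0) | (vox > box - 1), axis=1)
    if np.any(outside):
        raise ValueError(f"{int(outside.sum())} atoms fall outside the requested box")
    sigma_vox = 0.225 * resolution / voxel_size
    reach = max(2, int(np.ceil(4 * sigma_vox)))
    grid = np.zeros((box[2], box[1], box[0]), dtype=np.float64)
    for (vx, vy, vz), w in zip(vox, atoms.weights):
        x0, x1 = max(0, int(vx) - reach), min(box[0], int(vx) + reach + 2)
        y0, y1 = max(0, int(vy) - reach), min(box[1], int(vy) + reach + 2)
        z0, z1 = max(0, int(vz) - reach), min(box[2], int(vz) + reach + 2)
        gx = np.exp(-((np.arange(x0, x1) - vx) ** 2) / (2 * sigma_vox**2))
        gy = np.exp(-((np.arange(y0, y1) - vy) ** 2) / (2 * sigma_vox**2))
        gz = np.exp(-((np.arange(z0, z1) - vz) ** 2) / (2 * sigma_vox**2))
        grid[z0:z1, y0:y1, x0:x1] += w * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return DensityMap(grid.astype(np.float32), voxel_size, origin)


def difference_map(
    observed: DensityMap,
    reference: DensityMap,
    threshold: float = 3.0,
    min_voxels: int = 10,
    annotated_sites=None,
) -> tuple[DensityMap, pd.DataFrame]:
    """Normalized difference observed - reference with a report of
    positive residual blobs (unmodelled density).

    Both maps are normalized to mean 0 / sd 1 first; blobs are
    26-connected components of voxels above ``threshold`` (sd units)
    with at least ``min_voxels`` voxels.  The report gives each blob's
    centroid (A), peak (sd units), volume (voxels) and, when
    ``annotated_sites`` (n, 3 A) are supplied, the distance from the
    centroid to each site.
    """
    if observed.grid.shape != reference.grid.shape:
        raise ValueError("grid shape mismatch between observed and reference")
    if abs(observed.voxel_size - reference.voxel_size) > 1e-6 * observed.voxel_size:
        raise ValueError("voxel size mismatch between observed and reference")
    diff = normalize_map(observed).grid - normalize_map(reference).grid
    out = DensityMap(diff, observed.voxel_size, observed.origin.copy())
    above = diff > threshold
    labels, n_blobs = ndimage.label(above, structure=np.ones((3, 3, 3)))
    rows = []
    sites = None if annotated_sites is None else np.atleast_2d(np.asarray(annotated_sites, float))
    if n_blobs:
        volumes = ndimage.sum_labels(np.ones_like(diff), labels, index=range(1, n_blobs + 1))
        coms = ndimage.center_of_mass(diff, labels, index=range(1, n_blobs + 1))
        peaks = ndimage.maximum(diff, labels, index=range(1, n_blobs + 1))
        for bid, (vol, com, peak) in enumerate(zip(volumes, coms, peaks), start=1):
            if vol < min_voxels:
                continue
            centroid = observed.origin + np.array([com[2], com[1], com[0]]) * observed.voxel_size
            row = {
                "blob_id": bid,
                "x": centroid[0],
                "y": centroid[1],
                "z": centroid[2],
                "peak_sd": float(peak),
                "volume_voxels": int(vol),
            }
            if sites is not None:
                for si, site in enumerate(sites):
                    row[f"dist_site_{si}"] = float(np.linalg.norm(centroid - site))
            rows.append(row)
    report = pd.DataFrame(rows)
    return out, report


def average_subvolumes(
    volumes: list[DensityMap],
    poses: ParticleSet,
    symmetry: str = "C1",
) -> tuple[DensityMap, tuple[DensityMap, DensityMap]]:
    """Average subvolumes under their particle poses.

    Each volume is resampled by the inverse particle rotation (and
    inverse translation, taken from the pose position as an offset
    from the box center in A), so that true poses reconstruct the
    reference the volumes were rendered from.  ``symmetry="C2"``
    additionally averages in a 180 deg in-plane rotated copy.  Returns
    the average plus odd/even half-maps.
    """
    if len(volumes) != len(poses):
        raise ValueError("one pose per volume required")
    if not volumes:
        raise ValueError("no volumes to average")
    shape = volumes[0].grid.shape
    if any(v.grid.shape != shape for v in volumes):
        raise ValueError("subvolume size mismatch")
    if not (shape[0] == shape[1] == shape[2]):
        raise ValueError("subvolumes must be cubic")
    voxel = volumes[0].voxel_size
    mats = poses.matrices()
    offsets = poses.positions / voxel  # A -> voxels
    halves = [np.zeros(shape, dtype=np.float64), np.zeros(shape, dtype=np.float64)]
    counts = [0, 0]
    for i, vol in enumerate(volumes):
        back = rotate_grid(vol.grid, mats[i], offset_xyz=offsets[i])
        halves[i % 2] += back
        counts[i % 2] += 1
    half_maps = []
    for h, c in zip(halves, counts):
        arr = (h / c if c else h).astype(np.float32)
        if symmetry.upper() == "C2":
            arr = 0.5 * (arr + rotate_grid(arr, _rot_z_180()))
        elif symmetry.upper() != "C1":
            raise ValueError(f"unsupported symmetry {symmetry!r}")
        half_maps.append(DensityMap(arr, voxel, volumes[0].origin.copy()))
    total = (halves[0] + halves[1]) / len(volumes)
    total = total.astype(np.float32)
    if symmetry.upper() == "C2":
        total = 0.5 * (total + rotate_grid(total, _rot_z_180()))
    avg = DensityMap(total, voxel, volumes[0].origin.copy())
    return avg, (half_maps[0], half_maps[1])


def _rot_z_180():
    return np.diag([-1.0, -1.0, 1.0])


@dataclass
class FscCurve:
    """Fourier shell correlation between two maps."""

    frequencies: np.ndarray  # 1/A, increasing
    correlations: np.ndarray
    threshold: float
    resolution: float  # A at the first crossing of the threshold

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, float)
        self.correlations = np.asarray(self.correlations, float)


def fsc(a: DensityMap, b: DensityMap, threshold: float = 0.143) -> FscCurve:
    """Correlation per spherical Fourier shell; resolution reported at
    the first crossing below ``threshold`` (linearly interpolated),
    or at Nyquist if the curve never drops below it."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("grid shape mismatch")
    if not (a.grid.shape[0] == a.grid.shape[1] == a.grid.shape[2]):
        raise ValueError("cubic grids required")
    n = a.grid.shape[0]
    fa = np.fft.fftn(a.grid)
    fb = np.fft.fftn(b.grid)
    k = np.fft.fftfreq(n) * n
    kz, ky, kx = np.meshgrid(k, k, k, indexing="ij", sparse=True)
    shell = np.rint(np.sqrt(kz**2 + ky**2 + kx**2)).astype(int)
    n_shells = n // 2
    num = np.zeros(n_shells)
    den_a = np.zeros(n_shells)
    den_b = np.zeros(n_shells)
    flat = shell.ravel()
    valid = flat < n_shells
    np.add.at(num, flat[valid], np.real(fa.ravel()[valid] * np.conj(fb.ravel()[valid])))
    np.add.at(den_a, flat[valid], np.abs(fa.ravel()[valid]) ** 2)
    np.add.at(den_b, flat[valid], np.abs(fb.ravel()[valid]) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(den_a * den_b)
    corr = np.nan_to_num(corr[1:], nan=0.0)  # drop the DC shell
    freqs = np.arange(1, n_shells) / (n * a.voxel_size)
    res = 2 * a.voxel_size  # Nyquist
    below = np.where(corr < threshold)[0]
    if below.size:
        i = below[0]
        if i == 0:
            res = 1.0 / freqs[0]
        else:
            f0, f1 = freqs[i - 1], freqs[i]
            c0, c1 = corr[i - 1], corr[i]
            fx = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0) if c0 != c1 else f1
            res = 1.0 / fx
    return FscCurve(freqs, corr, threshold, float(res))


def map_back(
    template: DensityMap,
    pset: ParticleSet,
    out_box,
    voxel_size: float,
    origin=(0.0, 0.0, 0.0),
) -> DensityMap:
    """Place a (low-pass-filtered) average back at every particle pose
    inside a tomogram-sized box; overlapping placements sum.

    Placements falling (partly) outside the box are clipped with a
    warning reporting the count.
    """
    out_box = np.asarray(out_box, int)  # (nx, ny, nz)
    origin = np.asarray(origin, float)
    out = np.zeros((out_box[2], out_box[1], out_box[0]), dtype=np.float64)
    tshape = np.array(template.grid.shape)[::-1]  # (nx, ny, nz)
    mats = pset.matrices()
    pos_vox = (pset.positions - origin) / voxel_size
    n_clipped = 0
    half = (tshape - 1) / 2.0
    for i in range(len(pset)):
        rotated = rotate_grid(template.grid, mats[i].T)
        corner = pos_vox[i] - half  # float xyz corner in out grid
        base = np.floor(corner).astype(int)
        frac = corner - base
        if np.any(frac > 1e-6):
            rotated = ndimage.shift(rotated, shift=frac[::-1], order=1, mode="constant")
        lo = base
        hi = base + tshape
        if np.any(lo < 0) or np.any(hi > out_box):
            n_clipped += 1
        src_lo = np.maximum(0, -lo)
        src_hi = tshape - np.maximum(0, hi - out_box)
        dst_lo = np.maximum(0, lo)
        dst_hi = np.minimum(out_box, hi)
        if np.any(src_hi <= src_lo):
            continue
        out[dst_lo[2]:dst_hi[2], dst_lo[1]:dst_hi[1], dst_lo[0]:dst_hi[0]] += rotated[
            src_lo[2]:src_hi[2], src_lo[1]:src_hi[1], src_lo[0]:src_hi[0]
        ]
    if n_clipped:
        warnings.warn(f"{n_clipped} placements extended outside the box and were clipped")
    return DensityMap(out.astype(np.float32), voxel_size, origin)
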