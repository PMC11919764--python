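"""File I/O: particle pose tables (STAR and legacy whitespace tables),
density volumes (MRC2014) and atomic coordinates (PDB).

Two pose-table dialects are supported:

``star``
    A single ``data_`` block with one loop of particle rows, in the
    style written by subtomogram-averaging packages.  Coordinates may
    be stored either in Angstrom (this package's native output) or in
    voxels; pass ``coords_in_voxels=True`` together with a pixel size
    to convert on read.

``legacy_table``
    The 35-column whitespace table used by legacy dynamics/averaging
    workflows: columns 7-9 carry the Euler triple (rot, tilt, psi) and
    columns 24-26 the x, y, z coordinates in voxels.  Column 1 is the
    particle tag, column 10 the cross-correlation score, column 20 the
    tomogram index and column 21 the object index.  All other columns
    are preserved opaquely and written back unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import mrcfile
import numpy as np
import pandas as pd

from .particles import CORE_COLUMNS, ParticleSet
from .rotations import normalize_euler

__all__ = [
    "DensityMap",
    "AtomSet",
    "read_particles",
    "write_particles",
    "read_map",
    "write_map",
    "read_atoms",
]


# ---------------------------------------------------------------------------
# voxel data


@dataclass
class DensityMap:
    """A voxel grid in ZYX storage order with isotropic voxel size (A)
    and a world-frame origin (A, position of voxel [0,0,0])."""

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError(f"grid must be 3D with every axis >= 2, got {self.grid.shape}")
        if not (self.voxel_size > 0 and np.isfinite(self.voxel_size)):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self):
        return self.grid.shape

    def copy(self):
        return DensityMap(self.grid.copy(), self.voxel_size, self.origin.copy())


@dataclass
class AtomSet:
    """Point-mass atoms: positions in Angstrom plus per-atom weights."""

    positions: np.ndarray
    elements: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.weights is None:
            self.weights = np.ones(len(self.positions))
        self.weights = np.asarray(self.weights, float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom positions")
        if np.any(self.weights <= 0):
            raise ValueError("atom weights must be positive")

    def __len__(self):
        return len(self.positions)


# ---------------------------------------------------------------------------
# STAR dialect

_STAR_TAGS = {
    "particle_id": "_coatParticleId",
    "tomo_id": "_rlnTomoName",
    "object_id": "_coatObjectId",
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "z": "_rlnCoordinateZ",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "score": "_rlnAutopickFigureOfMerit",
    "class_label": "_rlnClassNumber",
    "layer": "_coatLayer",
}
_MANDATORY = ["x", "y", "z", "rot", "tilt", "psi"]


def read_particles(
    path,
    dialect: str = "star",
    *,
    pixel_size: float | None = None,
    coords_in_voxels: bool | None = None,
) -> ParticleSet:
    """Read a particle pose table.

    ``pixel_size`` (A/voxel) is stored as metadata; when
    ``coords_in_voxels`` is true the coordinates are multiplied by it
    on read.  The legacy table dialect always stores voxel coordinates,
    so there ``coords_in_voxels`` defaults to True; for STAR it
    defaults to False (Angstrom on disk).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "star":
        df, px_from_file = _read_star(path)
        in_voxels = bool(coords_in_voxels)
    elif dialect == "legacy_table":
        df, px_from_file = _read_legacy(path), None
        in_voxels = True if coords_in_voxels is None else coords_in_voxels
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    px = pixel_size if pixel_size is not None else (px_from_file or 1.0)
    if in_voxels:
        df[["x", "y", "z"]] = df[["x", "y", "z"]].astype(float) * px
    rot, tilt, psi = normalize_euler(
        df["rot"].to_numpy(float), df["tilt"].to_numpy(float), df["psi"].to_numpy(float)
    ) if len(df) else (np.array([]),) * 3
    df["rot"], df["tilt"], df["psi"] = rot, tilt, psi
    return ParticleSet(df, pixel_size=px)


def _read_star(path: Path):
    try:
        doc = gemmi.cif.read_file(str(path))
    except Exception as exc:  # pragma: no cover - gemmi message passthrough
        raise ValueError(f"malformed STAR file {path}: {exc}") from exc
    if len(doc) == 0:
        raise ValueError(f"{path}: no data_ block")
    block = doc[0]
    tag_to_col = {v: k for k, v in _STAR_TAGS.items()}
    cols = {}
    found_tags = []
    for tag, col in tag_to_col.items():
        loop_col = block.find_loop(tag)
        vals = list(loop_col)
        if vals:
            cols[col] = vals
            found_tags.append(tag)
    missing = [_STAR_TAGS[c] for c in _MANDATORY if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    n = len(cols["x"])
    df = pd.DataFrame(index=range(n))
    for col, vals in cols.items():
        if len(vals) != n:
            raise ValueError(f"{path}: ragged column {col}")
        df[col] = vals
    for col in ("x", "y", "z", "rot", "tilt", "psi", "score"):
        if col in df:
            df[col] = _to_float(df[col], path)
    if "particle_id" not in df:
        df["particle_id"] = np.arange(n, dtype=np.int64)
    else:
        df["particle_id"] = df["particle_id"].astype(np.int64)
    if "object_id" in df:
        df["object_id"] = df["object_id"].astype(np.int64)
    if "class_label" in df:
        df["class_label"] = pd.to_numeric(df["class_label"], errors="coerce").astype("Int64")
    px = None
    px_col = list(block.find_loop("_rlnImagePixelSize"))
    if px_col:
        px = float(px_col[0])
    return df, px


def _to_float(series, path):
    try:
        return series.astype(float)
    except ValueError:
        vals = pd.to_numeric(series, errors="coerce")
        bad = int(np.where(vals.isna())[0][0])
        raise ValueError(f"{path}: malformed numeric value in row {bad}") from None


def write_particles(pset: ParticleSet, path, dialect: str = "star") -> None:
    """Write a pose table; ``read_particles`` inverts it (STAR stores
    Angstrom coordinates, the legacy table voxel coordinates)."""
    path = Path(path)
    if dialect == "star":
        _write_star(pset, path)
    elif dialect == "legacy_table":
        _write_legacy(pset, path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def _write_star(pset: ParticleSet, path: Path) -> None:
    df = pset.df
    tags, fmts, cols = [], [], []
    for col in CORE_COLUMNS:
        tags.append(_STAR_TAGS[col])
        cols.append(col)
    tags.append("_rlnImagePixelSize")
    lines = ["", "data_particles", "", "loop_"]
    lines += [f"{t} #{i + 1}" for i, t in enumerate(tags)]
    for _, row in df.iterrows():
        fields = []
        for col in cols:
            v = row[col]
            if col in ("x", "y", "z", "rot", "tilt", "psi", "score"):
                fields.append(f"{float(v):.6f}")
            elif col == "class_label":
                fields.append("-1" if pd.isna(v) else str(int(v)))
            else:
                fields.append(str(v))
        fields.append(f"{pset.pixel_size:.6f}")
        lines.append(" ".join(fields))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# legacy 35-column table

_LEGACY_NCOL = 35
# 1-based column indices
_LEGACY_MAP = {1: "particle_id", 10: "score", 20: "tomo_idx", 21: "object_id",
               7: "rot", 8: "tilt", 9: "psi", 24: "x", 25: "y", 26: "z"}


def _read_legacy(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        raw_lines = [ln for ln in fh if ln.strip()]
    for i, ln in enumerate(raw_lines):
        parts = ln.split()
        if len(parts) < 26:
            raise ValueError(f"{path}: row {i + 1} has {len(parts)} columns, expected >= 26")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise ValueError(f"{path}: malformed numeric value in row {i + 1}") from None
    if not rows:
        return pd.DataFrame(columns=["particle_id", "x", "y", "z", "rot", "tilt", "psi"])
    width = max(len(r) for r in rows)
    arr = np.zeros((len(rows), max(width, _LEGACY_NCOL)))
    for i, r in enumerate(rows):
        arr[i, : len(r)] = r
    df = pd.DataFrame()
    for idx, col in _LEGACY_MAP.items():
        df[col] = arr[:, idx - 1]
    df["particle_id"] = df["particle_id"].astype(np.int64)
    df["object_id"] = df["object_id"].astype(np.int64)
    df["tomo_id"] = "tomo_" + df.pop("tomo_idx").astype(int).astype(str)
    opaque = [k for k in range(1, arr.shape[1] + 1) if k not in _LEGACY_MAP]
    for k in opaque:
        df[f"legacy_c{k}"] = arr[:, k - 1]
    return df


def _write_legacy(pset: ParticleSet, path: Path) -> None:
    df = pset.df
    n = len(df)
    arr = np.zeros((n, _LEGACY_NCOL))
    for idx, col in _LEGACY_MAP.items():
        if col == "tomo_idx":
            arr[:, idx - 1] = [
                int(t.rsplit("_", 1)[-1]) if t.rsplit("_", 1)[-1].isdigit() else 0
                for t in df["tomo_id"]
            ]
        elif col in ("x", "y", "z"):
            arr[:, idx - 1] = df[col].to_numpy(float) / pset.pixel_size
        else:
            arr[:, idx - 1] = df[col].to_numpy(float)
    for col in df.columns:
        if col.startswith("legacy_c"):
            k = int(col[len("legacy_c"):])
            if k <= _LEGACY_NCOL:
                arr[:, k - 1] = df[col].to_numpy(float)
    with open(path, "w") as fh:
        for row in arr:
            # 8 decimals: voxel-valued coordinates stay < 1e-6 A after
            # conversion at typical pixel sizes
            fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# MRC volumes


def read_map(path) -> DensityMap:
    """Read an MRC2014 volume; voxel size must be isotropic."""
    path = Path(path)
    try:
        with mrcfile.open(str(path), permissive=False) as mrc:
            grid = np.asarray(mrc.data, dtype=np.float32)
            vx = mrc.voxel_size
            voxels = np.array([float(vx.x), float(vx.y), float(vx.z)])
            origin = np.array(
                [float(mrc.header.origin.x), float(mrc.header.origin.y), float(mrc.header.origin.z)]
            )
    except ValueError as exc:
        raise ValueError(f"corrupt or invalid MRC file {path}: {exc}") from exc
    if voxels.max() - voxels.min() > 1e-4 * voxels.max():
        raise ValueError(f"{path}: anisotropic voxel sizes {voxels} are not supported")
    return DensityMap(grid, float(voxels[0]), origin)


def write_map(dmap: DensityMap, path) -> None:
    """Write mode-2 (float32) MRC2014."""
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(dmap.grid.astype(np.float32))
        mrc.voxel_size = dmap.voxel_size
        mrc.header.origin.x = dmap.origin[0]
        mrc.header.origin.y = dmap.origin[1]
        mrc.header.origin.z = dmap.origin[2]


# ---------------------------------------------------------------------------
# PDB


def read_atoms(path) -> AtomSet:
    """Read ATOM/HETATM records from a PDB file (first model)."""
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    positions, elements = [], []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                for atom in res:
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    el = atom.element.name if atom.element.name != "X" else atom.name.strip()[:1]
                    elements.append(el)
    if not positions:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return AtomSet(np.array(positions), elements)
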