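"""The particle-pose table: the central object of the pipeline.

A :class:`ParticleSet` wraps a pandas DataFrame with one row per
particle.  Positions are always in Angstroms in a right-handed world
frame; orientations are canonical ZYZ Euler triples (see
:mod:`coatlattice.rotations`).  Extra columns (ground-truth labels,
provenance, legacy-table payload) ride along untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rotations import euler_to_matrix, normalize_euler

#: Columns every ParticleSet carries, in canonical order.
CORE_COLUMNS = [
    "particle_id",
    "tomo_id",
    "object_id",
    "x",
    "y",
    "z",
    "rot",
    "tilt",
    "psi",
    "score",
    "class_label",
    "layer",
]

LAYERS = ("inner", "vertex", "rod", "other")


@dataclass
class ParticleSet:
    """Table of particle poses plus pixel-size metadata (Angstrom/voxel)."""

    df: pd.DataFrame
    pixel_size: float = 1.0

    def __post_init__(self):
        self.df = _with_core_columns(self.df)
        self.validate()

    def validate(self):
        if self.pixel_size <= 0 or not np.isfinite(self.pixel_size):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        ids = self.df["particle_id"].to_numpy()
        if len(ids) != len(np.unique(ids)):
            dupes = self.df["particle_id"][self.df["particle_id"].duplicated()].tolist()
            raise ValueError(f"duplicate particle_id values: {sorted(set(dupes))[:10]}")
        pos = self.positions
        if pos.size and not np.all(np.isfinite(pos)):
            bad = np.where(~np.isfinite(pos).all(axis=1))[0]
            raise ValueError(f"non-finite positions at rows {bad[:10].tolist()}")

    def __len__(self):
        return len(self.df)

    @property
    def positions(self):
        """(n, 3) array of x, y, z in Angstrom."""
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def eulers(self):
        """(n, 3) array of (rot, tilt, psi) in degrees."""
        return self.df[["rot", "tilt", "psi"]].to_numpy(dtype=float)

    def matrices(self):
        """(n, 3, 3) stack of local-to-world rotation matrices."""
        e = self.eulers
        if len(e) == 0:
            return np.zeros((0, 3, 3))
        return euler_to_matrix(e[:, 0], e[:, 1], e[:, 2])

    def normals(self):
        """(n, 3) particle z-axes in world coordinates."""
        return self.matrices()[:, :, 2] if len(self) else np.zeros((0, 3))

    def copy(self):
        return ParticleSet(self.df.copy(), self.pixel_size)

    def select(self, mask_or_ids):
        """Subset by boolean mask (row-aligned) or iterable of particle ids."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            sub = self.df[arr]
        else:
            sub = self.df[self.df["particle_id"].isin(arr)]
        return ParticleSet(sub.reset_index(drop=True), self.pixel_size)

    def transformed(self, rotation=None, translation=None):
        """Apply one global rigid transform to every pose.

        ``rotation`` is a world-frame 3x3 matrix Q; positions become
        Q p + t and orientations Q R (local frames ride along).
        """
        out = self.df.copy()
        pos = self.positions
        if rotation is not None:
            Q = np.asarray(rotation, float)
            pos = pos @ Q.T
            mats = Q[None] @ self.matrices()
            from .rotations import matrix_to_euler

            rot, tilt, psi = matrix_to_euler(mats)
            out[["rot", "tilt", "psi"]] = np.c_[rot, tilt, psi]
        if translation is not None:
            pos = pos + np.asarray(translation, float)
        out[["x", "y", "z"]] = pos
        return ParticleSet(out, self.pixel_size)


def _with_core_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    defaults = {
        "tomo_id": "tomo_0",
        "object_id": 0,
        "score": 0.0,
        "class_label": pd.NA,
        "layer": "other",
    }
    for col in ("particle_id", "x", "y", "z", "rot", "tilt", "psi"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    df["particle_id"] = df["particle_id"].astype(np.int64)
    df["object_id"] = df["object_id"].astype(np.int64)
    df["tomo_id"] = df["tomo_id"].astype(str)
    df["layer"] = df["layer"].astype(str)
    df["score"] = df["score"].astype(float)
    extra = [c for c in df.columns if c not in CORE_COLUMNS]
    return df[CORE_COLUMNS + extra].reset_index(drop=True)


def particle_set(
    positions,
    eulers,
    *,
    layer="other",
    object_id=0,
    tomo_id="tomo_0",
    score=0.0,
    pixel_size=1.0,
    start_id=0,
    extra: dict | None = None,
) -> ParticleSet:
    """Convenience constructor from position/orientation arrays."""
    pos = np.atleast_2d(np.asarray(positions, float))
    eul = np.atleast_2d(np.asarray(eulers, float))
    if pos.shape[0] != eul.shape[0]:
        raise ValueError("positions and eulers length mismatch")
    n = pos.shape[0]
    rot, tilt, psi = (
        normalize_euler(eul[:, 0], eul[:, 1], eul[:, 2]) if n else (np.array([]),) * 3
    )
    data = {
        "particle_id": np.arange(start_id, start_id + n, dtype=np.int64),
        "tomo_id": tomo_id,
        "object_id": object_id,
        "x": pos[:, 0] if n else [],
        "y": pos[:, 1] if n else [],
        "z": pos[:, 2] if n else [],
        "rot": rot,
        "tilt": tilt,
        "psi": psi,
        "score": score,
        "layer": layer,
    }
    df = pd.DataFrame(data)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return ParticleSet(df, pixel_size)


def concat(sets: list[ParticleSet], reindex=False) -> ParticleSet:
    """Concatenate particle sets; ids must stay unique unless reindex."""
    if not sets:
        raise ValueError("nothing to concatenate")
    px = sets[0].pixel_size
    df = pd.concat([s.df for s in sets], ignore_index=True)
    if reindex:
        df["particle_id"] = np.arange(len(df), dtype=np.int64)
    return ParticleSet(df, px)
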