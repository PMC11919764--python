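"""End-to-end pipeline orchestration.

A YAML config drives simulate -> clean -> neighbors -> alpha ->
correlation -> (optional) registration on a synthetic vesicle
population, writing TSV tables, an optional scatter figure, and a
machine-readable JSON summary carrying the seed, the config hash and
every parameter, so a rerun with the same config is bit-identical for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lattice import (
    RegionMask,
    lattice_clean,
    layer_registration,
    neighbor_cloud,
    alpha_diameter_correlation,
    ring_masks,
    vertex_alpha,
)
from .membrane import fit_sphere
from .particles import ParticleSet, concat
from .synthetic import CageParams, CorruptionModel, corrupt, make_cage, make_two_layer

DEFAULTS = {
    "seed": 0,
    "n_vesicles": 12,
    "diameter_min": 600.0,
    "diameter_max": 2400.0,
    "edge_length": 300.0,
    "five_way_fraction": 0.1,
    "pos_noise_sd": 5.0,
    "ang_noise_sd": 2.0,
    "junk_fraction": 0.0,
    "r_max": 450.0,
    "l_window": [0.7, 1.3],  # in units of edge_length
    "opposite_tol": 30.0,
    "clean_k_min": 3,
    "registration": None,  # or {"registered": bool, "offset": [x,y,z], "region_radius": r}
    "make_figures": False,
    "out_dir": "coatlattice_out",
}


@dataclass
class PipelineConfig:
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**DEFAULTS, **user}
        return cls(merged)

    def hash(self):
        blob = json.dumps(self.params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the summary dict (also written to ``summary.json``).
    """
    p = config.params
    out = Path(out_dir if out_dir is not None else p["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(p["seed"])
    rng = np.random.default_rng(seed)
    L = float(p["edge_length"])

    # --- simulate a vesicle population
    diam = np.linspace(p["diameter_min"], p["diameter_max"], int(p["n_vesicles"]))
    vertex_sets, diameters = [], {}
    next_id = 0
    for obj, D in enumerate(diam):
        res = make_cage(
            CageParams(
                diameter=float(D),
                edge_length=L,
                five_way_fraction=float(p["five_way_fraction"]),
                seed=seed + obj,
                center=(2.5 * float(diam.max()) * obj, 0.0, 0.0),
            )
        )
        df = res.vertices.df.copy()
        df["object_id"] = obj
        df["particle_id"] += next_id
        next_id = int(df["particle_id"].max()) + 1
        vs = ParticleSet(df, res.vertices.pixel_size)
        model = CorruptionModel(
            pos_noise_sd=float(p["pos_noise_sd"]),
            ang_noise_sd=float(p["ang_noise_sd"]),
            junk_fraction=float(p["junk_fraction"]),
            seed=seed + 10_000 + obj,
        )
        vs = corrupt(vs, model, res.surface)
        vertex_sets.append(vs)
        next_id = int(vs.df["particle_id"].max()) + 1
        fitted = fit_sphere(vs.positions[(vs.df["truth"] == "true").to_numpy()])
        diameters[obj] = fitted.diameter
    particles = concat(vertex_sets, reindex=True)

    # --- clean
    window = (p["l_window"][0] * L, p["l_window"][1] * L)
    mean_dip = np.mean(
        [np.degrees(np.arcsin(min(1.0, L / d))) for d in diameters.values()]
    )
    z_exp = -L * np.sin(np.radians(mean_dip))
    # expected neighbor sites: the first-shell ring at spacing L,
    # dipped below the tangent plane by the population-mean curvature
    masks = ring_masks(L, z_exp)
    cleaned = lattice_clean(particles, masks, r_max=float(p["r_max"]), k_min=int(p["clean_k_min"]))

    # --- neighbors + alpha + correlation
    cloud = neighbor_cloud(cleaned, float(p["r_max"]))
    cloud.to_csv(out / "neighbor_cloud.tsv", sep="\t", index=False)
    table = vertex_alpha(
        cleaned, window, float(p["opposite_tol"]), diameters=diameters, cloud=cloud
    )
    table.to_csv(out / "vertex_alpha.tsv", sep="\t", index=False)
    per_obj = table.groupby("object_id").agg(alpha=("alpha", "mean"), diameter=("diameter", "first")).reset_index()
    r, pval, slope, intercept = alpha_diameter_correlation(table)

    summary = {
        "tool": "coatlattice",
        "version": __version__,
        "seed": seed,
        "config_hash": config.hash(),
        "parameters": p,
        "n_particles_simulated": int(len(particles)),
        "n_particles_cleaned": int(len(cleaned)),
        "diameters": {str(k): float(v) for k, v in diameters.items()},
        "alpha": {
            "n_vertices": int(len(table)),
            "mean": float(table["alpha"].mean()),
            "min": float(table["alpha"].min()),
            "max": float(table["alpha"].max()),
        },
        "alpha_diameter_correlation": {
            "pearson_r": r,
            "p_two_tailed": pval,
            "slope": slope,
            "intercept": intercept,
        },
    }

    # --- optional two-layer registration stage
    if p.get("registration"):
        reg_cfg = p["registration"]
        offset = reg_cfg.get("offset", [0.0, 0.0, -120.0])
        radius = float(reg_cfg.get("region_radius", 80.0))
        verts, inner = make_two_layer(
            CageParams(diameter=float(diam[-1]), edge_length=L, seed=seed + 77),
            registered=bool(reg_cfg.get("registered", True)),
            inner_offset=tuple(offset),
        )
        region = RegionMask(label="below_vertex", shape="ball", center=offset, radius=radius)
        report = layer_registration(verts, inner, region, r_max=2.0 * abs(offset[2]))
        summary["registration"] = {
            "n_selected": report.n_selected,
            "uniformity_p": report.uniformity_p,
            "verdict": report.verdict,
        }

    if p.get("make_figures"):
        _figure_alpha_vs_diameter(per_obj, slope, intercept, out / "alpha_vs_diameter.png")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _figure_alpha_vs_diameter(per_obj, slope, intercept, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(per_obj["diameter"], per_obj["alpha"], s=12, c="k")
    xs = np.linspace(per_obj["diameter"].min(), per_obj["diameter"].max(), 50)
    ax.plot(xs, slope * xs + intercept, "r-", lw=1)
    ax.set_xlabel("vesicle diameter (Å)")
    ax.set_ylabel("vertex angle α (°)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
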