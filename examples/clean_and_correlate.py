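"""A miniature end-to-end analysis of a noisy vesicle population.

Simulates 12 coated vesicles (diameters 600-2400 A) with positional
and angular picking noise plus 20% junk particles, cleans the table by
neighbor analysis against the expected first-shell ring, fits each
membrane sphere, and correlates the per-vesicle vertex angle with the
fitted diameter - the coat-flexibility analysis in miniature.
"""

import numpy as np

from coatlattice import (
    CageParams,
    CorruptionModel,
    ParticleSet,
    alpha_diameter_correlation,
    concat,
    corrupt,
    fit_sphere,
    lattice_clean,
    make_cage,
    vertex_alpha,
)
from coatlattice.lattice import ring_masks

L = 300.0
diameters_true = np.linspace(600.0, 2400.0, 12)
sets, fitted = [], {}
next_id = 0
for obj, D in enumerate(diameters_true):
    cage = make_cage(CageParams(diameter=float(D), edge_length=L, seed=obj,
                                center=(7500.0 * obj, 0.0, 0.0)))
    df = cage.vertices.df.copy()
    df["particle_id"] += next_id
    df["object_id"] = obj
    noisy = corrupt(
        ParticleSet(df),
        CorruptionModel(pos_noise_sd=5.0, ang_noise_sd=2.0, junk_fraction=0.2, seed=100 + obj),
        cage.surface,
    )
    next_id = int(noisy.df["particle_id"].max()) + 1
    sets.append(noisy)
    true_mask = (noisy.df["truth"] == "true").to_numpy()
    fitted[obj] = fit_sphere(noisy.positions[true_mask]).diameter
population = concat(sets)

dip = float(np.mean([np.arcsin(L / d) for d in fitted.values()]))
cleaned = lattice_clean(population, ring_masks(L, -L * np.sin(dip)), r_max=450.0, k_min=3)
n_junk = (population.df["truth"] == "junk").sum()
print(f"simulated {len(population)} particles ({n_junk} junk), kept {len(cleaned)} after cleaning")

table = vertex_alpha(cleaned, diameters=fitted)
# median per vesicle: the handful of junk survivors carry random
# orientations and hence wild alpha values
per_vesicle = table.groupby("object_id").agg(
    alpha=("alpha", "median"), diameter=("diameter", "first")
).reset_index()
r, p, slope, intercept = alpha_diameter_correlation(per_vesicle)
lo, hi = table["alpha"].quantile([0.05, 0.95])
print(f"alpha (5-95%) spans {lo:.1f} - {hi:.1f} deg "
      f"across fitted diameters {min(fitted.values()):.0f} - {max(fitted.values()):.0f} A")
print(f"alpha vs diameter: Pearson r = {r:.3f}, two-tailed p = {p:.2e}")
# A strong positive r: the cage opens up on larger (flatter) vesicles,
# i.e. the outer coat geometry tracks membrane curvature.
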