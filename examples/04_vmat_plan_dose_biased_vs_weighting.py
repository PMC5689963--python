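"""VMAT arc dose with fluence-map-biased vs conventional FM weighting.

Both estimators target the same dose; the biased method draws each
particle's control point from the per-pixel CPDF of the fluence maps (via
a numerical inverse look-up table), so far fewer particles land under
closed MLC leaves and the target uncertainty is reached with fewer
histories.
"""

from psrdose import build_toy_beam_model
from psrdose.plan import calculate_plan_dose, particle_reduction_factor
from psrdose.synthetic import make_toy_vmat_arc
from psrdose.transport import DoseGrid

model = build_toy_beam_model(8, 6)
arc = make_toy_vmat_arc(36, "sweeping_slit", "uniform", rng_seed=1)
phantom = DoseGrid.empty((-7.5, -7.5, 92.5), (0.5, 0.5, 0.5), (30, 30, 30))

results = {}
for method in ("biased", "weighting"):
    res = calculate_plan_dose(arc, model, phantom, method=method,
                              target_uncertainty=2.0, rng_seed=7,
                              batch_particles=50_000,
                              max_particles=20_000_000)
    results[method] = res
    print(f"{method:9s}: {res.n_particles:>9,} particles to reach "
          f"{res.uncertainty_percent:.2f}% average uncertainty; "
          f"less-useful (closed-leaf) particles: "
          f"{res.less_useful.percent:.2f}%")

factor = particle_reduction_factor(results["weighting"].n_particles,
                                   results["biased"].n_particles)
print(f"particle reduction factor: {factor:.1f}x "
      "(biased sampling avoids control points whose leaves are closed "
      "at the particle's position)")
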