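"""Maximum-consistency MILP: how many deregulation calls can co-hold?

A planted truth with one contradictory pair on a fully coupled reaction
pair: the MILP can satisfy all planted calls plus exactly one side of the
pair, so two alternative optima exist and the consensus (their
intersection) is exactly the planted set.
"""

from fluxshift import (
    ToySpec, apply_environment, brute_force_consistency, build_remi_problem,
    enumerate_alternative_optima, make_toy_model, plant_flux_truth,
)
from fluxshift.synthetic import default_environment

model = apply_environment(make_toy_model(ToySpec(seed=3)), default_environment())
truth = plant_flux_truth(model, seed=3, n_up=3, n_down=2, n_contradictory=2)
print("planted:", {r: c.direction for r, c in truth.planted.items()})
print("contradictory pair:", {r: c.direction for r, c in truth.contradictory.items()})

joint = build_remi_problem(model, truth.dereg)
sol = enumerate_alternative_optima(joint)
print(f"M_max = {sol.m_max} of {len(truth.dereg)} calls simultaneously satisfiable")
print(f"{len(sol.alternative_sets)} alternative optimal sets; "
      f"consensus = {sorted(sol.consensus)}")

bf_m, bf_sets = brute_force_consistency(model, truth.dereg)
print(f"brute-force oracle agrees: M_max {bf_m}, "
      f"families identical: {set(sol.alternative_sets) == set(bf_sets)}")
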