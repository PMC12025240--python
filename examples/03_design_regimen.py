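"""Design dose regimens against a synthetic PK/PD cohort: generate the
cohort, wrap the efficacy/safety/cost objectives as a three-objective
problem, optimize, and print representative trade-offs.

Run:  python examples/03_design_regimen.py
"""

import numpy as np

from moswo import MOSWOConfig, run
from moswo.therapy import (
    CohortModel,
    ObjectiveWeights,
    RegimenVector,
    generate_cohort,
    regimen_problem,
)

# 300 synthetic patients: dose grid -> exposure (Cmax/AUC, lognormal
# inter-patient variability) -> saturating Emax response and graded toxicity
cohort = generate_cohort(300, seed=7)
print(cohort.to_frame().head())

weights = ObjectiveWeights()  # E_max=100%, S_max=grade 3, C_max=5000
problem = regimen_problem(cohort, weights)
result = run(problem, MOSWOConfig(pop_size=100, budget=10_000, seed=1))

model = CohortModel.fit(cohort)
members = sorted(result.archive.members, key=lambda m: m.objectives[2])
print(f"\n{len(members)} non-dominated regimens; three representative picks:")
for label, ind in [("cheapest", members[0]),
                   ("mid-cost", members[len(members) // 2]),
                   ("most effective", min(members, key=lambda m: m.objectives[0]))]:
    reg = RegimenVector.from_array(ind.position)
    ae, ar, c = ind.objectives
    print(f"  {label:15s} doseA={reg.dose_a:6.1f}mg q{reg.interval:4.1f}h "
          f"doseB={reg.dose_b:6.1f}mg x{reg.duration:4.1f}wk | "
          f"efficacy={weights.e_max - ae:5.1f}% "
          f"expected tox grade={ar:.2f} cost={c:7.0f} "
          f"TI={model.therapeutic_index(reg):.2f}")
# each line is one Pareto-optimal trade-off: no other found regimen is
# simultaneously more effective, safer and cheaper
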