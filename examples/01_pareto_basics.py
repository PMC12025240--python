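"""Dominance, non-dominated sorting, crowding and the bounded archive on a
tiny hand-made population.

Run:  python examples/01_pareto_basics.py
"""

import numpy as np

from moswo import Archive, Individual, crowding_distance, non_dominated_sort, update_archive

# six candidate solutions of a bi-objective minimization problem
objectives = [
    (0.1, 0.9), (0.5, 0.5), (0.9, 0.1),   # a trade-off front
    (0.6, 0.6), (0.95, 0.3), (0.3, 0.95),  # dominated by the front above
]
population = [
    Individual(position=np.zeros(1), objectives=np.array(f)) for f in objectives
]

fronts = non_dominated_sort(population)
print("fronts (index sets, best first):", fronts)
# the first front holds the mutually non-dominated trade-offs; every member
# of a later front is dominated by someone in an earlier one

crowding_distance([population[i] for i in fronts[0]])
for i in fronts[0]:
    print(f"  member {i} objectives={objectives[i]} crowding={population[i].crowding}")
# boundary solutions carry infinite crowding so extreme trade-offs survive
# any truncation; interior members score the normalized gap to neighbours

archive = Archive(capacity=4)
update_archive(archive, population)
print("archive after update (only non-dominated kept):")
print(archive.objectives())
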