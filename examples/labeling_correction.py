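"""Forward-map and invert oligomer fractions under incomplete labeling.

Takes published-style corrected fractions, predicts the step histogram an
experiment would observe at 80% labeling efficiency, and inverts it back.
"""
import numpy as np

from smbleach import (
    LabelingModel,
    OligomerDistribution,
    forward_observe,
    group_fractions,
    particle_to_entity,
    solve_corrected_fractions,
)

model = LabelingModel(p_f=0.8, n_max=5)

low = np.array([0.435, 0.467, 0.049, 0.049, 0.0])    # low-density composition
high = np.array([0.133, 0.560, 0.135, 0.172, 0.0])   # high-density composition

for label, x in [("low density", low), ("high density", high / high.sum())]:
    r = forward_observe(x, model)
    result = solve_corrected_fractions(r, model)
    entity = group_fractions(particle_to_entity(OligomerDistribution(x)))
    print(f"{label}:")
    print(f"  true particle fractions : {np.round(x, 3)}")
    print(f"  expected step fractions : {np.round(r, 3)}  (one-step {100*r[0]:.1f}%)")
    print(f"  re-inverted fractions   : {np.round(result.corrected.fractions, 3)}"
          f"  (residual {result.residual_norm:.1e})")
    print(f"  entity shares           : monomer {100*entity['monomer']:.0f}%,"
          f" dimer {100*entity['dimer']:.0f}%, oligomer {100*entity['oligomer']:.0f}%")
    print()

print("The one-step share drops from ~57% to ~32% between the two compositions;")
print("entity shares weight particles by subunit count, so oligomers dominate at")
print("high density even though dimers are the most common particle.")
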