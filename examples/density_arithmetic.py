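"""Receptor-density bookkeeping: particles per area to receptors per cell.

Converts measured particle densities to per-cell receptor counts for a
COS-7-sized cell, and expresses expression levels as fold ratios over
physiological reference densities.
"""
from smbleach import fold_over_reference, receptors_per_cell

for density in (0.22, 0.42, 0.76):
    n = receptors_per_cell(density, cell_area=1200.0)
    print(f"{density:.2f} particles/um^2 x 1200 um^2 -> ~{n} receptors per cell")

print()
bmax = 7.0  # pmol/mg at the low expression level
for name, ref in [("hepatocyte membranes", 0.5), ("mesangial cells", 3.06)]:
    fold = fold_over_reference(bmax, ref)
    print(f"B_max {bmax} pmol/mg over {name} ({ref} pmol/mg): {fold:.1f}-fold")
print("The low expression condition sits roughly 2- to 14-fold above")
print("physiological receptor densities, depending on the reference tissue.")
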