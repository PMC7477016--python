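"""F_ST drift calibration: realized differentiation vs split depth.

Splits one population of N_e = 500 in two, lets them drift 10 / 50 / 100
generations, and measures genome-wide Weir-Cockerham F_ST (ratio of sums).
"""

import numpy as np

import sweepscan as sw
from sweepscan.experiments import fst_at_split

print("split (gens)  t/2Ne    realized F_ST (3 replicates)")
for t in (10, 50, 100):
    vals = [fst_at_split(seed=10 * t + k, split_gens=t) for k in range(3)]
    print(f"{t:>11}   {t/1000:.3f}    {np.mean(vals):.4f}  (each: "
          + ", ".join(f"{v:.4f}" for v in vals) + ")")

print(
    "\nUnder pure drift F_ST grows ~ t/2N_e, so these splits walk through the\n"
    "0.008-0.025 differentiation band seen between closely and distantly\n"
    "related East African populations, and beyond it at the deepest split."
)
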