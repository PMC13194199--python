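"""Determine complex stoichiometry by the method of continuous variation.

Nine equal-molarity mixtures (volume ratios 1:9 ... 9:1, i.e. ligand mole
fractions 0.1 ... 0.9, refined here to a 0.05 grid) are generated under an
M + 2L <=> ML2 mass-action equilibrium at constant total concentration.
The response maximum locates the complex composition: an ML2 species
peaks at x = 2/3.
"""

import numpy as np

from platequant.datasets import load_job_mixture_fractions
from platequant.simulate import EquilibriumSpec, job_series
from platequant.stoichiometry import locate_maximum, ratio_from_xmax

print("bundled mixture fractions:", np.round(load_job_mixture_fractions(), 2))

fractions = np.round(np.arange(0.10, 0.901, 0.05), 10)
series = job_series(EquilibriumSpec(n=2, log_K=8.0, total_conc=0.1), fractions)

loc = locate_maximum(series)  # quadratic vertex around the top grid point
result = ratio_from_xmax(loc.x_max)
print(f"response maximum at x = {result.x_max:.3f} ({loc.method})")
print(f"ligand:metal ratio = {result.continuous_ratio:.2f} -> {result.label}")
# x_max near 2/3 identifies the 2:1 ligand-to-metal complex; a maximum at
# 0.5 would instead indicate a 1:1 species.
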