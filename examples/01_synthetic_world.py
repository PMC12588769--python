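"""Generate a synthetic landscape with known suitability ground truth.

Builds the default 64 km x 64 km world (1 km cells): autocorrelated climate
coupled to elevation through a lapse rate, derived topography, a
forest/cropland/other land cover, and a human-footprint analog; then the
true suitability surface (unimodal in warm-month temperature and terrain
ruggedness, increasing in 7 km forest fraction) and 150 presence points
sampled from it.
"""

import numpy as np

from scalesdm import (
    SyntheticTruth,
    generate_landscape,
    sample_occurrences,
    true_suitability,
)

truth = SyntheticTruth(seed=0)
stack = generate_landscape(64, 64, 1000.0, truth)
suit = true_suitability(stack, truth)
occ = sample_occurrences(suit, 150, seed=1, elevation=stack["elevation"])

print("layers:", ", ".join(stack.names))
for name in ("elevation", "tem_warmmon", "annualprec", "footprint"):
    vals = stack[name].valid_values()
    print(f"  {name:12s} mean={vals.mean():8.1f}  sd={vals.std():7.1f}")
lc = stack["landcover"].values
print(f"land cover: {100*(lc==1).mean():.0f}% forest, {100*(lc==2).mean():.0f}% cropland")
print(f"true suitability: mean={suit.valid_values().mean():.2f} "
      f"(in [0,1]; higher = better habitat)")
elevs = [r.elevation for r in occ]
print(f"{len(occ)} presences, mean elevation {np.mean(elevs):.0f} m")
print("Presences concentrate where aggregated forest cover is high and the")
print("warm-month temperature sits near the species' 15 degC optimum.")
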