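"""Fit the five-learner AUC-weighted ensemble and evaluate it.

Cross-validates GLM, GAM, a MaxEnt-style L1 model, random forest and
gradient boosting on presence vs pseudo-absence features at the chosen
scales, keeps every run with held-out AUC > 0.7, weights them by AUC, and
reports held-out metrics, the maxSSS binarization threshold, and variable
importances.
"""

import numpy as np

from scalesdm import (
    BaseLearnerSpec,
    SyntheticTruth,
    auc,
    boyce_index,
    build_ensemble,
    cross_validate,
    generate_landscape,
    sample_occurrences,
    sample_pseudo_absences,
    true_suitability,
    tss_max,
    variable_importance,
)
from scalesdm.ensemble import ALGORITHMS, runs_table
from scalesdm.projection import extract_features

truth = SyntheticTruth(seed=0)
stack = generate_landscape(64, 64, 1000.0, truth)
suit = true_suitability(stack, truth)
occ = sample_occurrences(suit, 150, seed=1)
cells = occ.cells(stack.reference)
pa = sample_pseudo_absences(stack.reference, 2000, cells, n_sets=1, seed=2)[0]

radii = {"forest": 7.0, "tem_warmmon": 6.0, "tri": 8.0, "footprint": 1.0}
Xp, okp = extract_features(stack, radii, cells)
Xb, okb = extract_features(stack, radii, pa.cells)
Xp, Xb = Xp[okp].reset_index(drop=True), Xb[okb].reset_index(drop=True)

runs = cross_validate(Xp, [Xb], [BaseLearnerSpec(a) for a in ALGORITHMS],
                      k=5, repeats=2, seed=3)
table = runs_table(runs)
print("mean held-out AUC per algorithm:")
print(table.groupby("algorithm")["auc"].mean().round(3).to_string())

model = build_ensemble(runs, Xp, Xb)
s_pos, s_neg = model.predict(Xp), model.predict(Xb)
tss, _ = tss_max(s_pos, s_neg)
print(f"\nensemble: {len(model.members)}/{len(runs)} members above AUC 0.7")
print(f"  AUC={auc(s_pos, s_neg):.3f}  TSS={tss:.3f}  "
      f"Boyce={boyce_index(s_pos, s_neg):.3f}")
print(f"  maxSSS threshold = {model.threshold_maxsss:.3f}")

import pandas as pd

eval_X = pd.concat([Xp, Xb], ignore_index=True)
print("\npermutation importance (1 - |r| between original and permuted predictions):")
for var in model.variable_set:
    print(f"  {var:18s} {variable_importance(model, eval_X, var, seed=4):.3f}")
print("The forest-fraction term generated the strongest true effect, so it")
print("should dominate; AUC/TSS/Boyce are held-in here (cf. CV table above).")
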