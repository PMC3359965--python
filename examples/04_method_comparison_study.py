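"""Scaled-down method-comparison study over part of the model schedule.

Runs the first 8 scheduled models (one density block), fits all three
estimators, and reports how closely each method's f and W summaries track
the generating models, plus the averaged-signal t-scores.  The full
56-model run (``run_simulation_study()`` with defaults, a few minutes)
adds the paired t-tests and correlation tests via ``compare_methods``.
"""

import voxgc as v

res = v.run_simulation_study(model_ids=range(1, 9), T=200, seed=3)
tab = res.table

for stat in ("f", "W"):
    for blk in ("yx", "xy"):
        d_lasso = (tab[f"lasso_{stat}_{blk}"] - tab[f"truth_{stat}_{blk}"]).abs().mean()
        d_pair = (tab[f"pair_{stat}_{blk}"] - tab[f"truth_{stat}_{blk}"]).abs().mean()
        print(f"{stat}_{blk}: mean |est − truth| lasso {d_lasso:.3f}  pairwise {d_pair:.3f}")
# smaller distances mean the estimator tracks the true between-ROI
# connectivity better; LASSO-GC should win in every row.

print("\naveraged-signal t-scores (one value per direction and model):")
print(tab[["model_id", "avg_t_yx", "avg_t_xy"]].to_string(index=False))
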