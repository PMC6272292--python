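"""Does degraded training data help or hurt? A small-scale trend run.

Compares a forest trained on a small clean set against the same forest
trained on clean + degraded data (coordinate jitter on a structural fraction,
label bias + extra noise on an IC50-like fraction), with a linear model as
the control.  Scaled down (2 replicates, 400 clean + 1200 degraded) so it
runs in about a minute; the full-size experiment lives in
vinarf.experiments.low_quality_experiment.
"""

import numpy as np

from vinarf.experiments import low_quality_experiment
from vinarf.models import RFConfig

result = low_quality_experiment(
    seed=5, n_clean=400, n_degraded=1200, n_test=300, n_replicates=2,
    rf_config=RFConfig(n_trees=60, mtry_grid=(2,), seeds=(1, 2, 3)),
)

rf_c = float(np.median(result["rf_clean_rmse"]))
rf_a = float(np.median(result["rf_clean_plus_degraded_rmse"]))
mlr_c = float(np.median(result["mlr_clean_rmse"]))
mlr_a = float(np.median(result["mlr_clean_plus_degraded_rmse"]))
print(f"RF  test RMSE: clean only {rf_c:.3f}  ->  clean+degraded {rf_a:.3f}")
print(f"MLR test RMSE: clean only {mlr_c:.3f}  ->  clean+degraded {mlr_a:.3f}")
print(f"forest helped (not hurt) in {result['rf_not_hurt']} of "
      f"{result['n_replicates']} replicates")
print("(extra volume outweighs the degradation for the forest; the linear"
      " model cannot exploit it)")
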