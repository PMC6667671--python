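"""Three learning scenarios analysed end to end.

Simulates small cohorts under three generative hypotheses — stage-1
noise-reduction only ("identity"), proportional two-stage noise reduction
("contrast"), and no learning ("static") — and runs the block-metric
pipeline plus mixed-model day-trend tests on each.
"""

import pandas as pd

from metavpl import ExperimentConfig, ObserverSpec, simulate_cohort
from metavpl import block_metrics, trend_test

SCENARIOS = {
    "identity": (ObserverSpec.identity_vpl(), ExperimentConfig.identity()),
    "contrast": (ObserverSpec.contrast_vpl(), ExperimentConfig.contrast()),
    "static": (ObserverSpec.static(), ExperimentConfig.identity()),
}

for name, (spec, cfg) in SCENARIOS.items():
    tables, _ = simulate_cohort(12, spec, cfg, seed=11)
    bm = pd.concat([block_metrics(tb, cfg) for tb in tables])
    print(f"\n{name} cohort (12 subjects):")
    for measure in ("threshold", "type1_auc", "type2_auc"):
        r = trend_test(bm, measure)
        tag = "falls" if (r["p"] < 0.05 and r["slope"] < 0) else (
            "rises" if r["p"] < 0.05 else "flat"
        )
        print(f"  {measure:10s}  slope/day {r['slope']:+8.4f}   "
              f"p = {r['p']:.3f}   -> {tag}")

print(
    "\nOnly stage-1 noise reduction (identity) makes metacognitive accuracy"
    " fall while the staircase keeps objective accuracy flat; proportional"
    " two-stage reduction (contrast) keeps both flat; without learning"
    " nothing trends."
)
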