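"""From predicted ages to aging indicators and composite indices.

Biological aging = residual of predicted age on chronological age (positive
means biologically older than expected).  The telomere indicator is the
standardized negated T/S ratio (shorter = older), not age-regressed.  The
composite is the sum of the five z-scored indicators on subjects with all
layers; PC1 is the alternative weighted composite.
"""

import numpy as np
import pandas as pd

from omiclocks import (
    AgingIndicatorSet,
    CohortConfig,
    composite_pc1,
    composite_sum,
    residualize_on_age,
    simulate_cohort,
    simulate_telomere,
    telomere_indicator,
)
from omiclocks.config import LAYERS

cohort, truth = simulate_cohort(CohortConfig(n=4000), seed=3)

# stand-in for clock outputs: noisy predicted ages built from the planted
# deviations (a real run uses crossval_predict_age, see example 02);
# note each stage gets its own seed so random streams never overlap
rng = np.random.default_rng(33)
table = pd.DataFrame(index=cohort.index, columns=list(LAYERS), dtype=float)
for layer in LAYERS[1:]:
    predicted = cohort["age"] + 5 * truth.deviations[layer] + rng.normal(0, 2, len(cohort))
    table[layer] = residualize_on_age(predicted.to_numpy(), cohort["age"].to_numpy())
tl = simulate_telomere(cohort, truth, seed=31)
table.loc[tl.subjects, "telomere"] = telomere_indicator(tl.values.iloc[:, 0])

ind = AgingIndicatorSet(indicators=table)
for layer in LAYERS[1:]:
    r = np.corrcoef(table[layer], cohort["age"])[0, 1]
    print(f"{layer:<14s} cor(indicator, age) = {r:+.1e}  (zero by construction)")

comp_sum = composite_sum(ind)
comp_pc1 = composite_pc1(ind)
print(f"\ncomposite on {len(comp_sum.values)} overlap subjects")
print(f"sum-composite variance: {comp_sum.values.var(ddof=1):.2f} "
      "(~5 for independent unit indicators)")
print("PC1 loadings (unit norm, positive sum; the noisy telomere indicator")
print("barely correlates with the others, so it gets little weight):")
for layer, w in comp_pc1.loadings.items():
    print(f"  {layer:<14s} w = {w:+.3f}")
print(f"leading eigenvalue: {comp_pc1.leading_eigenvalue:.2f}")
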