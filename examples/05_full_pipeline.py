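"""End-to-end run: simulate -> preprocess -> clocks -> composites ->
associations -> permutation FDR, with all artifacts written to ./scratch_run.

Equivalent shell usage:  omiclocks run-all --outdir scratch_run --seed 5
(the CLI uses the full-size default panels; this example shrinks them to
finish in under a minute).
"""

import numpy as np

from omiclocks import (
    ClockConfig,
    CohortConfig,
    FDRConfig,
    LayerSimConfig,
    PipelineConfig,
    run_pipeline,
)

config = PipelineConfig(
    seed=5,
    outdir="scratch_run",
    cohort=CohortConfig(n=400),
    layers={
        "epigenetic": LayerSimConfig(
            name="epigenetic", n_markers=1000, n_informative=100,
            target_r2=0.9, coverage=0.7,
        ),
        "transcriptomic": LayerSimConfig(
            name="transcriptomic", n_markers=500, n_informative=50,
            target_r2=0.55, coverage=0.85,
        ),
        "proteomic": LayerSimConfig(
            name="proteomic", n_markers=171, n_informative=40, target_r2=0.8,
            censor_mode="limit", censor_frac=0.02, coverage=0.85,
        ),
        "metabolomic": LayerSimConfig(
            name="metabolomic", n_markers=231, n_informative=60,
            target_r2=0.52, censor_mode="missing", censor_frac=0.02,
            coverage=0.95,
        ),
    },
    clocks=ClockConfig(
        candidates={
            "epigenetic": [0, 100, 500, 1000],
            "transcriptomic": [50, 200, 500],
            "proteomic": None,
            "metabolomic": None,
        }
    ),
    fdr=FDRConfig(n_permutations=200),
)

result = run_pipeline(config)

print("clock accuracies (out-of-fold cor with age):")
for name, fit in result.clock_fits.items():
    age = result.cohort.loc[fit.oof_predictions.index, "age"]
    r = np.corrcoef(fit.oof_predictions, age)[0, 1]
    print(f"  {name:<14s} r={r:.3f}  (k*={fit.k_star} markers)")

print(f"\ncomposite overlap: {len(result.indicators.overlap_ids)} subjects "
      "(subjects measured on all five layers)")
thr = result.fdr.threshold
print("FDR 5% threshold:", "none" if thr is None else f"p <= {thr:.3g}")
sig = result.associations[result.associations["fdr_significant"] == 1]
print(f"{len(sig)} significant determinant-indicator associations; artifacts "
      "in ./scratch_run")
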