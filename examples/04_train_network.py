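"""Train the 5-5-2 backpropagation ensemble and predict held-out excerpts.

Twenty independently initialized sigmoid networks (5 inputs, 5 hidden, 2
outputs) are trained for 80,000 full-batch epochs at learning rate 0.1 on
8 excerpts (2 per quadrant) and tested on the remaining 4; predictions are
inverse-mapped to the 1-9 rating scale and averaged across networks.
"""

import numpy as np

import physioaffect as pa

design = pa.StudyDesign(seed=42)
trials, ratings = pa.generate_study(design)
features = pa.build_feature_matrix(trials, ratings)

ensemble = pa.run_trials(features, pa.MLPConfig(seed=42))

final = np.array([t.final_mse for t in ensemble.traces])
print(f"converged trials (MSE < 0.02): {sum(t.converged for t in ensemble.traces)}/20")
print(f"final training MSE: median {np.median(final):.5f}, worst {final.max():.5f}")

print("\ntest excerpt   predicted V/A   observed V/A")
for i, e in enumerate(ensemble.test_excerpts):
    pv, pa_ = ensemble.mean_predictions[i]
    ov = features.loc[e, "mean_valence"]
    oa = features.loc[e, "mean_arousal"]
    print(f"  {e:>4}        {pv:.2f} / {pa_:.2f}     {ov:.2f} / {oa:.2f}")
print("\nPer-dimension |predicted - observed| is the error that the "
      "evaluation stage converts to accuracy percentages.")
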