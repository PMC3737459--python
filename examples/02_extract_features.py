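"""Extract the excerpt x feature matrix from raw recordings.

Each trial is reduced to five standardized, baseline-corrected features
(z-units): skin conductance level, heart rate, respiration rate, and
rectified zygomaticus/corrugator EMG; features and ratings are then
averaged over participants, one row per excerpt.
"""

import physioaffect as pa

design = pa.StudyDesign(seed=42)
trials, ratings = pa.generate_study(design)
features = pa.build_feature_matrix(trials, ratings)

print(features.round(3))
print("\nPositive hr rows are excerpts whose music raised heart rate above "
      "baseline (high-arousal quadrants); positive scl/corr rows mark "
      "negative-valence excerpts.")
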