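"""One-call pipeline: simulate, extract, model, evaluate, attribute.

Produces the full report bundle - feature matrix, correlations, stepwise
linear models, network ensemble performance, quadrant means, and the
contribution analysis - and writes features/predictions/errors CSVs plus
report.json when an output directory is given.
"""

from physioaffect.evaluation import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig())  # default design, effects, network

print(f"seed {report['seed']}, config hash {report['config_hash']}")
print(f"network trials converged: {report['nn']['converged_trials']}"
      f"/{report['nn']['n_trials']}")

for model in ("nn", "linear"):
    s = report[model]["summary"]
    print(f"\n{model} performance on the 4 held-out excerpts:")
    for dim in ("valence", "arousal"):
        d = s[dim]
        print(f"  {dim}: mean error {d['mean_error']:.3f} rating units, "
              f"accuracy {d['accuracy_pct']:.2f}%")

print("\nquadrant mean ratings (valence, arousal):")
for q, m in report["quadrant_means"].items():
    print(f"  {q:>9}: {m['mean_valence']:.2f}, {m['mean_arousal']:.2f}")

print("\nAccuracy is 100 - 100 x (mean error / 8), the error expressed as a "
      "share of the 1-9 scale's span.")
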