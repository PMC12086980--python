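"""Screen intervention-level indicators before modelling.

Generates a synthetic dataset, plants a strongly collinear indicator pair,
and runs the two screens: |phi| >= 0.5 (collinearity, inclusive boundary)
and agreement > 80% (near-identical responses, strict boundary).
"""

import numpy as np

from metareg import GeneratorConfig, flag_pairs, generate
from metareg.screening import apply_actions

ds, _ = generate(GeneratorConfig(n_trials=80, seed=5))
frame = ds.indicator_frame()

# plant a near-duplicate of 'school' to show what a flag looks like
rng = np.random.default_rng(0)
noisy_copy = np.where(rng.random(len(frame)) < 0.9, frame["school"], 1 - frame["school"])
frame["school_shadow"] = noisy_copy

report = flag_pairs(frame, actions={("school", "school_shadow"): "merge"})
print(report.to_frame().to_string(index=False))

reduced = apply_actions(frame, report)
print(f"\ncolumns before: {frame.shape[1]}, after actions: {reduced.shape[1]}")
print("merged column present:", "school_or_school_shadow" in reduced.columns)

# Flagged pairs list the correlation and agreement that triggered them; the
# 'merge' action replaces the pair by its logical OR so the model sees one
# indicator carrying both signals.
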