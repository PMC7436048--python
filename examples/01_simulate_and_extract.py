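"""Simulate a small e-nose study and extract curve features.

Builds 3 classes x 20 samples of 8-channel sensor recordings, extracts the
16-features-per-sensor curve descriptor block, and prints the table shape
plus the class means of one informative and one uninformative column.
"""

import numpy as np

from enosefs.synthetic_data import SimulationConfig, make_feature_dataset

config = SimulationConfig(n_classes=3, samples_per_class=20, seed=42)
table = make_feature_dataset(config, scheme="curve", n_interval_values=9)

print(f"feature table: {table.n_samples} samples x {table.n_features} columns")
print(f"informative columns (from class-separated sensors): {table.informative_mask.sum()}")

# column 0 = sensor 0 max response (informative); last sensor is uninformative
informative_col = table.values[:, 0]
noise_col = table.values[:, table.feature_names.index("s7_max_resp")]
for c in range(config.n_classes):
    sel = table.labels == c
    print(
        f"class {c}:  s0_max_resp mean = {informative_col[sel].mean():6.3f}   "
        f"s7_max_resp mean = {noise_col[sel].mean():6.3f}"
    )
print(
    "-> the informative sensor's response grows with the class index; the\n"
    "   uninformative sensor's response does not depend on the class."
)
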