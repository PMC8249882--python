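"""Scanner-noise consistency and sample-size power, at demonstration scale.

The field-strength analog regenerates the same subjects under low
("3T-like") and high ("1.5T-like") noise and correlates their change maps;
the sample-size analog measures how often each metric detects the true
atrophy region as nested subsets grow.
"""

from cortexshift import NoiseSpec
from cortexshift.experiments import (
    ExperimentConfig,
    run_noise_experiment,
    run_samplesize_experiment,
)

df = run_noise_experiment(ExperimentConfig(level=3, n_per_group=4, seed=5))
med = df[["r_thickness", "r_area", "r_volume"]].median().round(3)
print("cross-noise-level consistency (median Pearson r per subject):")
print(f"  area {med['r_area']}, volume {med['r_volume']}, thickness {med['r_thickness']}")
print("  -> surface area is the most noise-robust measure.\n")

cfg = ExperimentConfig(level=3, sample_sizes=(12, 24), replicates=4, seed=6,
                       noise=NoiseSpec.preset("1.5T"))
power = run_samplesize_experiment(cfg)
print("detection power (fraction of replicate subsets with a true-region hit):")
print(power.pivot(index="n", columns="metric", values="power").round(2).to_string())
print("\nVolume, which combines the thickness and area signals, detects the")
print("simulated atrophy at least as often as either component alone.")
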