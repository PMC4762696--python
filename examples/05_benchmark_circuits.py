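"""Spiking benchmark: default vs optimized radii for representation.

Builds a network of D single-dimension spiking LIF ensembles, drives it with
a slowly varying unit vector, and compares the per-step Euclidean decoding
error under the default radius (1) and the optimized radius.  The measured
RMSE ratio feeds the heuristic neuron reduction (MSE ~ 1/N, so an RMSE
factor f permits f^2 fewer neurons).

Scaled for a quick demonstration (3 trials of 2 s); the benchmark protocol
uses more trials and longer signals.
"""

from nefopt import reduced_neuron_count, run_experiment

report = run_experiment(
    "represent", D=64, neurons_per_dim=50, trials=3, duration=2.0,
    seed=0, mode="spiking", include_reduced=False,
)
print("representation of a 64-D unit vector, 50 spiking neurons/dimension:")
print(f"  RMSE default radius (1)        : {report.default_dist.rmse:.4f}")
print(f"  RMSE optimized radius "
      f"({report.optimized_radius:.3f})  : {report.optimized_dist.rmse:.4f}")
print(f"  reduction factor               : {report.reduction_factor:.2f}")
n_red = reduced_neuron_count(50, report.reduction_factor)
print(f"  heuristically reduced neurons  : 50 -> {n_red} per dimension")
# the reduced network holds the default-radius error level with a fraction
# of the neurons; run_experiment(include_reduced=True) simulates it directly
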