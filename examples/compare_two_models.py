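"""Affinity-range agreement between two prediction sets.

Two models predicting the same complexes are compared by the ordinal
distance between their range classes: same range, adjacent, or more than
one range apart.
"""

from wntcrd import (
    AffinityPrediction,
    SyntheticSpec,
    compare_models,
    generate_descriptor_matrix,
    generate_measurements,
    predict_matrix,
    search,
    ModelSearchConfig,
)

spec = SyntheticSpec(m_protein=10, m_lipid=2, noise_sd=0.3, seed=3)
matrix = generate_descriptor_matrix(spec)
measurements, _ = generate_measurements(matrix, spec)

result = search(matrix, measurements, ModelSearchConfig(k=3, n_lipid=1))
top, runner_up = result.candidates[0], result.candidates[1]
records = matrix.records()
preds_a = predict_matrix(top.model, records)
preds_b = predict_matrix(runner_up.model, records)

summary = compare_models(preds_a, preds_b)
print(f"comparing {top.model.name} vs {runner_up.model.name} "
      f"over {summary.n_compared} complexes:")
print(f"  same range      {summary.fraction_same:.0%}")
print(f"  adjacent ranges {summary.fraction_adjacent:.0%}")
print(f"  further apart   {summary.fraction_far:.0%}")
print("\nThe three fractions partition the complexes by how far apart the "
      "two models' ordinal affinity calls are.")
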