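"""AHP weighting: judgment matrices, eigenvector weights, consistency.

Builds the domain-level judgment matrix from the instrument's published
domain weights (patient 0.1976, disease 0.4905, therapeutic 0.3119),
recovers the weights by power iteration, then shows what controlled
inconsistency does to the consistency ratio (CR < 0.1 passes; larger means
the pairwise judgments contradict each other too much to trust).
"""

import numpy as np

from vterisk import aggregate_matrices, matrix_from_weights, principal_weights

weights = [0.1976, 0.4905, 0.3119]
labels = ["patient", "disease", "therapeutic"]

consistent = matrix_from_weights(weights, labels=labels)
res = principal_weights(consistent)
print("consistent ratio matrix:")
print(np.round(consistent.values, 3))
print(f"recovered weights: {np.round(res.weights, 4)}, "
      f"lambda_max = {res.lambda_max:.4f}, CR = {res.cr:.4f}")

for sd in (0.05, 0.2, 0.5):
    noisy = matrix_from_weights(weights, perturbation_sd=sd, seed=1, labels=labels)
    r = principal_weights(noisy)
    verdict = "pass" if r.cr < 0.1 else "FAIL"
    print(f"perturbation sd = {sd}: lambda_max = {r.lambda_max:.4f}, "
          f"CR = {r.cr:.4f} ({verdict}), "
          f"max weight error = {np.max(np.abs(r.weights - weights)):.4f}")

# five experts with independently perturbed judgments, pooled by the
# element-wise geometric mean (preserves reciprocity)
experts = [matrix_from_weights(weights, perturbation_sd=0.3, seed=s, labels=labels)
           for s in range(5)]
pooled = principal_weights(aggregate_matrices(experts))
print(f"geometric-mean pool of 5 noisy experts: weights = "
      f"{np.round(pooled.weights, 4)}, CR = {pooled.cr:.4f}")
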