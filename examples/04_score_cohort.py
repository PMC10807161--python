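"""Score a synthetic patient cohort with the instrument.

Draws 2000 patients with 10% prevalence per indicator (BMI bands sampled
jointly so at most one is present), scores them additively — protective
indicators (Asian population, anticoagulant use) subtract — and prints the
total-score distribution. Raw totals only: clinical risk thresholds are
deliberately out of scope until case data exist to calibrate them.
"""

import numpy as np

from vterisk import CohortModel, load_instrument, score_cohort, score_range, simulate_cohort

spec = load_instrument()
lo, hi = score_range(spec)
print(f"attainable totals: {lo} (all protective) .. {hi} (maximal risk set)")

records = simulate_cohort(CohortModel(n_patients=2000, default_prevalence=0.10, seed=8), spec)
scores = score_cohort(records, spec)

totals = scores["total_score"].to_numpy()
print(f"cohort of {len(scores)}: mean {totals.mean():.2f}, sd {totals.std(ddof=1):.2f}, "
      f"range {totals.min()} .. {totals.max()}")
q = np.percentile(totals, [5, 25, 50, 75, 95]).astype(int)
print(f"percentiles 5/25/50/75/95: {q.tolist()}")
negative = (totals < 0).mean()
print(f"{negative:.1%} of patients net below zero (protective factors dominate)")

one = records[0]
report = score_cohort([one], spec)
present = [i for i, v in one.flags.items() if v]
print(f"\nexample patient {one.patient_id}: present = {present}, "
      f"total = {report['total_score'][0]}")
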