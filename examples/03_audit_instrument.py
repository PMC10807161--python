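"""Audit the packaged 39-indicator VTE risk instrument.

Re-derives every combined weight by the hierarchy product rule and every
integer score by the 100-x-weight rounding rule, and reports the rows of
the published table that cannot be reproduced — they are kept as printed
(the publication is canonical) but flagged, never silently corrected.
"""

from vterisk import audit_instrument, load_instrument

spec = load_instrument()
print(f"{spec.title} (v{spec.version})")
print(f"indicators: {len(spec.indicators)}, "
      f"protective: {[n.node_id for n in spec.indicators if n.direction == 'protective']}")

report = audit_instrument(spec)
print(f"\ncorrected leaf combined weights sum to {report.leaf_weight_sum:.4f}")

print("\nconsistency ratios (all must be < 0.1):")
for node_id, printed, recomputed, status in report.consistency_checks:
    print(f"  node {node_id}: printed {printed:.4f}, recomputed {recomputed:.4f} ({status})")

print("\ncombined-weight rows outside rounding agreement:")
for row in report.rows:
    if row.combined_status == "mismatch":
        print(f"  {row.node_id}: printed {row.printed_combined}, "
              f"product rule gives {row.expected_combined}")

print("\nscore rows deviating from the rounding rule:")
for row in report.rows:
    if row.score_status == "mismatch":
        print(f"  {row.node_id}: printed {row.printed_score}, rule gives {row.rule_score}")

print(f"\nrows with reconstructed (derived) scores: {', '.join(report.derived_rows)}")
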