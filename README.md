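# vterisk

Delphi consensus statistics, Analytic Hierarchy Process (AHP) weighting,
and a packaged cancer-associated venous thromboembolism (VTE) risk
scoring instrument.

Cancer patients face a 4–7× elevated risk of VTE (deep-vein thrombosis and
pulmonary embolism), and risk-tailored thromboprophylaxis needs a scored
checklist of risk factors. One established way to build such an instrument
without outcome data is expert consensus: a multi-round **Delphi** survey
filters candidate indicators, and the **AHP** converts expert judgments of
relative importance into weights and integer scores. `vterisk` implements
that whole pipeline as a tested Python library — for methodologists
building consensus-based clinical instruments, and for anyone who wants to
apply or scrutinize the resulting VTE instrument (3 domains, 10
subdomains, 39 indicators, including two *protective*, negatively scored
factors: Asian population and anticoagulant use).

## The statistics at its core

**Delphi round statistics.** Each of *m* experts rates *n* candidate
indicators on three 5-point Likert dimensions (necessity, importance,
operability). Per item the package computes the mean, sample SD,
coefficient of variation CV = s/x̄ and the full-score ratio; an indicator
is retained iff, on every dimension, mean ≥ 4.0, full-score ratio > 50%
and CV < 0.25. Agreement across the panel is Kendall's coefficient of
concordance with tie correction,

    W = 12 S / ( m²(n³ − n) − m Σᵢ Tᵢ ),   χ² = m (n − 1) W on n − 1 df,

where S is the squared deviation of item rank-sums and Tᵢ corrects for
ties within expert *i*'s ranking. Panel reliability is the authority
coefficient Cr = (Cs + Ca)/2 from the familiarity coefficient Cs and the
judgment-basis coefficient Ca (> 0.70 is conventionally acceptable).

**AHP weighting.** Pairwise-comparison judgment matrices on the Saaty 1–9
scale are solved for their principal eigenvector (power iteration; the row
geometric-mean method is the built-in cross-check), with consistency
diagnostics CI = (λmax − n)/(n − 1) and CR = CI/RI(n); CR < 0.1 passes.
Hierarchical synthesis multiplies local weights down the tree, and an
indicator's score is 100 × combined weight rounded half-up (minimum
magnitude 1), negated for protective factors.

**The packaged instrument** ships as a versioned YAML artifact with full
provenance per row, and `audit_instrument` re-derives every combined
weight and score, flagging the handful of published rows that cannot be
reproduced from the table's own structure (they are kept as printed —
the publication is canonical — but never silently trusted).

## Worked example

```python
>>> from vterisk import load_instrument, score_patient, PatientRecord, score_range
>>> spec = load_instrument()
>>> score_range(spec)
(-7, 82)
>>> r = score_patient(PatientRecord("p1", {"2.2.1": True, "1.4.1": True, "3.1.5": True}), spec)
>>> r.total_score
3
```

The patient has stomach cancer (+6), D-dimer ≥ 500 µg/L (+3) and is on
anticoagulants (−6): net total 3 on a scale from −7 (all protective, no
risk factors) to 82 (maximal exclusivity-resolved risk set). Raw totals
only — high/low risk cut-points require clinical case data and are out of
scope.

The `examples/` scripts narrate one capability each; `python
examples/03_audit_instrument.py` prints, among other things:

```
consistency ratios (all must be < 0.1):
  node root: printed 0.0517, recomputed 0.0516 (within_rounding)
  node 1: printed 0.0229, recomputed 0.0228 (within_rounding)
  node 2: printed 0.0000, recomputed 0.0000 (exact)
  node 3: printed 0.0176, recomputed 0.0176 (exact)
```

i.e. every judgment matrix behind the instrument passes the consistency
test, and the published CR values are reproduced to within the rounding of
their printed λmax. See `docs/methods.md` for the audit's full findings,
including the four rows of the published table it flags.

A thin CLI wraps the same functions:

```sh
vterisk simulate panel --out fixtures --seed 7
vterisk summarize fixtures/ratings.csv --invited 27
vterisk audit
vterisk score patients.csv
```

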