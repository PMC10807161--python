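# Methods

This note documents the statistical procedures `vterisk` implements, the
conventions and defaults it adopts where the underlying methodology
leaves choices open, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## Delphi round statistics

**Item descriptives.** Ratings are integers 1..5 on three dimensions
(necessity, importance, operability). Per item and dimension the package
reports the arithmetic mean, the *sample* standard deviation (n − 1
denominator, the convention in the Delphi methodology literature; the
population SD is available via `ddof=0`), the coefficient of variation
CV = SD/mean, and the full-score ratio (fraction of responses equal to 5).
Missing cells are excluded pairwise for descriptives.

**Retention filter.** An indicator survives a round iff, on *every*
dimension (conjunctive, the default; a disjunctive `any_dimension` mode
exists): mean ≥ 4.0 (inclusive), full-score ratio strictly > 0.50, and
CV strictly < 0.25. The strict/inclusive boundary choices follow the
usual phrasing of these criteria ("≥ 4.0 points", "over 50%", "< 0.25").
Each dropped item records the first failed criterion per dimension, in
the fixed order mean → full-score → CV. Any threshold can be disabled
(`None`) or changed; filtering is deterministic and monotone under
threshold relaxation (property-tested).

**Kendall's W.** Within each expert, items are ranked with average ranks
for ties; the tie-corrected coefficient is
`W = 12 S / (m²(n³ − n) − m Σᵢ Tᵢ)` with `Tᵢ = Σ(t³ − t)` over tie groups
of expert *i*, and the test statistic is `χ² = m(n − 1)W` on `n − 1`
degrees of freedom (upper-tail p from the χ² distribution). This is
identical to the tie-corrected Friedman statistic, which is the
independent oracle in the test suite. Experts with incomplete ratings in
a dimension are removed listwise (logged). When every expert gives every
item the same rating the denominator vanishes and W is 0/0; the package
raises a dedicated error rather than returning 0.

**Authority coefficient.** Cr = (Cs + Ca)/2 exactly. The familiarity map
(Cs: level 5 → 1.0 down to level 1 → 0.2 in steps of 0.2) and the
judgment-basis table (Ca contributions — theoretical analysis
0.3/0.2/0.1, practical experience 0.5/0.4/0.3, peer understanding and
intuition 0.1 at every influence level) are the conventional tables of
this methodology; both are plain mappings that callers can override, and
a missing entry is a configuration error, never a silent default. The
midpoint identity makes panel means linear: mean Cr is exactly the
midpoint of mean Cs and mean Ca (property-tested).

**Display rounding.** Reported two- and four-decimal values use
round-half-to-even (banker's rounding), matching how the published tables
break ties (0.905 → 0.90, 0.24525 → 0.2452); raw precision is preserved
in all JSON output. Integer risk scores are the one deliberate exception
(half-up, below).

## AHP engine

**Weights.** The priority vector of a judgment matrix is the normalized
principal eigenvector, computed by power iteration from the uniform
vector with tolerance 1e−12 in max norm and a 10,000-iteration cap
(non-convergence is an error carrying the last iterate; in practice
reciprocal matrices of order ≤ 9 converge in tens of iterations). λmax is
the mean of component-wise Rayleigh ratios at the fixed point. The row
geometric-mean method is provided both as an alternative and as the
cross-check used in tests; the two agree exactly on consistent matrices.

**Consistency.** CI = (λmax − n)/(n − 1), CR = CI/RI(n), with CI = CR = 0
by convention for n ≤ 2 (2×2 reciprocal matrices are always consistent).
Two RI tables ship: `RI_52` (0.52 at n = 3; the table used by the AHP
software common in this application area, and the default because the
instrument's printed CR values reproduce exactly under it —
(3.0183 − 3)/2/0.52 = 0.0176) and Saaty's classical `RI_SAATY` (0.58 at
n = 3). Custom tables are accepted as plain mappings.

**Group aggregation.** Expert matrices are pooled by the element-wise
geometric mean, the standard choice because it is the only aggregation
preserving reciprocity; it also preserves shared consistency
(property-tested). For panels that report only mean Likert ratings per
criterion, `matrix_from_mean_ratings` builds the consistent ratio matrix
of the means, with optional snapping to the nearest Saaty value.

**Synthesis and scores.** Combined weights multiply local weights down
the tree. An indicator's score is 100 × combined weight rounded half-up
on the magnitude, clamped to a minimum magnitude of 1 (a retained
indicator must move the total; this reproduces the published −1/1 scores
of sub-1% weights), and negated for protective indicators. Half-up rather
than half-even here because the published instrument resolves the only
observable tie-adjacent cases upward.

## The packaged instrument and its audit

The instrument ships as YAML with per-row provenance: `printed` for
values read directly from the publication, `derived` for the five score
cells whose rendering in the published table is ambiguous (1.2.3, 2.3.1,
3.1.3, 3.1.4, 3.2.1); derived scores come from the package's own rounding
rule applied to the printed combined weight. Validation enforces the
structural counts (3 domains, 10 subdomains, 39 indicator leaves, exactly
2 protective indicators, nonzero integer scores) and the published
numbering gaps are preserved (there is no 1.3.3).

`audit_instrument` recomputes each combined weight by the product rule on
*normalized* sibling weights — the reading under which the 39 leaf
weights must sum to the root weight (they do: 1.0000) and under which a
subdomain's sole indicator inherits the subdomain weight in full — and
classifies each row as `exact`, `within_rounding` (≤ one unit in the last
printed decimal, attributable to the 4-decimal rounding of the published
local weights) or `mismatch`. On the packaged file it flags exactly four
rows:

* **2.3.1** (vessel/lymphatic compression): printed 0.0485 vs product
  0.0480;
* **3.2.1** (hip/knee surgery): printed 0.0495 vs product 0.0490;
* **2.1.1** (diagnosis ≤ 6 months) and **3.3.1** (central venous
  catheterization): each is the sole indicator of its subdomain yet is
  printed with a local weight equal to its parent's *combined* weight, so
  the subdomain discount is applied twice (printed 0.0150 vs corrected
  0.1226, and 0.0015 ≈ 0.0382² vs corrected 0.0382).

Score recomputation flags two further rows where the published integer
departs from the rounding rule: 1.1.3 (BMI ≥ 28: printed 2, rule gives 1 —
plausibly category stacking over the BMI > 24 band) and 2.1.1 (printed 1,
rule gives 2 from the printed weight 0.0150, a 1.50 tie). The published
values remain canonical everywhere: the audit reports, it never corrects.
Published CR values reproduce exactly or to within the rounding of their
printed λmax (root 0.0517 vs 0.0516; patient domain 0.0229 vs 0.0228).

**Scoring.** Patient totals are additive over present indicators. The two
BMI bands form the single packaged exclusivity group; when both are
flagged only the higher-magnitude member counts (ties broken toward the
later, higher-category row) and the suppressed flag is reported. The
attainable range of the packaged instrument is −7 (both protective
factors, nothing else) to 82 (maximal exclusivity-resolved risk set;
verified against brute-force enumeration on a toy instrument). Clinical
risk thresholds (high/low cut-points) are deliberately **not** provided:
they require case-level outcome data that do not yet exist for this
instrument, so the scorer returns raw totals only.

## Synthetic-data generators

All generators draw from one explicit `numpy` seed; no global state, no
time or locale dependence, bit-identical across platforms
(property-tested).

**Panels** use a consensus mixture model: each (expert, dimension) adopts
a common latent item-quality ordering with probability `consensus`, else
an independent random permutation of it; ratings are latent quality plus
centered Gaussian noise (`noise_sd`), rounded and clamped to 1..5. The
single `consensus` knob maps monotonically onto expected Kendall's W
(checked over 200 seeded replicates per setting): 0 gives the
independence null (W < 0.1 with high probability at 50 experts), 1 with
zero noise gives W = 1 exactly. Defaults — 23 experts, 47 items,
consensus 0.7, noise 0.8, latent qualities evenly spread over
[2.8, 4.9] — mirror the panel size of the consultation the package
models and produce W in the 0.1–0.25 range and CV near 0.2, the regime
of a real mid-consensus round. What the model does *not* emulate:
correlated rating dimensions, expert-specific severity/leniency biases,
item-difficulty heteroscedasticity, and the narrower quality spread of a
literature-pre-screened indicator pool (so the default round drops more
items than a real late-round panel would — the full-score criterion
bites hardest under rating noise). Passing tests therefore demonstrate
correctness of the statistics, not calibration to any particular real
panel.

**Profiles** draw familiarity levels (default split 5/15/3 across levels
5/4/3, with an exact largest-remainder quota option) and per-basis
influence levels skewed toward theory and experience, giving panel-mean
Ca near 0.9 as senior clinical panels report. **Cohorts** draw
independent per-indicator Bernoulli flags (default prevalence 0.10);
exclusivity-group members are sampled jointly from one uniform draw
walking members in descending score magnitude with mass capped at 1, so
at most one member is ever present and degenerate all-ones prevalences
deterministically select the highest band. Real comorbidity correlation
structure is out of scope.

## Numerical choices and degenerate inputs

* Reciprocity and unit-diagonal validation at relative tolerance 1e−9;
  weights sum to 1 within 1e−12.
* Sibling local weights are expected to sum to 1 within 5e−4 (4-decimal
  printed weights carry that much rounding residue); larger deviations
  are warnings at load and structural flags in the audit, not fatal.
* Audit "within rounding" band: one unit in the last printed decimal
  (1e−4 on 4-decimal weights), because the recomputation starts from
  already-rounded published local weights.
* Decimal display rounding goes through `decimal.Decimal` on the shortest
  float representation to avoid binary artifacts at exact ties.
* Degenerate inputs fail loudly with typed errors: all-identical ratings
  (W undefined), fewer than 2 ratings per item, unknown labels, missing
  coefficient-table entries, nonpositive weights, non-convergence.

## Limitations

The package reconstructs and operationalizes a consensus instrument; it
cannot validate it. Discrimination, calibration and risk-threshold
determination need clinical cohorts and are explicitly out of scope, as
are fuzzy AHP/ANP variants, incomplete-matrix completion, and
questionnaire authoring. The exact expert-level rating data behind the
published round statistics are not public, so round-level W/χ² values
can only be checked through their algebraic identities and tie-correction
bounds, not reproduced digit-for-digit.
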