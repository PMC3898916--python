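# Methods

`amsnet` analyses the symptomatology of acute mountain sickness (AMS) as a
network problem over self-report questionnaires. Each subject-day pairs a
seven-item visual analogue scale (VAS) questionnaire with the five-item
Lake Louise Score (LLS). The analysis asks whether AMS behaves as a single
syndrome or decomposes into distinct symptom patterns, by clustering
questionnaires whose item profiles are highly correlated.

## Data model and scoring

Each VAS item is a mark on a 100 mm line between two anchor statements.
Some items are printed with the severe anchor on the left, so raw
measurements (distance from the left end) are *oriented*: reversed items
map v → 100 − v, making 0 mm = no symptom and 100 mm = maximal severity
for every item. Orientation is an involution and is applied before any
other computation.

The seven items are headache, two nausea wordings, two fatigue wordings,
dizziness and sleep quality. The duplicated fatigue item is an attention
check: a record whose two oriented fatigue responses disagree by more than
the agreement threshold (default 40 mm) is excluded. The threshold is
inclusive — a disagreement of exactly 40 mm passes — reading "minimum
agreement required" as an inclusive bound; the boundary choice is
configurable.

Derived scores:

- **Total VAS** = weighted sum of the seven oriented items (unit weights
  by default, range 0–700 mm). Weights are exposed so alternative symptom
  weightings can be explored.
- **Five-symptom profile**: sleep, GI upset, dizziness, headache, fatigue;
  the duplicated nausea and fatigue items are averaged.
- **LLS total** = sum of the five 0–3 items; the **AMS case definition**
  is total > 2 with headache > 0.

## Correlation network

Every QC-passing questionnaire is a node. An undirected edge joins two
questionnaires whose item profiles (all seven items by default; the
five-symptom composite as a sensitivity mode) have Pearson correlation
r ≥ 0.95, with r stored as the edge weight. The high threshold restricts
the graph to near-identical symptom patterns; questionnaires with no
supra-threshold neighbour drop out of the network, and zero-variance
profiles (whose correlation is undefined) never form edges. The threshold
is inclusive at equality; with continuous mm data, exact equality has
measure zero.

## Markov clustering

The network is partitioned with the Markov Cluster algorithm (MCL),
implemented from scratch on dense numpy matrices:

1. add self-loops (unit weight by default) and column-normalise the
   weighted adjacency into a stochastic flow matrix;
2. iterate **expansion** (matrix power, default 2) and **inflation**
   (entrywise power, default 1.4, followed by column renormalisation),
   then prune entries below 1e−6 and renormalise;
3. stop when the largest entry change falls below 1e−8 (cap 200
   iterations; non-convergence is flagged on the result, not fatal);
4. read clusters off the limit matrix: nodes with positive self-flow are
   *attractors*; attractors that reach one another form an attractor
   system; every node joins the system receiving the largest share of its
   column mass (ties break toward the larger system, then the system
   containing the smallest attractor label, so extraction is
   deterministic);
5. clusters smaller than the minimum size (default 30) are reported as
   *unclustered*, preserving the accounting rather than silently dropping
   nodes.

Inflation controls granularity — larger values fragment the graph into
more, smaller clusters. 1.4 is the analysis default. Expansion power,
self-loop scheme, pruning threshold and tolerance are standard MCL
devices, not scientifically load-bearing; tests assert results are
insensitive to pruning at this scale, and that column sums stay 1 ± 1e−9
through every step. Per-cluster per-item medians summarise the symptom
phenotype of each cluster.

The dense implementation is appropriate up to a few thousand nodes;
sparse-matrix engineering for larger graphs is out of scope.

## Symptom statistics

- **Spearman rank correlation** (mid-ranks for ties) between the five
  symptom composites, computed over one questionnaire per subject to
  avoid repeated-measures inflation. 95% intervals use the Fisher z
  transform: tanh(atanh ρ ± z·(n−3)^(−1/2)).
- The **per-symptom mean** is the plain arithmetic mean of that symptom's
  four off-diagonal coefficients (this is what reproduces the published
  summary row; no Fisher-z averaging). No confidence interval is attached
  to the mean row: no reproducible recipe for one exists.
- A **symptom graph** thresholds the 5×5 matrix (default cutoff 0.4) and
  reports isolated symptoms; on the published coefficients sleep is the
  sole outlier at this cutoff.
- **Treatment balance** across clusters is tested with Pearson's
  chi-squared (no continuity correction) on the arm × cluster contingency
  table; column percentages are reported at 1 dp.
- **Severity diagnostics**: sample mean/sd/median/IQR of total scores,
  skewness, the square-root transform, and a Kolmogorov–Smirnov normality
  test with estimated mean and sd (Lilliefors-type null,
  Dallal–Wilkinson p approximation via statsmodels). Note that such a
  test, when correctly calibrated, exceeds p = 0.10 for exactly 90% of
  true-null samples — p > 0.10 on a given dataset is evidence of adequate
  normality, not a guarantee the test produces large p-values almost
  surely.

## Synthetic cohort generator

No record-level dataset is publicly archived, so every downstream stage
is exercised on a generator that emulates the study's structure:

- **292 subjects**: 103 followed longitudinally for 9 study days (3650 m
  on days 1–4, 5200 m after) with treatment arms assigned
  42:41:20 (placebo : antioxidant : sildenafil), plus 189 cross-sectional
  subjects at 4730 m with unknown treatment — 1116 subject-days in all.
- **Three symptom archetypes** over a diffuse background, mixed per
  record with weights 0.388/0.121/0.041 vs 0.45 background (the clustered
  mass and its split mirror the canonical 407/127/43 cluster sizes out of
  1045). The archetype mean profiles encode the three canonical
  phenotypes qualitatively — poor sleep + fatigue with little headache;
  poor sleep + headache + fatigue; headache + fatigue with little sleep
  disturbance — they are configuration, not measured values.
- **Within-archetype noise**: items are archetype mean + N(0, 5 mm),
  truncated to [0, 100] (instrument censoring at the line ends) and
  rounded to 0.1 mm. Two same-archetype records then correlate across
  items at roughly s²/(s² + σ²), where s² is the variance of the
  archetype's item means (600–740 mm² for the shipped profiles) and
  σ² = 25 mm², i.e. r ≈ 0.96–0.97 — above the 0.95 network threshold —
  while between-archetype correlations stay ≤ ~0.8. This attenuation
  argument fixed the noise scale; the truncated-normal family itself is a
  modelling choice, as the real response distribution is unknown.
- **Background** records draw each item independently from
  100·Beta(0.55, 2.4): right-skewed, low severity, so total scores skew
  right while background profile pairs correlate above 0.95 only rarely
  (~0.002), which is what leaves the background unclustered.
- **Duplicate-fatigue consistency**: archetype records draw both fatigue
  items around the same mean (natural disagreement beyond 40 mm has
  probability ~1e−8); background records draw the second fatigue response
  independently from the same marginal, rejection-constrained to agree
  within 35 mm. Injected QC discordance displaces the duplicate by at
  least 41 mm (surviving rounding), so the QC filter recovers injected
  failures exactly and a zero injection rate yields zero failures.
- **Subject effects**: a per-subject severity offset (sd 4 mm) shifts all
  items equally; it cancels in profile–profile Pearson correlations by
  construction. Day-to-day within-subject persistence is *not* modelled:
  each record's mixture component is drawn independently.
- **LLS derivation**: each composite is binned 0–25/26–50/51–75/76–100 →
  0/1/2/3, with ±1 jitter at probability 0.1, clamped — a monotone
  VAS–LLS association with realistic disagreement.

What passing tests on this cohort do and do not show: they demonstrate
that the pipeline recovers planted cluster structure at the published
parameter settings (r ≥ 0.95, inflation 1.4, minimum size 30) and that
every arithmetic operation matches its published in-table counterpart;
they do not certify the clinical findings, which depend on the real
cohort. Two deliberate realism gaps follow from the design: the
generator's symptom-correlation matrix need not match the published one
(archetypes were shaped for cluster recovery, not for the 5×5 Spearman
structure), and the sleep-substitution sensitivity rerun degrades cluster
agreement on synthetic data because next-day sleep values cross mixture
components — on real data, within-subject persistence is what keeps that
analysis stable.

## Numerical and design choices

- Sample sizes throughout tests are the shipped defaults (~1116 records)
  for the end-to-end checks and a scaled cohort (~320–1080 records) for
  multi-seed property suites; both recover the planted structure.
- The square-root skewness diagnostic runs on a low-severity-weighted
  variant of the generator (80% background), because the transform is a
  normalising map only in the strongly right-skewed regime; the shipped
  default mixture is only mildly right-skewed.
- Published-table reproduction: per-symptom means are asserted within
  0.005 of the printed 2-dp values (exact at printed precision);
  Fisher-z interval bounds are asserted within 0.011 of the printed
  bounds, since the printed coefficients are themselves rounded to 2 dp
  and that rounding propagates up to ~0.008 into the bounds through the
  z transform.
- Degenerate inputs: zero-variance profiles yield no edges; empty
  networks, empty clusters, zero contingency marginals, single-value
  standard deviations and sub-minimum sample sizes raise errors naming
  the offending stage.
- Missing sex/age metadata is carried as an explicit "missing" category,
  never dropped; malformed CSV rows are reported with physical line
  numbers and abort the read unless explicitly skipped.

## Known limitations

- Exact node-level concordance with the original published clustering is
  not testable (the record-level data are no longer distributed); only
  structural concordance on synthetic data and in-table arithmetic are.
- MCL granularity is monotone in inflation in practice, not by theorem;
  the property suite asserts it on a grid of inflation values over
  several synthetic networks.
- The generator does not simulate physiological covariates, altitude
  profiles beyond the fixed itinerary, or within-subject day-to-day
  autocorrelation beyond the constant subject offset.
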