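# Methods

## Cohort model

The unit of analysis is a patient with at least one CKD-coded diagnosis
event; the **index date** is the first such event (the only choice that is
reproducible from an event table — "any CKD event" would make the index
ambiguous). Age is completed calendar years at index. The qualifying AKI
window is `[index − lookback, index)` with a calendar-year `lookback`
(default 3 years, `pd.DateOffset` arithmetic, so leap years are handled by
the calendar rather than a 365.25-day approximation).

A patient is **HA-AKI** when an inpatient encounter falls in
`[first_aki − 90d, first_aki]`. The phrase "AKI within 90 days of an
inpatient hospitalization" is directionally ambiguous; we read it as the
hospitalization preceding or accompanying the AKI, and expose
`ha_direction ∈ {encounter_before, encounter_after, either}` for the other
readings. Inpatient encounters are recognized either by event kind or by CPT
code membership in an editable default set (hospital observation/inpatient
E&M ranges 99218–99239, 99251–99255, 99291, 99304–99307, 94002, G0378, and
two TriNetX-style internal encounter identifiers); the set is a default, not
ground truth. AKI/CKD default code prefixes are {N17, 584} and {N18, 585};
the ICD-9 AKI code is 584 (acute kidney failure).

Exclusions: dialysis strictly before the first AKI — or, for patients with
no qualifying AKI, before index — and age under 18 at index, with under-18
taking precedence when both apply. Patients lacking any CKD event are
dropped and counted in the run log.

**Rare-feature rule.** A feature is retained when its prevalence reaches the
threshold (default 1%) in *at least one* cohort; per-cohort matrices then
drop features absent from that cohort. A drop-if-rare-anywhere rule would
force identical feature counts across cohorts, which contradicts the
intended behaviour of cohort-specific feature universes.

**Baseline table.** Percentages for sex/race/ethnicity/comorbidities use the
full cohort N as denominator; age-group percentages use only patients with a
recorded age (missing birth dates yield missing ages). Categorical
comparisons are Pearson chi-square on the level-count table (zero-count
levels removed), continuous ones independent-samples t-tests; degenerate
inputs (zero variance, empty cells) produce NaN rather than an error.

## Comorbidity networks

`OER_ij = C_ij·N/(C_i·C_j)` is computed exactly from integer counts for all
unordered pairs; `C_ij = 0` gives OER 0, and zero-prevalence features are a
caller error. The analysis network keeps OER > 1 edges; the prominent
network additionally keeps edges at or above the q-th quantile (default
q = 0.90, linear-interpolation quantile — no method is canonical, so the
numpy default is used and the realized threshold is reported). Raising q can
only remove edges. Isolated nodes are dropped.

The five metrics are computed on the **unweighted** graph: degree as raw
neighbour count, betweenness unnormalized (pair-path fraction sums — the
scale on which published disease-network values like 113.37 live), closeness
normalized to (0, 1] with the Wasserman–Faust component scaling, and
diameter / average path length on the largest connected component (the
definition for disconnected graphs is otherwise undefined). A singleton
graph has diameter 0 and undefined path length.

**Community detection** is fast-unfolding (Louvain) modularity optimization
(networkx implementation) at resolution γ (default 1.0, with an optional
scan over γ ∈ [0.8, 1.6] for the smallest γ giving ≥ 3 communities). By
default the optimizer sees the OER edge weights — matching how Gephi's
modularity routine, the de facto standard for this kind of analysis, treats
weighted graphs — while the five metrics stay unweighted; `use_weights=False`
restores fully unweighted detection. Louvain is order-sensitive, so node
order is canonicalized (sorted codes) and the seed fixed (default 20220901);
results are then deterministic. Top-k cluster shares are reported against
both the top-k universe (sums to 100%) and all partitioned nodes.

Cohort-versus-cohort metric comparisons use Welch two-sample t-tests on the
node-level metric distributions; the path-length comparison uses per-node
mean shortest-path lengths and is reported N/A when both sides are
degenerate.

## Variable clustering

Binary indicators are treated as quantitative after centering and unit
scaling: for 0/1 variables the correlation-ratio and squared-correlation
formulations of the homogeneity criterion coincide up to coding, and the
quantitative route has a closed-form oracle (H of a cluster = largest
eigenvalue of its correlation matrix; H(singleton) = 1; for two variables
H = 1 + |r|). Agglomeration recomputes the merge cost
d(A,B) = H(A) + H(B) − H(A∪B) ≥ 0 for candidate pairs at each step (plain
O(n³)-style agglomeration; with n ≤ ~70 features this is milliseconds, so
the k-means-style exchange pass some implementations add is omitted). Ties
in d (within 1e-12) break on the lexicographically smallest member names,
making the tree invariant to column order. `cut(K)` replays the first
n − K merges; total homogeneity is non-increasing along the path. Zero
variance columns are rejected with the offending names. The sklearn-style
`VariableClusterer.transform` returns each cluster's synthetic variable
(first-PC score, sign fixed so loadings sum positive).

## Cluster matching

With at most three clusters per method the assignment search is exhaustive
(≤ 6 bijections after truncating to the smaller k), maximizing total
intersection — raw counts, not Jaccard, because the two methods produce
systematically different cluster sizes. Ties prefer pairing the largest
clusters together, then the lexicographically smallest pairing. The
similarity percentage is

`100 · |covered(A) ∩ covered(B)| / |covered(A) ∪ covered(B)|`

where covered(·) is the union of a method's top-3 clusters; this is the
"union of pairwise intersections" over all cluster pairs, so a variable that
merely changes cluster within the top-3 still counts as matched (the
per-pair table shows the displacement). The formula is isolated in one
function, and a per-pair mean-Jaccard alternative is reported alongside.
Cross-cohort tables: *similar* = matched in every cohort; *dissimilar* =
matched in an AKI cohort but not in the reference cohort's matched set,
distinguishing features absent from the reference universe entirely
(asterisk semantics) from features present but not selected (dash
semantics); *unique* = in a cohort's universe but selected by neither
method. Membership regression is a statsmodels logistic fit per binary
contrast; perfect separation or non-convergence flags the coefficient
non-estimable instead of raising.

## Synthetic EHR generator

The generator emulates the study design the pipeline targets, not any real
population. Defaults (chosen once, before any tuning): 5,000 patients split
0.102 / 0.115 / 0.783 into intended HA-AKI / CA-AKI / No-AKI; per-cohort
demographics (sex/race/ethnicity distributions, age means 65.1 / 66.4 /
68.6, sd ≈ 13.4) mirroring the published baseline table; index dates
uniform over mid-2013–mid-2022; 34 diagnosis and 34 procedure codes drawn
from realistic ICD-10-CM / CPT pools, of which 3 × 10 form planted blocks at
baseline prevalence 0.05 and 4 form a rare tail at 0.004 that exercises the
1% filter.

Co-occurrence is planted with a **shared latent Bernoulli per block**: a
patient carries a block with probability q = 0.2, in which case member
features fire with probability min(0.95, multiplier × baseline), baseline
otherwise. Multiplier 1 reduces exactly to independence (pairwise OER → 1);
the default multiplier 6 yields within-block OER ≈ 2 against cross-block
OER ≈ 1, enough for both clustering methods to recover the blocks at
n = 5,000 while remaining a genuinely noisy inference problem. Timing is
drawn so the cohort rules are exercised, not merely satisfied: AKI events
30–1,050 days before index (safely inside 3 calendar years), HA encounters
0–90 days before the AKI, a 5% fraction of No-AKI patients with a *stale*
AKI 1,100–1,800 days before index (safely outside), 2% dialysis exclusions
placed strictly before the first AKI (or before index), 1% under-18
patients, benign inpatient encounters for 15% of No-AKI patients,
duplicated diagnosis events, and out-of-window procedure events that must
not flip the feature matrix. Every draw comes from a single numpy
Generator, so a fixed seed gives byte-identical outputs; the intended label
of every patient and the block of every feature are returned as ground
truth, and exact agreement between intended labels and the cohort rules is
the generator's primary correctness check.

What the generator does **not** model — and hence what passing tests do not
establish about real data: visit-level billing structure, code ontology
hierarchy and synonymy, ICD-9/ICD-10 era mixing (the crosswalk is exercised
only on toy fixtures), informative missingness, temporal correlation between
comorbidities, demographic–comorbidity dependence, and insurance coverage
gaps. Recovery of planted blocks shows the estimators are correct and
well-calibrated, not that real comorbidity structure is as clean.

## Problem sizes and determinism

The default study conditions (n = 5,000, three blocks per domain,
multiplier 6) run the full pipeline in seconds on one CPU and are the sizes
used by the test suite and `scripts/acceptance.py`. Pipeline runs serialize
their config (hash embedded in `summary.json`) and are byte-identical for
identical config + seed. Known limitations: the per-cohort resolutions and
OER thresholds published for the original health-system extract are
data-dependent descriptive values, not constants this package can
reproduce; Gephi itself is replaced by GEXF/GraphML export; only a stub
ICD-9→ICD-10 crosswalk ships (pass your own table for real mixed-era data).
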