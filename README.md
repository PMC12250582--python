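# patientprofiler

Hybrid patient-profiling of acute-kidney-injury (AKI) to chronic-kidney-disease
(CKD) progression from longitudinal EHR event tables. The package is written
for epidemiologists and clinical data scientists who want to phenotype the
comorbidity structure of a CKD population stratified by AKI history, without
access to the original health-system extract: a tested synthetic EHR generator
stands in for real data, and every analysis stage also accepts user-supplied
`patients.csv` / `events.csv` tables.

## What it computes

**Cohorts.** Patients with a CKD diagnosis (ICD-10-CM N18 / ICD-9 585) are
classified by their AKI history (N17 / 584) in the 3 years before the first
CKD-coded event:

- **HA-AKI** (hospital-acquired): an inpatient encounter (configurable CPT
  set) falls within the 90 days up to the first AKI;
- **CA-AKI** (community-acquired): any other qualifying AKI;
- **No-AKI**: no AKI inside the lookback window.

Dialysis before the first AKI (or before index for never-AKI patients) and age
under 18 are exclusions. Diagnoses and procedures are binarized per patient
(procedures restricted to the 3-year lookback) and features below 1%
prevalence in every cohort are dropped.

**Comorbidity networks.** For each cohort, every code pair (i, j) gets an
observed-to-expected ratio

```
OER_ij = C_ij · N / (C_i · C_j)
```

where C_i, C_j are code counts, C_ij the co-occurrence count and N the cohort
size; OER > 1 means the pair co-occurs more than expected under independence.
Edges with OER > 1 form the phenotypic network (optionally thresholded at the
90th-percentile OER for the "prominent" view). Five unweighted metrics are
computed — diameter, degree, unnormalized betweenness, average path length,
normalized closeness — and fast-unfolding (Louvain) modularity optimization
partitions the codes into communities.

**Variable clustering.** Independently, the binarized codes are clustered
hierarchically under the homogeneity criterion: a cluster's homogeneity is
the largest eigenvalue of its correlation matrix (the variance its first
principal "synthetic variable" captures), and each merge step joins the pair
of clusters losing the least total homogeneity.

**Cluster matching.** Each method's top-3 clusters are matched by exhaustive
search over assignments maximizing the total intersection; the similarity
percentage is the share of all covered variables selected by both methods.
Matched sets across cohorts yield similar / dissimilar / unique phenotype
tables, and logistic regression quantifies how selected codes predict cohort
membership (odds ratios with Wald CIs).

## Worked example

```bash
ppa run --simulate --seed 1 --out demo
```

simulates 5,000 patients (42,282 events) and runs every stage. The log
reports

```
cohort sizes: {'HA_AKI': 496, 'CA_AKI': 581, 'NO_AKI': 3774}; excluded: {'pre_aki_dialysis': 99, 'under_18': 50}
rare-feature filter: retained 30 / 34 features
```

i.e. roughly 10%/12% of included patients carry hospital- and
community-acquired AKI, 149 patients are excluded by the dialysis and age
rules, and the four planted sub-1%-prevalence codes are filtered out.
`demo/summary.md` then tabulates the per-cohort networks, e.g. for No-AKI
diagnoses:

| nodes | edges | diameter | avg degree | avg path length | avg betweenness | avg closeness | modularity | top-3 cluster % |
|---|---|---|---|---|---|---|---|---|
| 32 | 277 | 2 | 17.31 | 1.44 | 6.84 | 0.70 | 0.32 | 37.50/31.25/31.25 |

and the cross-method comparison

```
diagnosis / NO_AKI: 100.0% matched (mean Jaccard 88.89%)
```

meaning the network communities and the variable clusters select exactly the
same diagnosis codes — expected here, because the generator plants three
disjoint high-co-occurrence blocks that both methods recover. Artifacts per
run: `cohort_assignments.csv`, `baseline_table.tsv`, sparse feature matrices,
Gephi-compatible `.gexf` graphs (plus a median-thinned `_viz` variant),
node-metric TSVs, dendrogram JSONs, match reports, and a deterministic
`summary.json` keyed by the config hash.

The same stages are available as library calls (`generate_cohort_events`,
`assign_cohorts`, `compute_oer_edges`, `detect_communities`,
`cluster_variables`, `match_clusters`, ...) and as sklearn-style estimators
(`ComorbidityNetworkClusterer`, `VariableClusterer`) that cluster the
*columns* of a patients × codes matrix.

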