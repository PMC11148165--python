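# dysbiome

Multicompartment microbiome dysbiosis analysis for critically ill cohorts.

Mechanically ventilated ICU patients undergo rapid, progressive disruption of
their oral, lung, and gut bacterial communities: diversity collapses,
beneficial obligate anaerobes disappear, and respiratory pathogens take over.
`dysbiome` packages the statistical machinery needed to quantify that process
from genus-level 16S count tables and relate it to 60-day survival — for
microbiome researchers and critical-care translational groups who want a
tested, reproducible reimplementation of this analysis style rather than a
pile of one-off scripts.

## What it computes

**Community typing.** Counts x_i for sample i follow a Dirichlet-multinomial
mixture (DMM): component z_i ~ Categorical(π), composition p_i ~
Dirichlet(α_{z_i}), x_i ~ Multinomial(n_i, p_i). The mixture is fit by EM
(responsibility-weighted Minka fixed-point updates for α), the number of
components K is chosen by a Laplace approximation to the log model evidence
combined with a ≥10%-membership prevalence rule, and clusters are named
High / Intermediate / Low Diversity by mean rarefied Shannon index.

**Dysbiosis Index.** A multinomial-logit classifier with the High-Diversity
cluster as reference. With feature vector f (CLR-transformed taxon
abundances, optionally the Shannon index) and coefficient vectors b1, b2:

    X = exp(b1·[1,f]),  Y = exp(b2·[1,f])
    P(H) = 1/(1+X+Y),  P(I) = X/(1+X+Y),  P(L) = Y/(1+X+Y)

The three published compartment models (oral, lung, gut) ship verbatim and
can classify new samples directly; the full derivation pipeline (top-50 CLR
taxa + Shannon → stability-selection feature screen → multinomial fit →
held-out accuracy with exact binomial CI) is also implemented.

**Everything around it.** Read-depth QC (≥1000 reads; unsoiled rectal swabs
excluded), rarefied Shannon diversity (100 subsamples at depth 1000), CLR
transforms, Bray-Curtis/PCoA/PERMANOVA with Bonferroni correction,
empirical-Bayes moderated-t differential abundance with BH correction,
oxygen-requirement and pathogenicity class aggregation, gut-origin-enrichment
(>30%) and dominance (>50%) flags, taxa–biomarker Pearson correlation maps,
Kaplan-Meier/log-rank, Cox proportional hazards (Efron or Breslow ties), and
a shared-random-intercept joint longitudinal–survival model with bootstrap
CIs for the association coefficient ν. A synthetic cohort generator
reproduces the whole data structure — three compartments, three visit
intervals, cluster-dependent hazards, informative dropout, biomarkers
loading on pathogen abundance — so every stage is testable end to end
without access to patient data.

## Worked example

```python
import numpy as np, pandas as pd
from dysbiome.synthetic import SimulationConfig, simulate_cohort
from dysbiome.ecology import qc_filter, shannon_table
from dysbiome.dmm import select_k, label_clusters
from dysbiome.dysbiosis import derive_index, predict
from dysbiome.io import load_paper_model

cohort = simulate_cohort(SimulationConfig(seed=1, n_subjects=100))
table, report = qc_filter(cohort.count_tables["lung"]["baseline"], cohort.metadata)
print(f"lung baseline: {report.n_retained}/{report.n_input} samples pass QC")

shannon = shannon_table(table, depth=1000, reps=100, seed=1)
model = select_k(table, K_max=5, seed=1)
labeling = label_clusters(model, shannon.loc[table.sample_ids].to_numpy())
labels = np.array(labeling.sample_labels(model))
print(f"selected K = {model.K} (Laplace log evidence {model.laplace_log_evidence:.1f})")
sizes = pd.Series(labels).value_counts().sort_index()
print("cluster sizes:", {k: int(v) for k, v in sizes.items()})
print("mean Shannon:", {labeling.labels[k]: round(v, 2)
                        for k, v in sorted(labeling.mean_shannon.items())})

derived = derive_index(table, labels, shannon, compartment="lung", seed=1)
print(f"dysbiosis index: held-out accuracy {derived.accuracy:.3f} "
      f"(95% CI {derived.ci[0]:.3f}-{derived.ci[1]:.3f}, n={derived.n_test})")

paper = load_paper_model("lung")
f = pd.Series(0.0, index=paper.feature_names)
f["ShannonIndex"] = 4.0
pred = predict(paper, f)
print(f"published lung model at Shannon=4: P(H)={pred.p_high:.3f} -> {pred.label}")
```

Output:

```
lung baseline: 100/100 samples pass QC
selected K = 3 (Laplace log evidence -19249.3)
cluster sizes: {'High': 37, 'Intermediate': 38, 'Low': 25}
mean Shannon: {'Low': 1.82, 'High': 3.33, 'Intermediate': 2.81}
dysbiosis index: held-out accuracy 0.950 (95% CI 0.751-0.999, n=20)
published lung model at Shannon=4: P(H)=0.839 -> High
```

Reading the numbers: the evidence-based selection recovers the three
community types the generator planted; cluster sizes and per-cluster mean
Shannon show the expected High > Intermediate > Low diversity gradient; the
re-derived lung index classifies 19 of 20 held-out samples into their DMM
cluster; and a hypothetical sample with Shannon index 4 and average (CLR = 0)
taxon abundances is confidently High-Diversity under the published lung
coefficients.

The same analysis is scriptable from the shell:

```bash
dysbiome simulate --seed 1 --n-subjects 100 --out-dir cohort/
dysbiome qc cohort/counts_lung_baseline.tsv --metadata cohort/metadata.tsv --out lung_qc.tsv
dysbiome dmm-fit lung_qc.tsv --kmax 5 --out clusters.tsv
dysbiome run-all --seed 1 --out-dir run1/   # full pipeline + report.json
```

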