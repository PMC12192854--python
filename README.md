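# allonet

Allosteric-network analysis of protein conformational ensembles, built for
multidomain kinases of the Src family (SH3–SH2–linker–SH1 architecture).
From Cα coordinate ensembles of several "systems" (wildtype, ligand-bound,
mutants — each labelled active-like or inactive-like) the package computes:

* **flexibility descriptors** — backbone/Cα RMSD, per-residue RMSF and
  ΔRMSF = RMSF(WT) − RMSF(mutant), distances/angles, PAM-medoid
  representative structures, Wilcoxon distribution comparisons;
* **essential dynamics** — PCA of the 3N×3N Cα fluctuation covariance and
  extreme projections along PC1;
* **surfaces and interfaces** — Shrake–Rupley SASA, interdomain interface
  residues by ΔSASA > 1.0 Å², ligand-pocket surface area and contact
  occupancy;
* **correlation networks** — the dynamic cross-correlation matrix (DCCM)
  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), the residue graph with edges
  where |C_ij| > 0.8, Louvain communities, per-module purity, the
  lowest-purity *integration module*, betweenness centrality and
  threshold-consistency of top connectors;
* **interface-weighted allosteric-hub scores** — per residue r,

      ρ_r  = corr(b_r, y)            (betweenness profile vs state labels)
      μ_r  = (1/N) Σ_s M_{r,s}       (mean module-mixing index)
      mix_weighted_corr_r = ρ_r · μ_r
      interface_weighted_score_r = ρ_r · μ_r · (1 + f_r)

  with f_r the fraction of systems in which r sits at an interdomain
  interface; residues scoring > 0.5 are flagged as allosteric hubs;
* **a conformational-state classifier** — a 1000-tree random forest on 16
  geometric descriptors with Min–Max scaling, stratified 80/20 split and
  SMOTE (0.5) on the training data only, reporting accuracy, per-class
  precision/recall/F1, AUC, and Gini + permutation importances.

Because microsecond trajectories are not desk-reproducible, the package
ships a first-class synthetic-ensemble generator that plants the
statistical structure the analysis assumes — intra-domain correlation
blocks, cross-domain hub couplings that differ between active-like and
inactive-like systems, and class-separated feature tables — so every stage
is testable end-to-end against known ground truth.

## Worked example

```python
from allonet import synth
from allonet.pipeline import RunConfig, run_pipeline

config = RunConfig(out_dir="demo", seed=7, study=synth.compact_study_config())
result = run_pipeline(config)

top = result.hub_table.nlargest(8, "interface_weighted_score")
print(top[["residue_id", "region", "rho", "mu", "f_interface",
           "interface_weighted_score"]].round(3).to_string(index=False))
```

The compact study design is an 80-residue five-region protein, six systems
(2 active-like, 4 inactive-like), three replicates of 400 frames each, with
the interdomain linker planted as the cross-domain coupling element in
active-like systems only.  The run prints:

```
 residue_id region   rho    mu  f_interface  interface_weighted_score
         37      L 0.921 0.053        0.833                     0.089
         40      L 0.832 0.053        1.000                     0.088
         38      L 0.869 0.053        0.833                     0.084
         33      L 0.632 0.053        1.000                     0.067
         39      L 0.640 0.053        0.833                     0.062
         35      L 0.992 0.034        0.500                     0.051
         34      L 0.703 0.034        1.000                     0.048
         36      L 0.774 0.016        1.000                     0.025
```

The eight top-scoring residues are exactly the eight planted linker hubs:
their betweenness profiles track the activity labels (ρ_r up to 0.99), they
recur in region-mixed modules (μ_r > 0), and they are interface-enriched
(f_r up to 1.0).  The pairwise DCCM similarity matrix shows the class
structure the scores exploit — near-perfect correlation within a class,
visibly lower across classes:

```
             WT  WT-ATP  WT-DAS  E290K-ATP  I364N-ATP  K275A-ATP
WT         1.00    1.00    0.79       0.80       0.81       0.81
WT-ATP     1.00    1.00    0.79       0.80       0.80       0.81
WT-DAS     0.79    0.79    1.00       0.99       0.99       0.99
E290K-ATP  0.80    0.80    0.99       1.00       0.99       0.99
I364N-ATP  0.81    0.80    0.99       0.99       1.00       0.99
K275A-ATP  0.81    0.81    0.99       0.99       0.99       1.00

classifier AUC: 0.899
```

All tabular outputs (`hub_scores.csv`, `communities.csv`, `betweenness.csv`,
`dccm_similarity.csv`, `rmsf_<system>.csv`, …) land in the output directory,
and a rerun with the same config and seed reproduces them byte-identically.

## Command line

```sh
allonet synth --out data/ --seed 17 --compact     # write a study set to disk
allonet run  --compact --out run/ --seed 17       # full pipeline
allonet network --manifest data/manifest.json --domains data/domain_map.json --out net/
```

Subcommands `descriptors`, `surface`, `pca`, `network`, `hubs` and
`classify` run one stage (plus its dependencies) on a manifest or on a
freshly generated study set.

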