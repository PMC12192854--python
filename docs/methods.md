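# Methods

## Scope and model

`allonet` analyses conformational ensembles of a multidomain Src-family
kinase — five structural regions: SH3, SH2, the interdomain linker (L), and
the catalytic domain's N- and C-lobes (SH1N, SH1C) — and asks which
residues mediate state-dependent interdomain communication.  The chain of
inference is: displacement correlations (DCCM) → a thresholded residue
graph → community structure and centrality → a per-residue score that
combines state discrimination, module mixing, and interface enrichment.
Residue numbering follows the construct (first residue may be 60); all
matrices are positional with an explicit bidirectional mapping.

## Descriptors

* **Superposition** is least-squares optimal (Kabsch via SVD, determinant
  correction so only proper rotations are applied).  A fit needs ≥ 3
  non-collinear atoms.
* **RMSF** uses an iterated fit-to-mean: frames are superposed to the
  current mean structure and the mean recomputed, twice.  The fixed point
  is reached almost immediately for unimodal ensembles; the convention
  matches standard fluctuation analysis.
* **Per-domain RMSD** defaults to the *global-fit* convention — fit on the
  whole selection, measure deviation over the domain — so the value reads
  as the domain's displacement relative to the core.  A domain-fit mode is
  exposed (`fit="domain"`).
* **Representative structures** are PAM k-medoids on the pairwise fitted
  RMSD matrix; k ∈ 2–8 is chosen by maximal mean silhouette and the medoid
  of the most populated cluster is returned.  For long ensembles the RMSD
  matrix is computed on an even frame subsample (default ≤ 200 frames;
  pipeline default 100) — medoid selection is a summary, not a statistic,
  and is insensitive to this thinning.  All-identical frames return frame 0
  with a degenerate-clustering warning.
* **Distribution comparisons** use the two-sided Wilcoxon signed-rank test
  for paired samples; unpaired or unequal-length samples fall back to the
  rank-sum test with a logged warning.  All-zero paired differences are a
  degenerate-test error, not p = 1.

## SASA and interfaces

SASA is Shrake–Rupley: each atom's sphere is inflated by the probe radius
(1.4 Å), covered with 960 golden-spiral points, and the fraction of points
outside every neighbour's inflated sphere is scaled by 4π(r+probe)².
Element radii: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å.  The point
count trades accuracy for speed; at 960 points the single-atom error vs the
analytic sphere is < 0.1 % and packed-structure totals move < 2 % when the
count is quadrupled.

Interface residues between two structural parts lose more than 1.0 Å² of
SASA on association: ΔSASA_r = SASA_r(isolated part) − SASA_r(complex),
computed with only the two parts' atoms present (occlusion by the rest of
the protein is deliberately excluded, matching the two-body definition).
Per system, interfaces are evaluated on the representative (medoid)
structure for every region pair, and the union feeds the interface
frequency f_r.  Pocket surface area is the summed SASA of all residues
within 5 Å of the ligand; by default the ligand itself does not occlude
(the area of the unliganded pocket surface) — `include_ligand=True` gives
the occluded variant.

## Essential dynamics

PCA of the 3N×3N covariance of Cα coordinates about the mean (population
1/F normalisation), frames superposed to the ensemble mean first — the same
reference convention as RMSF.  Eigenvalues are clipped at 0 (tolerance
−1e-8); extreme projections reconstruct conformations on a single mode
between the minimum and maximum observed projections.

## Correlation networks

The DCCM uses vector displacements: C_ij = ⟨Δr_i·Δr_j⟩ normalised by the
residue fluctuation magnitudes, so it is symmetric with unit diagonal and
bounded in [−1, 1].  `align=True` (fit-to-mean) is correct for raw
trajectories; ensembles generated by this package are already expressed in
a common reference frame and are analysed with `align=False` — refitting
such ensembles would project out the rigid-body components of the *planted*
correlation and bias entries downward.  Zero-variance residues get zero
off-diagonal correlation with a warning.  Replicates are combined by
element-wise averaging of per-replicate DCCMs (default) or by frame
concatenation.

The residue graph keeps an edge where |C_ij| strictly exceeds 0.8, with
weight |C_ij| and shortest-path length −log|C_ij| (so strongly correlated
pairs are dynamically close; `1minus` and `unweighted` transforms are
available).  Communities are Louvain on the weighted graph, best of 10
seeded restarts by modularity; isolated residues are recorded as
unassigned.  Module purity is the fraction of members from the module's
dominant region; the *integration module* is the lowest-purity module of
size ≥ 4 (ties: larger, then lower id).  Betweenness uses the length
weights and the standard 2/((N−1)(N−2)) normalisation over the graph's
node count.  Threshold consistency rebuilds the graph over a grid
(0.70–0.90 by default) and scores each residue by the fraction of
thresholds at which it is a top-25 connector.

## Hub scoring

Per residue r over the N systems: ρ_r is the Pearson correlation of the
betweenness profile with the binary activity labels (constant profiles are
flagged and set to 0); M_{r,s} = 1 − purity of the module containing r in
system s; μ_r is the mean of M_{r,s}; the mix-weighted correlation is
ρ_r·μ_r and the interface-weighted score is ρ_r·μ_r·(1+f_r).  A hub
requires score > 0.5 strictly, which implies ρ_r > 0.25.

Two mixing variants are implemented.  The default (`own_module`) credits
every residue with its own module's heterogeneity.  The stricter
`integration_gated` variant credits only members of the single integration
module per system.  The default was chosen because Louvain routinely
splits a genuinely mixed set of coupling residues across several mixed
modules; gating on one module then under-counts all but one fragment, and
planted coupling residues become unrecoverable even when every one of them
sits in a region-mixed module.  The ungated index preserves the intended
semantics — zero for pure modules, monotone in heterogeneity, bounded —
and makes recovery robust (see the acceptance report).  The
threshold-consistency score is reported as an auxiliary `unified_score`
(consistency × mix-weighted correlation) and does not enter the
interface-weighted score.

## Synthetic study sets

The generator emulates the statistical signatures of a simulation campaign
without dynamics.  Per system, a planted residue correlation matrix is
built from three levels — intra-region ρ_intra, hub cross-region ρ_hub,
background ρ₀ — projected to the nearest PSD matrix (eigenvalue clipping at
1e-8, diagonal renormalised), Cholesky-factorised, and sampled as i.i.d.
zero-mean Gaussian displacements applied identically and independently per
axis around a fixed solenoid reference geometry (3.8 Å Cα spacing, packed
successive turns so SASA/interface stages see plausible contacts).  Because
the same residue-level correlation drives x, y and z, the planted matrix
*is* the expected DCCM, giving every downstream stage an analytic target:
the sampling error of an entry is ≈ (1−C_ij²)/√F.

Default design (matching the study layout): six systems — WT and WT-ATP
active-like, WT-DAS and three mutants inactive-like — three replicates
each; the full-scale domain map spans residues 60–502 (443 residues) with
2000 frames per replicate, and a compact 80-residue variant with 400-frame
replicates is used for tests and the acceptance report.

The planted hubs default to the interdomain linker, globally coupled in
active-like systems (ρ_hub = ρ_intra = 0.90) and collapsed to background in
inactive-like systems (ρ_hub = ρ₀ = 0.72).  The background level is not
arbitrary: a valid correlation matrix cannot couple one residue above 0.8
to many partners that are mutually only weakly correlated — PSD repair
silently shrinks such hub rows far below the edge threshold.  Above-
threshold cross-domain hub edges therefore require a substantially
correlated global background, which is also the physically sensible
picture of a concertedly moving active state.  With these defaults the
active-like networks are globally integrated through the linker while the
inactive-like networks fragment into five pure domain cliques.

What the generator does **not** emulate: anharmonic and multi-basin
dynamics, temporal autocorrelation (frames are i.i.d.), side-chain packing
and real interface chemistry, ligand kinetics, and any mean-structure
difference between states (classes differ only in their correlation
structure).  Passing tests therefore demonstrate that the pipeline recovers
planted *correlation-network* structure, not that it would resolve subtle
conformational differences in real trajectories.

Feature tables for the classifier are generated separately: 16 Gaussian
features, a configurable informative subset (default 7) separated by
d pooled standard deviations, configurable class imbalance.

## State classifier

Frame-level stratified 80/20 split (the frame-shuffled protocol; a grouped
split by system is recommended for real, autocorrelated trajectories and is
available by passing a grouped table), Min–Max scaling fitted on the
training split only, SMOTE oversampling of the minority class to a 0.5
minority/majority ratio on training data only (in-package implementation:
k = 5 nearest minority neighbours, uniform interpolation), then a
1000-tree random forest with unrestricted depth.  Permutation importance is
the mean drop in held-out AUC over 10 shuffles per feature.  The default
16-descriptor geometry spec (10 region-centroid distances, 5 region spans,
one interdomain angle) is derived from the domain map so it applies to any
five-region protein; named residue-pair descriptors can be supplied
instead.

## Problem sizes and numerical tolerances

Acceptance-level experiments run at: DCCM sampling fidelity F = 10⁴ on the
compact map; community recovery at ρ_intra = 0.85, ρ₀ = 0.10, F = 5000,
20 seeds (ARI > 0.9 required in ≥ 18); planted-hub recovery over 20
generated study sets (compact design, interfaces included); betweenness
validated exactly against an exhaustive path-enumeration oracle on 100
random graphs of ≤ 12 nodes; classifier behaviour at 2000 frames/class
(d = 3) and 5000 frames/class (d = 0, AUC expected in 0.45–0.55).
Matrix-identity checks use 1e-8–1e-12 absolute tolerances; Monte-Carlo
checks use 3σ-style bounds stated in each test.

## Known limitations

* Hub scores scale with the number of active-like systems (μ_r averages
  over all systems), so absolute score magnitudes are design-dependent;
  rankings are the robust output, and the 0.5 hub threshold is meaningful
  only for designs with strong recurrent mixing across many systems.
* Louvain is stochastic; best-of-10 restarts with recorded seeds tames but
  does not eliminate partition variability on near-degenerate graphs.
* The Shrake–Rupley implementation loops per atom and is sized for
  Cα-resolution synthetic structures and single all-atom structures, not
  for per-frame SASA over long trajectories.
* Binary trajectory formats (XTC/DCD) are out of scope; multi-model PDB and
  CSV frame tables are the supported inputs.
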