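# Methods

`masldscreen` implements a fully in silico screening pipeline for
multitarget nutraceutical candidates against a ten-protein MASLD panel
(nuclear receptors FXR, PPAR-α/γ, THR-β; lipogenic/cholesterogenic enzymes
ACC1, FASN, DGAT2, HMGCR; transport/regulatory proteins LIPG, FABP4). This
note records the models, the defaults and why they were chosen, the
numerical conventions, and the limits of what the synthetic study can show.

## Curation

Bioactivity records (SMILES + target + IC50 in nM + replicate metadata) are
standardized with RDKit: largest organic fragment (salt stripping), charge
neutralization, canonical tautomer, then a fixed pH-7.4 protonation rule
set (carboxylic/sulfonic acids deprotonated; non-aromatic, non-amide amines
protonated). The tautomer signature is the InChIKey of the neutral
canonical tautomer; the deduplication key is (first 14-character InChIKey
connectivity block, tautomer signature), so salts and tautomer drawings of
one compound merge. Standardization is idempotent by construction — the
charge rules are applied last and are exactly undone by the neutralization
step on re-entry.

Replicate IC50s aggregate by the median. Reliability is quantified as
RSE = SEM/mean over the replicate set; a single measurement has RSE 0 (it
cannot be internally inconsistent). Labels binarize at IC50 ≤ 1 µM
(boundary inclusive) and are censored — retained but excluded from training
— when RSE strictly exceeds 15%. Regulatory triage is a membership lookup
of the connectivity block in packaged, editable text lists (a food-grade
list and a toxicology-alert list, both synthetic stand-ins for GRAS/Novel
Food and alert registries; no network access). Red-flag compounds are
dropped from downstream triage.

## Features

2048-bit Morgan fingerprints (radius 2) plus continuous descriptors (MW as
average formula mass, H-bond donors/acceptors, Crippen logP, TPSA,
rotatable bonds, elemental counts). A packaged fallback descriptor table
pins MW/logP/TPSA for the six anchor actives (baicalin, myricetin,
luteolin, rutin, diosmin, genistein) so formulation outputs are
reproducible regardless of toolkit version drift.

Feature curation (fit on training folds only, reused downstream): bits with
minority frequency < 1% and continuous features with variance < 1e−8 are
dropped; for continuous pairs with |r| > 0.95 the member with lower mutual
information with the label is dropped (MI via equal-frequency 10-bin
discretization); the continuous block is robust-scaled, (x − median)/IQR
with linear-interpolation quantiles, falling back to MAD and then to no-op
for degenerate spreads.

## Models

Per target, a stacked ensemble of three pluggable base learners — defaults:
random forest (500 trees), XGBoost, and LightGBM, i.e. one bagging learner
and two gradient-boosted variants — each with inverse-frequency weighting
of the positive class. Folds are leakage-safe: scaffold splits co-assign
all compounds sharing a Bemis–Murcko scaffold (greedy largest-first packing
into the smallest fold; an assertable invariant checks no scaffold spans
folds), and time splits cut timestamp quantiles with stable tie-breaking.
The logistic meta-model and the isotonic calibrator are fitted strictly on
the out-of-fold probability matrix. Single-class training folds are skipped
with a warning; if that leaves single-class out-of-fold labels, training
aborts with an explicit error.

Reported metrics: per-fold and pooled OOF ROC-AUC, PR-AUC, accuracy,
balanced accuracy, precision/recall/F1, MCC, Brier, and a Hosmer–Lemeshow
test on 10 equal-frequency risk bins (χ² with g−2 df). The decision
threshold t_opt maximizes F1 on the calibrated OOF predictions
(config-switchable to Youden's J). Hyperparameter search is a compact
Tree-structured Parzen Estimator (γ = 0.25 good/bad split, Gaussian kernel
densities, 24 candidates per proposal) after 10 random startup trials, with
pure random search and exhaustive grid enumeration as fallbacks; it is
deterministic given the seed. Default budget 50 trials; the pipeline runs
with the documented learner defaults unless tuning is requested.

## Aggregation and ranking

TA counts targets with calibrated p ≥ 0.50 (inclusive boundary,
config-switchable, chosen to match the p ≥ 0.50 classification convention).
TA_weighted is Σ w_t·p_t with the packaged pathway-weight table (weights
sum to 8.289); with no weights configured it reduces to the mean. The main
ranking score defaults to TA_weighted. Candidates order by TA, then main
score, then TA_weighted, stably. Priority tiers: TA ≥ 3 high, 1–2 medium,
0 low. The selectivity flag requires max p ≥ 0.80 and second-max ≤ 0.40;
selectivity entropy is the Shannon entropy (natural log; base-2 optional)
of the profile normalized to a distribution. Inter-model concordance uses
Kendall's W with tie correction and mean pairwise Jaccard of top-20 lists.

## Chemical space

Structural clustering: single linkage (config: complete/average) on
1 − Tanimoto over Morgan bits, cut at each threshold in 0.10–0.40 (step
0.05), keeping the silhouette-maximizing cut. Silhouette conventions:
singleton members contribute 0; k = 1 and k = n partitions score −1, which
is what triggers the fallback chain — threshold shift toward maximum
similarity (5th percentile of positive distances), mutual-kNN communities
(k = 5), then MST largest-edge cut. MOA clustering reuses the same
machinery on cosine distance between probability vectors (grid 0.05–0.50);
zero rows are excluded with a warning. Medoids minimize summed
intra-cluster distance. The diversity index is 1 − mean pairwise Tanimoto.
Break-gap (activity-cliff) scanning flags (pair, target) combinations with
Tanimoto ≥ 0.80 and |Δp| ≥ 0.40, with a 3×3 grid mode over
{0.75, 0.80, 0.85} × {0.30, 0.40, 0.50}. Target co-activation is Spearman
rank correlation; heat-map columns order by cluster id ascending, then
TA_weighted and main score descending.

## PBPK and coverage

A screening-level one-compartment Bateman model: with k = Cl/Vd,
Vd_tot = Vd·mass, molar dose D = dose/MW,

    C(t) = F·D·Ka / (Vd_tot·(Ka − k)) · (e^(−kt) − e^(−Ka·t))   [µM]

with tmax = ln(Ka/k)/(Ka − k). Defaults: Ka = 0.8 h⁻¹, Cl = 0.1 L·h⁻¹·kg⁻¹,
Vd = 0.6 + 0.02·logP L/kg, 70 kg body mass, F = 1 unless overridden; the
packaged per-compound override table takes precedence. Ka = k is perturbed
by ε with a warning. The single compartment is labeled hepatic; no organ
partitioning is modeled. Time grid 0–24 h at 0.02 h; windows: morning and
evening [0, 12] h from intake, postprandial [0, 6] h.

Genistein's override F = 0.135 is back-calculated from its published
100 mg → Cmax ≈ 0.75 µM dose–response anchor (the model's closed form
gives 5.557 µM at F = 1), and independently reproduces the ≈160 mg minimum
dose for ≥ 50% postprandial coverage; the other anchors keep the neutral
F = 1 screening default because no dose anchor pins them.

%T>IC50 is never computed on summed concentrations: per target, component
effects E = C/(IC50 + C) (Hill n = 1) are aggregated by HSA (max) or Bliss
independence (1 − Π(1 − E)); coverage is the fraction of the window where
the aggregated effect ≥ 0.5 — which reduces exactly to C > IC50 for a
single compound — and the window figure is the target-weight-weighted mean.
Both aggregation modes are implemented; Bliss is the default and always
dominates HSA. The minimum simulated dose (MSD) is the smallest grid dose
reaching the coverage target, bisection-refined; coverage tolerance bands:
≥ 70% meets the primary design threshold, 50–70% is tolerated only with a
justified enhancement strategy (e.g. phytosome, benchmark ~5.2× relative
bioavailability, applied to F and capped at 1), below 50% fails. AUC
identities are checked against F·D/(Cl·mass); the numeric horizon is 12
elimination half-lives because at 10 the truncated tail can exceed the
0.1% identity tolerance when Ka/k ≈ 5.

## Formulation

Selection is a mixed-integer linear program over binary (candidate, dose
level) variables (HiGHS via SciPy): maximize α·TA + β·TA_weighted
(defaults α = β = 1) subject to portion mass ≤ 2000 mg (default cap,
config-exposed; per-form caps are not quantified anywhere authoritative),
window membership, at most one member per structural and per MOA cluster,
pairwise Tanimoto distance ≥ 0.3 (default), and per-compound regulatory
dose limits; compounds whose MSD exceeds their limit enter only in an
adjuvant role at the capped dose. Binary variables are required by the
one-per-cluster and selection logic, so the "linear program" is solved
exactly as a MILP. Infeasible instances return the best relaxation (mass,
then pairwise constraints dropped) with every constraint flag recomputed
from the emitted components — the audit is independent of the solver. An
exhaustive subset-enumeration oracle cross-checks the MILP on small pools.
The technology report is a static lookup (carriers, stability risks,
sensory notes) for the packaged anchor actives; unknown compounds get
descriptor-only rows, never inferred text.

## Synthetic study

The generator emulates a curated multi-target screening extract. Structures
come from 12 flavonoid-like scaffold cores (flavone, isoflavone, flavanone,
chalcone, coumarin, arylbenzofuran, aurone, azaflavone, benzoxazole,
stilbene, xanthone, arylbenzothiophene) with two substituent slots drawn
from 20 small groups, giving distinct Bemis–Murcko scaffolds for meaningful
scaffold splits; pseudo-timestamps are generation order so time splits are
meaningful too.

Activity truth is a planted logistic model on standardized true continuous
descriptors (not fingerprints, so fingerprint models must generalize),
effect scale 4.0, per-target intercepts solved by bisection to hit the
configured prevalence (default 0.30). A planted 8% of compounds receive a
+2.5 latent boost across all targets (the multi-target actives used for
enrichment checks). IC50s realize the truth exactly:
log10 IC50_nM = 3 − σ·(Φ⁻¹(p) + g), g ~ N(0,1), σ = 0.6, so
P(IC50 ≤ 1 µM) = p. Three replicates with lognormal CV 0.2 exercise the RSE
censoring rule (~15–18% of labels censor at these settings; censoring is
monotone in CV). Defaults — 600 compounds × 10 targets — are the study
conditions used by the acceptance checks; every stage is deterministic
given the seed.

What the synthetic study does not emulate: real SAR (activity derives from
global physicochemistry, not pharmacophores), assay heterogeneity across
sources, correlated inter-target pharmacology beyond the planted
multi-target subset, and real PK variability. Passing tests therefore
demonstrate pipeline correctness and recoverability of planted signal at
realistic noise — not predictive validity on real ChEMBL extracts.

## Numerical conventions and edge cases

Quantiles use linear interpolation. Tanimoto of two empty fingerprints is 0
with a warning. All-zero probability profiles have entropy 0 with a
warning. Isotonic calibration on single-class input degrades to the
identity map with a warning. Single-class test sets report missing AUCs.
Ties in ranking and heat-map ordering preserve input order (stable sorts).
Cluster ids are canonicalized by first appearance. The acceptance study,
examples, and tests run at desk scale (≤ 600 compounds) so the whole suite
completes in a few minutes on one core.

## Known limitations

No live ChEMBL retrieval (offline tables only), no real registry
integration, no multi-compartment PK, transporters, circadian kinetics, or
microbiota metabolism; carrier/sensory outputs are lookups, not models. The
Ka/Cl "empirical scaling" from MW/logP/TPSA is represented only by defaults
plus overrides, since no authoritative functional form is available.
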