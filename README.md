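# masldscreen

In silico multitarget nutraceutical screening for metabolic
dysfunction-associated steatotic liver disease (MASLD): from raw
bioactivity tables to calibrated per-target activity probabilities,
system-level candidate ranking, chemical-space mapping, screening-level
pharmacokinetic exposure simulation, and chrono-window formulation design.

MASLD is a multifactorial disease; single-target potency is a poor design
criterion for food-grade interventions. `masldscreen` is written for
computational chemists and nutraceutical formulators who want one auditable
trajectory from `IC50` records to a product specification: which compounds,
at which doses, in which intake window, under which regulatory and
diversity constraints.

## The method

For a ten-protein MASLD panel (FXR, PPAR-α, PPAR-γ, THR-β, ACC1, FASN,
DGAT2, HMGCR, LIPG, FABP4):

1. **Curation** — structures standardized (salt stripping, canonical
   tautomer, pH 7.4 protonation), deduplicated on the InChIKey connectivity
   block, replicate IC50s aggregated by the median; active ⇔ IC50 ≤ 1 µM;
   labels with replicate RSE > 15% censored; regulatory triage against
   local food-grade/alert lists.
2. **Models** — per target, a stacked ensemble (random forest + two
   gradient-boosted learners) under Bemis–Murcko scaffold or time splits,
   logistic meta-model on out-of-fold probabilities, isotonic calibration:
   p_t = calibrated p(active) per compound and target.
3. **Aggregation** — total activity TA = #{t : p_t ≥ 0.50} and the weighted
   score s = Σ_t w_t·p_t (TA_weighted) with pathway weights; hierarchical
   ranking TA → main score → TA_weighted; priority tiers, selectivity
   entropy, Kendall's W / Jaccard concordance.
4. **Chemical space** — Tanimoto clustering of ECFP4-style fingerprints
   with silhouette auto-cut and kNN/MST fallbacks, MOA clustering of
   probability vectors, break-gap (activity-cliff) scanning.
5. **PBPK** — one-compartment Bateman exposure
   C(t) = F·D·Ka/(V·(Ka−k))·(e^(−kt) − e^(−Ka·t)); per-target Hill effects
   E = C/(IC50+C) aggregated across components (HSA/Bliss); %T>IC50 window
   coverage; minimum simulated dose (MSD).
6. **Formulation** — MILP selection (maximize α·TA + β·TA_weighted) under
   portion-mass, one-per-cluster, Tanimoto-diversity, and regulatory-dose
   constraints, emitting `ranked_hits.csv` / `portfolio.csv`.

A seeded synthetic-data module generates structure-bearing multi-target
screens with planted logistic ground truth, so every stage is testable
offline. Full details in [docs/methods.md](docs/methods.md).

## Worked example

Dose finding for a genistein-like lead (packaged PK overrides: Ka 0.8 h⁻¹,
Cl 0.1 L·h⁻¹·kg⁻¹, Vd = 0.6 + 0.02·logP, F = 0.135):

```bash
$ python examples/04_pbpk_dose_finding.py
genistein params: Ka=0.8 1/h, Cl=0.1 L/h/kg, Vd=0.64 L/kg, F=0.135, k=0.15625 1/h
tmax = 2.54 h, Cmax(100 mg) = 0.750 uM
trapezoidal AUC / analytic F*D/(Cl*m): 0.99970
MSD for >=50% coverage over 0-6 h: 160 mg (coverage 59.1%)
```

The curve peaks ~2.5 h after intake; 100 mg stays below the 1 µM
half-maximal threshold, and the smallest dose giving ≥50% of the 0–6 h
postprandial window above threshold is 160 mg. The AUC line verifies the
numeric integral against the analytic identity F·D/(Cl·body mass).

The full pipeline runs from the shell:

```bash
masldscreen --outdir run all --n-compounds 200 --seed 7
```

which writes the curated table, per-target model metrics,
`ranked_hits.csv` (probabilities, TA/TA_weighted, priorities, cluster
memberships), break-gap report, exposure summary, and `portfolio.csv`
(product, window, component, dose, role, constraint flags). Each
`examples/0*.py` script demonstrates one capability with a narrated
printout.

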