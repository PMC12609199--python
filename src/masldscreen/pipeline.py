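"""Stage orchestration: each function is a pure mapping from (inputs,
config, seed) to artifacts, shared by the library API, the examples, and
the thin command-line layer.

Stage order: synth -> curate -> featurize -> train -> rank -> cluster ->
pbpk -> formulate.  Artifacts are plain CSV/YAML files; every writer embeds
the resolved config hash for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation, chemspace, curation, features, formulation, models, pbpk
from .config import PipelineConfig
from .synthetic import SyntheticSpec, generate_dataset

log = logging.getLogger(__name__)


def run_curation(records: pd.DataFrame, config: PipelineConfig):
    comps, rejects = curation.deduplicate_and_aggregate(
        records,
        activity_threshold_nM=config.thresholds.activity_nM,
        rse_threshold=config.thresholds.rse_censor,
        panel_targets=set(config.panel.target_ids),
    )
    # red-flag compounds are excluded from downstream triage
    kept = [c for c in comps if c.status != "red_flag"]
    return kept, curation.curated_table(kept), rejects


def run_featurize(compounds, overrides=None) -> features.FeatureMatrix:
    ids = [c.compound_id for c in compounds]
    return features.featurize([c.canonical_smiles for c in compounds],
                              index=ids, overrides=overrides)


def run_training(compounds, fm: features.FeatureMatrix,
                 curated: pd.DataFrame, config: PipelineConfig,
                 timestamps=None) -> dict:
    """Train one stacked model per panel target on non-censored labels and
    score every curated compound with calibrated probabilities."""
    ids = [c.compound_id for c in compounds]
    smiles = {c.compound_id: c.canonical_smiles for c in compounds}
    labels = curated.pivot(index="compound_id", columns="target_id",
                           values="label").reindex(ids)
    trained: dict[str, models.TargetModel] = {}
    prob = pd.DataFrame(index=pd.Index(ids, name="compound_id"),
                        columns=list(config.panel.target_ids), dtype=float)
    base_prob: dict[str, pd.DataFrame] = {}
    for target in config.panel.target_ids:
        if target not in labels.columns:
            raise ValueError(f"no curated records for panel target {target}")
        usable = labels[target].isin(["active", "inactive"]).to_numpy()
        y = (labels[target].to_numpy() == "active")[usable].astype(int)
        sub_ids = np.asarray(ids)[usable]
        sub_smiles = [smiles[i] for i in sub_ids]
        fitted = features.curate_features(
            features.FeatureMatrix(index=pd.Index(sub_ids), bits=fm.bits[usable],
                                   continuous=fm.continuous.loc[sub_ids]), y)
        X = fitted.matrix()
        plan = models.make_splits(
            sub_smiles, k=config.model.n_folds, kind=config.model.split_kind,
            timestamps=None if timestamps is None
            else np.asarray(timestamps)[usable])
        if plan.kind == "scaffold":
            models.assert_scaffold_disjoint(plan)
        model = models.train_stacked_model(
            X, y, plan, target_id=target, rf_trees=config.model.rf_trees,
            seed=config.model.seed, threshold_rule=config.model.threshold_rule,
            hl_bins=config.model.hl_bins)
        trained[target] = model
        X_all = features.apply_curation(fm, fitted).matrix()
        prob[target] = model.predict_proba(X_all)
        base_prob[target] = model.predict_base_proba(X_all).set_axis(ids, axis=0)
    return {"models": trained, "probabilities": prob, "base_probabilities": base_prob}


def run_ranking(prob: pd.DataFrame, config: PipelineConfig,
                smiles: dict | None = None) -> pd.DataFrame:
    return aggregation.score_hits(
        prob, config.panel, smiles=smiles,
        threshold=config.thresholds.probability,
        inclusive=config.thresholds.ta_inclusive)


def run_clustering(hits: pd.DataFrame, smiles: dict,
                   config: PipelineConfig) -> dict:
    ids = list(hits["compound_id"])
    fps = np.vstack([features.compute_fingerprint(smiles[i]) for i in ids])
    structural = chemspace.cluster_structural(
        fps, grid=config.cluster.structural_grid,
        linkage_method=config.cluster.linkage, knn_k=config.cluster.knn_k)
    p_cols = [f"p_{t}" for t in config.panel.target_ids]
    P = hits[p_cols].to_numpy(dtype=float)
    moa, keep = chemspace.cluster_moa(
        P, linkage_method=config.cluster.linkage, knn_k=config.cluster.knn_k)
    table = chemspace.cluster_table(ids, structural, moa, keep)
    hits = hits.merge(table[["compound_id", "cluster_id", "moa_cluster_id"]],
                      on="compound_id", how="left")
    p_frame = pd.DataFrame(P, index=ids, columns=list(config.panel.target_ids))
    breaks = chemspace.break_gap_scan(
        fps, p_frame, config.thresholds.break_gap_tanimoto,
        config.thresholds.break_gap_delta_p)
    grid_counts = chemspace.break_gap_grid(
        fps, p_frame, config.thresholds.break_gap_tan_grid,
        config.thresholds.break_gap_gap_grid)
    return {"hits": hits, "structural": structural, "moa": moa,
            "cluster_table": table, "break_gaps": breaks,
            "break_gap_grid": grid_counts,
            "diversity_index": chemspace.diversity_index(fps),
            "rank_correlations": chemspace.target_rank_correlations(p_frame),
            "fingerprints": fps}


def run_pbpk(hits: pd.DataFrame, smiles: dict, config: PipelineConfig,
             top_n: int = 12, dose_grid=None) -> dict:
    """Derive PK parameters for the leading hits, assign each to its
    best-covered chrono-window, and find the minimum simulated dose."""
    cfg = config.pbpk
    if dose_grid is None:
        dose_grid = tuple(range(25, 2001, 25))
    windows = {}
    for name, (t0, t1) in cfg.windows.items():
        targets = [t for t in cfg.window_targets.get(name, ())
                   if t in config.panel.target_ids]
        if not targets:
            continue
        windows[name] = pbpk.WindowSpec(
            name=name, t0=t0, t1=t1,
            target_weights={t: 1.0 for t in targets},
            ic50={t: cfg.default_ic50_uM for t in targets},
            aggregation=cfg.aggregation)
    rows = []
    overrides = pbpk.load_pk_overrides()
    for rec in hits.head(top_n).itertuples(index=False):
        desc = features.compute_descriptors(smiles[rec.compound_id])
        params = pbpk.derive_pk_parameters(
            mw=desc["mw"], logp=desc["logp"], tpsa=desc["tpsa"],
            overrides=overrides.get(rec.compound_id),
            default_ka=cfg.default_ka, default_cl=cfg.default_cl,
            default_f=cfg.default_f, body_mass=cfg.body_mass_kg)
        # window assignment: highest mean p over each window's targets
        best_window, best_p = None, -1.0
        for name, w in windows.items():
            p_mean = float(np.mean([getattr(rec, f"p_{t}") for t in
                                    w.target_weights]))
            if p_mean > best_p:
                best_window, best_p = name, p_mean
        w = windows[best_window]
        msd = pbpk.find_min_dose(params, w,
                                 coverage_target=config.formulation.coverage_tolerated,
                                 dose_grid=dose_grid,
                                 t_end=cfg.grid_end_h, dt=cfg.grid_step_h)
        prof = pbpk.simulate_exposure(
            replace(params, dose_mg=msd["msd_mg"] or max(dose_grid)),
            compound=rec.compound_id, t_end=cfg.grid_end_h, dt=cfg.grid_step_h)
        cov = pbpk.window_coverage([prof], w)
        rows.append({
            "compound_id": rec.compound_id, "window": best_window,
            "ka": params.ka, "cl": params.cl, "vd": params.vd, "f": params.f,
            "mw": params.mw,
            "msd_mg": msd["msd_mg"], "achievable": msd["achievable"],
            "coverage_pct": cov.aggregated, "cmax_uM": prof.cmax,
            "tmax_h": prof.tmax,
        })
    return {"exposure": pd.DataFrame(rows), "windows": windows}


def run_formulation(hits: pd.DataFrame, exposure: pd.DataFrame,
                    fps_lookup: dict, config: PipelineConfig,
                    limits: dict | None = None) -> list:
    cands = []
    hit_rows = hits.set_index("compound_id")
    for rec in exposure.itertuples(index=False):
        if rec.msd_mg is None or not rec.achievable:
            continue
        h = hit_rows.loc[rec.compound_id]
        cands.append(formulation.Candidate(
            compound_id=rec.compound_id, window=rec.window,
            ta=int(h["TA"]), ta_weighted=float(h["TA_weighted"]),
            cluster_id=int(h.get("cluster_id", 0)),
            moa_cluster_id=int(h.get("moa_cluster_id", 0)),
            msd_mg=float(rec.msd_mg),
            regulatory_limit_mg=(limits or {}).get(rec.compound_id),
            fingerprint=fps_lookup.get(rec.compound_id),
            coverage_pct=float(rec.coverage_pct)))
    specs = []
    for window in config.pbpk.windows:
        spec = formulation.optimize_portfolio(
            cands, window,
            portion_cap_mg=config.formulation.portion_mass_cap_mg,
            alpha=config.formulation.alpha, beta=config.formulation.beta,
            min_tanimoto_distance=config.formulation.min_tanimoto_distance,
            missing_policy=config.formulation.missing_limit_policy)
        if spec.components:
            specs.append(spec)
    return specs


def run_all(config: PipelineConfig, synth_spec: SyntheticSpec,
            outdir: str | Path | None = None) -> dict:
    """Full synthetic-study pipeline; writes every artifact when ``outdir``
    is given."""
    config.validate()
    chash = config.config_hash()
    ds = generate_dataset(synth_spec)
    compounds, curated, rejects = run_curation(ds["records"], config)
    fm = run_featurize(compounds)
    smiles = {c.compound_id: c.canonical_smiles for c in compounds}
    ts = [int(t) for t in
          ds["library"].set_index("compound_ref")["timestamp"]
          .reindex([c.compound_id for c in compounds]).fillna(0)]
    training = run_training(compounds, fm, curated, config, timestamps=ts)
    hits = run_ranking(training["probabilities"], config, smiles=smiles)
    clusters = run_clustering(hits, smiles, config)
    hits = clusters["hits"]
    pk = run_pbpk(hits, smiles, config)
    fps_lookup = {cid: fp for cid, fp in
                  zip(hits["compound_id"], clusters["fingerprints"])}
    specs = run_formulation(hits, pk["exposure"], fps_lookup, config)

    result = {"dataset": ds, "compounds": compounds, "curated": curated,
              "rejects": rejects, "features": fm, "training": training,
              "hits": hits, "clusters": clusters, "pbpk": pk,
              "formulations": specs, "config_hash": chash}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ds["records"].to_csv(outdir / "bioactivity_records.csv", index=False)
        ds["truth"].to_csv(outdir / "ground_truth.csv", index=False)
        curated.to_csv(outdir / "curated_compounds.csv", index=False)
        rejects.to_csv(outdir / "rejected_records.csv", index=False)
        metrics = models.metrics_table(list(training["models"].values()))
        metrics.to_csv(outdir / "model_metrics.csv", index=False)
        aggregation.write_ranked_hits(hits, outdir / "ranked_hits.csv", chash)
        clusters["cluster_table"].to_csv(outdir / "clusters.csv", index=False)
        clusters["break_gaps"].to_csv(outdir / "break_gaps.csv", index=False)
        pk["exposure"].to_csv(outdir / "exposure_summary.csv", index=False)
        formulation.write_portfolio(specs, outdir / "portfolio.csv", chash)
        (outdir / "run_info.json").write_text(json.dumps({
            "config_hash": chash, "seed": synth_spec.seed,
            "n_compounds": synth_spec.n_compounds}, indent=2))
    return result
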